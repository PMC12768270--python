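"""Orthogroup filtering, sequence-based resolution, TF expansion, overrides,
and cross-species integration.

``sw_local_score`` is an independent textbook Smith-Waterman dynamic
program (affine gaps, Gotoh three-matrix recursion) used as the oracle for
the package's alignment-backed similarity scores.
"""

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from gutmap.ortho import (OrthologyTable, filter_orthogroups,
                          pairwise_similarity, best_ancestral_orthologue,
                          resolve, expand_tf_flags, apply_overrides,
                          integrate, make_aligner)
from gutmap.preprocess import run_preprocess
from gutmap.synthetic import SyntheticConfig, make_profiles, make_sequences
from conftest import small_config

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_local_score(a, b, gap_open=2.0, gap_extend=0.1):
    """Textbook affine-gap Smith-Waterman: a gap of length L costs
    gap_open + gap_extend * L."""
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))        # best ending in match/mismatch
    E = np.full((n + 1, m + 1), NEG)    # best ending in gap in b (left)
    F = np.full((n + 1, m + 1), NEG)    # best ending in gap in a (up)
    best = 0.0
    open_cost = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - gap_extend)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def random_protein(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n))


class TestFilterOrthogroups:
    def _table(self, per_species):
        return OrthologyTable({"OG1": {
            f"sp{i}": [f"sp{i}_g{j}" for j in range(c)]
            for i, c in enumerate(per_species) if c
        }})

    def test_over_hard_max_dropped(self):
        t = self._table([25, 25, 25, 25, 21])       # 121 genes
        assert filter_orthogroups(t).groups == {}

    def test_balanced_over_soft_max_kept(self):
        t = self._table([16, 16, 16, 16, 17])       # 81 genes, balanced
        assert "OG1" in filter_orthogroups(t).groups

    def test_unbalanced_over_soft_max_dropped(self):
        t = self._table([70, 3, 3, 3, 2])           # 81 genes, ratio 35
        assert filter_orthogroups(t).groups == {}

    def test_small_groups_untouched(self):
        t = self._table([1, 1, 2])
        assert "OG1" in filter_orthogroups(t).groups


class TestPairwiseSimilarity:
    def test_identical_sequences_score_one(self):
        s = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        sim = pairwise_similarity({"a": s, "b": s})
        assert sim.loc["a", "b"] == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        seqs = {f"s{i}": random_protein(rng, 40) for i in range(4)}
        sim = pairwise_similarity(seqs)
        assert np.allclose(sim.to_numpy(), sim.to_numpy().T)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_dp(self, seed):
        rng = np.random.default_rng(seed)
        a = random_protein(rng, 50)
        b = list(a)
        b[rng.integers(0, 50)] = "W" if b[rng.integers(0, 50)] != "W" else "A"
        b = "".join(b)
        aligner = make_aligner()
        assert aligner.score(a, b) == pytest.approx(sw_local_score(a, b),
                                                    abs=1e-9)

    def test_random_pair_matches_dp(self):
        rng = np.random.default_rng(42)
        a, b = random_protein(rng, 60), random_protein(rng, 45)
        assert make_aligner().score(a, b) == pytest.approx(
            sw_local_score(a, b), abs=1e-9)

    def test_invalid_residue_reported(self):
        with pytest.raises(ValueError, match="bad"):
            pairwise_similarity({"ok": "MKT", "bad": "MK1"})


class TestBestAncestral:
    def test_single_gene_per_species(self):
        rng = np.random.default_rng(1)
        group = {"sp1": {"sp1_g": random_protein(rng, 30)},
                 "sp2": {"sp2_g": random_protein(rng, 30)}}
        out = best_ancestral_orthologue(group)
        assert set(out["gene"]) == {"sp1_g", "sp2_g"}
        assert out["n_candidates"].tolist() == [1, 1]

    def test_identical_paralogs_tie_to_lexicographic(self):
        rng = np.random.default_rng(2)
        s = random_protein(rng, 30)
        other = random_protein(rng, 30)
        group = {"sp1": {"sp1_b": s, "sp1_a": s}, "sp2": {"sp2_g": other}}
        out = best_ancestral_orthologue(group)
        chosen = out.set_index("species").loc["sp1", "gene"]
        assert chosen == "sp1_a"

    def test_planted_ancestor_recovered(self):
        cfg = small_config(n_orthogroups=40, paralog_rate=1.0,
                           mut_rate_ortho=0.1, mut_rate_extra=0.3,
                           seq_len=120, module_spec=[], frac_block=0,
                           frac_gradient=0, frac_terminal=0, seed=9)
        _, truth = make_profiles(cfg)
        seqs, orthology = make_sequences(cfg, truth)
        table = OrthologyTable(orthology)
        resolved = resolve(table, seqs)
        hits = total = 0
        for og, by_sp in truth.ancestor_gene.items():
            for sp, gene in by_sp.items():
                if len(orthology[og][sp]) > 1:
                    total += 1
                    hits += resolved.gene(og, sp) == gene
        assert total == 40
        assert hits / total >= 0.9

    def test_adding_worse_paralog_never_changes_choice(self):
        rng = np.random.default_rng(3)
        anc = random_protein(rng, 60)
        near = anc[:57] + "AAA"
        far = random_protein(rng, 60)
        group = {"sp1": {"sp1_x": near}, "sp2": {"sp2_g": anc}}
        base = best_ancestral_orthologue(group)
        group["sp1"]["sp1_zzz"] = far
        extended = best_ancestral_orthologue(group)
        pick = extended.set_index("species").loc["sp1", "gene"]
        assert pick == base.set_index("species").loc["sp1", "gene"]


class TestTFExpansion:
    def _table(self):
        return OrthologyTable({
            "OG1": {"sp1": ["a1"], "sp2": ["b1", "b2"]},
            "OG2": {"sp1": ["a2"], "sp2": ["b3"]},
        })

    def test_no_member_flagged(self):
        assert expand_tf_flags(set(), self._table()) == \
            {"OG1": False, "OG2": False}

    def test_single_member_flags_group(self):
        flags = expand_tf_flags({"b2"}, self._table())
        assert flags == {"OG1": True, "OG2": False}

    def test_idempotent(self):
        t = self._table()
        once = expand_tf_flags({"a2"}, t)
        # re-expressing the orthogroup flags at gene level and re-expanding
        flagged_genes = {g for og, f in once.items() if f
                         for genes in t.groups[og].values() for g in genes}
        twice = expand_tf_flags(flagged_genes, t)
        assert once == twice


class TestOverrides:
    def _table(self):
        return OrthologyTable({
            f"OG{i}": {"sp1": [f"hox{i}_sp1"], "sp2": [f"hox{i}_sp2"]}
            for i in range(21)
        } | {"OGx": {"sp1": ["other1"], "sp2": ["other2"]}})

    def test_empty_override_is_identity(self):
        t = self._table()
        assert apply_overrides(t, {}).groups == t.groups

    def test_merge_two_groups(self):
        t = self._table()
        out = apply_overrides(t, {"OG000PG0304": {
            "sp1": ["hox3_sp1", "hox4_sp1"],
            "sp2": ["hox3_sp2", "hox4_sp2"]}})
        assert "OG3" not in out.groups and "OG4" not in out.groups
        assert out.groups["OG000PG0304"]["sp1"] == ["hox3_sp1", "hox4_sp1"]
        assert "OGx" in out.groups

    def test_hox_style_21_to_8(self):
        # regroup 21 automatic groups into 8 paralogue-position groups
        t = self._table()
        new_ids = ["OG000PG01", "OG000PG02", "OG000PG0304", "OG000PG05",
                   "OG000PG0607", "OG000PG0910", "OG000PG08", "OG000PG1115"]
        splits = np.array_split(np.arange(21), 8)
        overrides = {
            nid: {sp: [f"hox{i}_{sp}" for i in chunk]
                  for sp in ("sp1", "sp2")}
            for nid, chunk in zip(new_ids, splits)
        }
        out = apply_overrides(t, overrides)
        hox_groups = [g for g in out.groups if g.startswith("OG000PG")]
        assert len(hox_groups) == 8
        assert sum(1 for g in out.groups if g.startswith("OG0")) == 8
        assert "OGx" in out.groups

    def test_duplicate_gene_rejected(self):
        t = self._table()
        with pytest.raises(ValueError, match="twice"):
            apply_overrides(t, {
                "N1": {"sp1": ["hox1_sp1"]},
                "N2": {"sp1": ["hox1_sp1"]},
            })


@pytest.fixture(scope="module")
def integrated(small_generated):
    datasets, seqs, orthology, truth = small_generated
    zscored = {}
    for ds in datasets:
        _, z = run_preprocess(ds)
        zscored[ds.species] = z
    resolved = resolve(OrthologyTable(orthology), seqs)
    im = integrate(zscored, resolved)
    return im, truth, zscored


class TestIntegrate:
    def test_rows_require_presence_in_all_species(self, integrated):
        im, truth, zscored = integrated
        for og in im.values.index:
            for sp in im.species:
                assert f"{sp}_{og}" in zscored[sp].values.index or \
                    any(g in zscored[sp].values.index
                        for g in [f"{sp}_{og}", f"{sp}_{og}_p2"])

    def test_species_blocks_inherit_zscore_moments(self, integrated):
        im, _, _ = integrated
        for sp in im.species:
            block = im.species_block(sp).to_numpy()
            nonconst = block.std(axis=1) > 0
            assert np.abs(block[nonconst].mean(axis=1)).max() < 1e-10
            assert np.abs(block[nonconst].std(axis=1, ddof=1) - 1).max() \
                < 1e-10

    def test_planted_module_peaks_preserved(self, integrated):
        im, truth, _ = integrated
        hits = total = 0
        for og in im.values.index:
            if not truth.archetype[og].startswith("module"):
                continue
            for sp in im.species:
                cols = im.col_meta.index[im.col_meta["species"] == sp]
                ranks = im.col_meta.loc[cols, "ap_rank"].to_numpy()
                prof = im.values.loc[og, cols].to_numpy()
                got = ranks[np.argmax(prof)]
                total += 1
                hits += abs(got - truth.peak_rank[og][sp]) <= 1
        assert total > 0
        assert hits / total >= 0.8

    def test_columns_cluster_by_position_not_species(self, integrated):
        from scipy.cluster.hierarchy import fcluster, linkage
        from sklearn.metrics import adjusted_rand_score
        im, _, _ = integrated
        X = im.values.to_numpy().T
        Z = linkage(X, method="average", metric="correlation")
        n_sp = len(im.species)
        labels = fcluster(Z, t=n_sp, criterion="maxclust")
        species_labels = pd.factorize(im.col_meta["species"])[0]
        # relative AP position binned into as many groups as species
        rel = im.col_meta.groupby("species")["ap_rank"].transform(
            lambda r: (r - 1) / (r.max() - 1))
        pos_labels = np.minimum((rel * n_sp).astype(int), n_sp - 1)
        ari_species = adjusted_rand_score(species_labels, labels)
        ari_position = adjusted_rand_score(pos_labels, labels)
        assert ari_position > ari_species

    def test_missing_species_rejected(self, integrated):
        im, truth, zscored = integrated
        from gutmap.ortho import ResolvedMap
        empty = ResolvedMap({"OG0000000": {"spZZ": "g"}})
        with pytest.raises(ValueError, match="missing"):
            integrate(zscored, empty)


def test_orthogroups_tsv_roundtrip(tmp_path, small_generated):
    _, _, orthology, _ = small_generated
    table = OrthologyTable(orthology)
    path = tmp_path / "Orthogroups.tsv"
    table.write_tsv(path)
    back = OrthologyTable.read_tsv(path)
    assert back.groups == {og: by_sp for og, by_sp in table.groups.items()}
    # dialect check: comma+space separated gene lists
    text = path.read_text()
    multi = [og for og, by_sp in table.groups.items()
             if any(len(g) > 1 for g in by_sp.values())]
    if multi:
        assert ", " in text
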