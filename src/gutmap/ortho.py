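"""Orthogroup handling: size filtering, best-ancestral-orthologue resolution,
TF-flag expansion, manual overrides, and cross-species matrix integration.

Orthogroups (sets of genes across species descending from one ancestral
gene) are consumed in the OrthoFinder ``Orthogroups.tsv`` dialect: one row
per orthogroup, one tab-separated column per species, gene lists joined by
", ".  Many-to-one relationships are resolved per species to the "best
ancestral orthologue" -- the paralog with the highest average Smith-Waterman
similarity to all other species' members -- so each orthogroup contributes
exactly one expression profile per species to the integrated matrix.

Alignment uses BLOSUM62 with gap opening 2 and extension 0.1 (a gap of
length L costs 2 + 0.1*L), local mode; raw scores are length-dependent, so
similarities are normalized by the geometric mean of the two self-alignment
scores, giving 1.0 for identical sequences.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYBZXJUO*")


def make_aligner(gap_open: float = 2.0, gap_extend: float = 0.1,
                 matrix: str = "BLOSUM62") -> PairwiseAligner:
    """Local aligner under the opening+per-residue gap cost convention."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass
class OrthologyTable:
    """orthogroup id -> species id -> list of gene ids."""

    groups: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        for og, by_sp in self.groups.items():
            if not any(by_sp.values()):
                raise ValueError(f"orthogroup {og} is empty")
            for sp, genes in by_sp.items():
                if len(genes) != len(set(genes)):
                    raise ValueError(f"duplicate gene ids in {og}/{sp}")

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for by_sp in self.groups.values():
            for sp in by_sp:
                if sp not in out:
                    out.append(sp)
        return sorted(out)

    def total_genes(self, og: str) -> int:
        return sum(len(g) for g in self.groups[og].values())

    def per_species_counts(self, og: str) -> dict[str, int]:
        return {sp: len(g) for sp, g in self.groups[og].items() if g}

    # -- OrthoFinder Orthogroups.tsv dialect ---------------------------------

    @classmethod
    def read_tsv(cls, path) -> "OrthologyTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        og_col = df.columns[0]
        groups: dict[str, dict[str, list[str]]] = {}
        for _, row in df.iterrows():
            by_sp = {}
            for sp in df.columns[1:]:
                genes = [g for g in re.split(r",\s*", row[sp]) if g]
                if genes:
                    by_sp[sp] = genes
            groups[row[og_col]] = by_sp
        return cls(groups)

    def write_tsv(self, path) -> None:
        species = self.species
        rows = []
        for og in sorted(self.groups):
            rows.append([og] + [", ".join(self.groups[og].get(sp, []))
                                for sp in species])
        pd.DataFrame(rows, columns=["Orthogroup"] + species).to_csv(
            path, sep="\t", index=False)


@dataclass
class ResolvedMap:
    """orthogroup -> species -> single representative gene, with provenance."""

    representative: dict[str, dict[str, str]]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def gene(self, og: str, sp: str) -> str:
        return self.representative[og][sp]

    def write_tsv(self, path) -> None:
        self.provenance.to_csv(path, sep="\t", index=False)


def filter_orthogroups(table: OrthologyTable, hard_max: int = 120,
                       soft_max: int = 80,
                       balance_ratio: float = 3.0) -> OrthologyTable:
    """Drop oversized and unbalanced orthogroups.

    Removes orthogroups with more than `hard_max` genes outright, and those
    with more than `soft_max` genes whose per-species representation is
    unbalanced (max / min-nonzero per-species gene count > `balance_ratio`).
    """
    kept = {}
    for og, by_sp in table.groups.items():
        total = sum(len(g) for g in by_sp.values())
        if total > hard_max:
            continue
        if total > soft_max:
            counts = [len(g) for g in by_sp.values() if g]
            if max(counts) / min(counts) > balance_ratio:
                continue
        kept[og] = by_sp
    return OrthologyTable(kept)


def pairwise_similarity(seqs: dict[str, str],
                        aligner: PairwiseAligner | None = None,
                        normalize: bool = True) -> pd.DataFrame:
    """Symmetric local-alignment similarity matrix over named sequences.

    With ``normalize`` (default), score(a, b) is divided by
    sqrt(score(a, a) * score(b, b)), mapping identical sequences to 1.0 and
    making scores comparable across sequence lengths.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    bad = [name for name, s in seqs.items()
           if not s or set(s) - VALID_RESIDUES]
    if bad:
        raise ValueError(f"invalid residues in sequence(s): {bad}")
    if aligner is None:
        aligner = make_aligner()
    names = list(seqs)
    n = len(names)
    S = np.zeros((n, n))
    self_scores = np.array([aligner.score(seqs[a], seqs[a]) for a in names])
    for i in range(n):
        S[i, i] = self_scores[i]
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = aligner.score(seqs[names[i]], seqs[names[j]])
    if normalize:
        denom = np.sqrt(np.outer(self_scores, self_scores))
        S = S / denom
    return pd.DataFrame(S, index=names, columns=names)


def best_ancestral_orthologue(group_seqs: dict[str, dict[str, str]],
                              aligner: PairwiseAligner | None = None,
                              normalize: bool = True) -> pd.DataFrame:
    """Pick each species' representative: the paralog most similar, on
    average, to all *other* species' sequences in the orthogroup.

    Ties break to the lexicographically smaller gene id.  Returns a frame
    with columns species, gene, score, margin (to the runner-up, NaN for
    singletons), n_candidates.
    """
    flat = {g: s for by_gene in group_seqs.values() for g, s in by_gene.items()}
    multi = any(len(by_gene) > 1 for by_gene in group_seqs.values())
    if len(group_seqs) < 2:
        raise ValueError("orthogroup must span at least 2 species")
    sim = (pairwise_similarity(flat, aligner, normalize)
           if multi or len(flat) > 1 else None)
    gene_species = {g: sp for sp, by_gene in group_seqs.items() for g in by_gene}
    rows = []
    for sp, by_gene in group_seqs.items():
        others = [g for g, s in gene_species.items() if s != sp]
        scored = []
        for g in sorted(by_gene):
            score = float(sim.loc[g, others].mean()) if others else np.nan
            scored.append((g, score))
        scored.sort(key=lambda t: (-t[1], t[0]))
        best, best_score = scored[0]
        margin = best_score - scored[1][1] if len(scored) > 1 else np.nan
        rows.append((sp, best, best_score, margin, len(scored)))
    return pd.DataFrame(rows, columns=["species", "gene", "score", "margin",
                                       "n_candidates"])


def resolve(table: OrthologyTable, seqs: dict[str, dict[str, str]],
            aligner: PairwiseAligner | None = None) -> ResolvedMap:
    """Resolve every orthogroup spanning >= 2 species to one gene per species.

    ``seqs[species][gene_id]`` supplies the protein sequences.  Orthogroups
    restricted to a single species are skipped (they cannot enter a
    cross-species comparison).
    """
    if aligner is None:
        aligner = make_aligner()
    rep: dict[str, dict[str, str]] = {}
    prov_rows = []
    for og in sorted(table.groups):
        by_sp = table.groups[og]
        present = {sp: g for sp, g in by_sp.items() if g}
        if len(present) < 2:
            continue
        if all(len(g) == 1 for g in present.values()):
            rep[og] = {sp: g[0] for sp, g in present.items()}
            for sp, g in present.items():
                prov_rows.append((og, sp, g[0], np.nan, np.nan, 1))
            continue
        group_seqs = {sp: {g: seqs[sp][g] for g in genes}
                      for sp, genes in present.items()}
        choice = best_ancestral_orthologue(group_seqs, aligner)
        rep[og] = dict(zip(choice["species"], choice["gene"]))
        for _, r in choice.iterrows():
            prov_rows.append((og, r["species"], r["gene"], r["score"],
                              r["margin"], r["n_candidates"]))
    prov = pd.DataFrame(prov_rows, columns=["orthogroup", "species", "gene",
                                            "score", "margin", "n_candidates"])
    return ResolvedMap(rep, prov)


def expand_tf_flags(gene_tf_flags: dict[str, bool] | set,
                    table: OrthologyTable) -> dict[str, bool]:
    """Orthogroup-level TF flags: an orthogroup is a TF orthogroup iff any
    member gene in any species is flagged.  Idempotent."""
    if isinstance(gene_tf_flags, set):
        flagged = gene_tf_flags
    else:
        flagged = {g for g, f in gene_tf_flags.items() if f}
    return {
        og: any(g in flagged for genes in by_sp.values() for g in genes)
        for og, by_sp in table.groups.items()
    }


def apply_overrides(table: OrthologyTable,
                    overrides: dict[str, dict[str, list[str]]],
                    ) -> OrthologyTable:
    """Replace manually curated orthogroups (Hox-style regrouping).

    `overrides` maps new orthogroup ids to species->gene lists.  Every
    source orthogroup containing any override gene is dissolved: its
    non-override genes are dropped with a warning (mirroring the discard of
    incoherent automatic groups), the override groups are added verbatim.
    A gene referenced by two override groups is an error.
    """
    seen: set[str] = set()
    override_genes: set[str] = set()
    for og, by_sp in overrides.items():
        for genes in by_sp.values():
            for g in genes:
                if g in seen:
                    raise ValueError(f"gene {g} appears twice in overrides")
                seen.add(g)
        override_genes |= {g for genes in by_sp.values() for g in genes}
    if not overrides:
        return OrthologyTable(dict(table.groups))
    kept: dict[str, dict[str, list[str]]] = {}
    dropped_extra = 0
    for og, by_sp in table.groups.items():
        members = {g for genes in by_sp.values() for g in genes}
        if members & override_genes:
            dropped_extra += len(members - override_genes)
            continue
        kept[og] = by_sp
    if dropped_extra:
        warnings.warn(
            f"{dropped_extra} gene(s) in dissolved orthogroups were not "
            "reassigned by the overrides and were dropped", stacklevel=2)
    for og, by_sp in overrides.items():
        kept[og] = {sp: list(genes) for sp, genes in by_sp.items() if genes}
    return OrthologyTable(kept)


@dataclass
class IntegratedMatrix:
    """Orthogroup x (species, segment) matrix of within-species z-scores.

    Rows are orthogroups expressed in every species; columns concatenate
    all species' segments, carrying (species, segment label, AP rank)
    metadata.  Each species' sub-block of a row inherits mean 0 / sd 1 from
    the per-species z-scoring.
    """

    values: pd.DataFrame
    col_meta: pd.DataFrame              # species, segment, ap_rank per column
    row_meta: pd.DataFrame              # tf_flag, override_flag per orthogroup

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.col_meta["species"]))

    def species_block(self, sp: str) -> pd.DataFrame:
        cols = self.col_meta.index[self.col_meta["species"] == sp]
        return self.values[cols]

    def subset(self, orthogroups) -> "IntegratedMatrix":
        ogs = [og for og in orthogroups if og in self.values.index]
        return IntegratedMatrix(self.values.loc[ogs], self.col_meta,
                                self.row_meta.loc[ogs])

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def integrate(zscored: dict[str, "object"], resolved: ResolvedMap,
              tf_flags: dict[str, bool] | None = None,
              override_ids: set[str] | None = None) -> IntegratedMatrix:
    """Build the cross-species integrated matrix from z-scored datasets.

    An orthogroup enters iff its representative gene survived expression
    filtering in *every* species present in `zscored` (datasets at stage
    ``zscored``, one per species, as produced by the preprocess chain).
    """
    species = sorted(zscored)
    missing = [sp for sp in species
               if not any(sp in by_sp for by_sp in
                          resolved.representative.values())]
    if missing:
        raise ValueError(f"species missing from resolved map: {missing}")
    col_meta_parts, block_cols = [], {}
    for sp in species:
        ds = zscored[sp]
        ds.require_stage("zscored")
        meta = ds.meta.sort_values("ap_rank")
        block_cols[sp] = list(meta.index)
        col_meta_parts.append(meta[["species", "segment", "ap_rank"]])
    col_meta = pd.concat(col_meta_parts)

    rows, kept_ogs = [], []
    for og in sorted(resolved.representative):
        by_sp = resolved.representative[og]
        if not all(sp in by_sp for sp in species):
            continue
        if not all(by_sp[sp] in zscored[sp].values.index for sp in species):
            continue
        parts = [zscored[sp].values.loc[by_sp[sp], block_cols[sp]]
                 for sp in species]
        rows.append(np.concatenate([p.to_numpy(float) for p in parts]))
        kept_ogs.append(og)
    values = pd.DataFrame(rows, index=kept_ogs, columns=col_meta.index)
    row_meta = pd.DataFrame({
        "tf_flag": [bool(tf_flags.get(og, False)) if tf_flags else False
                    for og in kept_ogs],
        "override_flag": [og in (override_ids or set()) for og in kept_ogs],
    }, index=kept_ogs)
    return IntegratedMatrix(values, col_meta, row_meta)
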