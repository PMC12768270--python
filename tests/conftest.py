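import numpy as np
import pandas as pd
import pytest

from gutmap.dataset import ExpressionDataset
from gutmap.synthetic import SyntheticConfig, generate, make_profiles
from gutmap.ortho import IntegratedMatrix


SMALL_MODULES = [
    ("M1", 0.05, 0.15, 20, 0.05),
    ("M2", 0.30, 0.15, 20, 0.05),
    ("M3", 0.55, 0.15, 20, 0.05),
    ("M4", 0.75, 0.15, 20, 0.05),
    ("M5", 0.95, 0.15, 20, 0.05),
]


def small_config(seed=0, **overrides):
    kwargs = dict(
        n_species=3,
        segments_per_species=(8, 8, 8),
        replicates=3,
        n_orthogroups=200,
        module_spec=[("M1", 0.05, 0.15, 10, 0.03),
                     ("M2", 0.30, 0.15, 10, 0.03),
                     ("M3", 0.55, 0.15, 10, 0.03),
                     ("M4", 0.75, 0.15, 10, 0.03),
                     ("M5", 0.95, 0.15, 10, 0.03)],
        paralog_rate=0.15,
        seq_len=80,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def small_generated():
    """One generated small dataset shared across tests (read-only)."""
    return generate(small_config(seed=7))


@pytest.fixture()
def toy_dataset():
    """3 genes x 6 samples (2 segments x 3 replicates), hand-friendly counts."""
    counts = pd.DataFrame(
        [[12, 11, 10, 0, 0, 0],
         [9, 9, 9, 9, 9, 9],
         [0, 0, 0, 0, 0, 0]],
        index=["g1", "g2", "g3"],
        columns=[f"s{i}" for i in range(6)],
    )
    meta = pd.DataFrame({
        "species": "spX",
        "segment": ["segA"] * 3 + ["segB"] * 3,
        "ap_rank": [1] * 3 + [2] * 3,
        "replicate": ["r1", "r2", "r3"] * 2,
    }, index=counts.columns)
    return ExpressionDataset(counts, meta, stage="raw")


def integrated_from_counts(seed=0, **overrides):
    """IntegratedMatrix built from generated counts via the preprocess chain.

    Genes are mapped 1-1 to orthogroups (no paralogs), bypassing sequence
    resolution for speed; this is the count-noise regime the generator's
    defaults define.
    """
    from gutmap.preprocess import run_preprocess

    cfg = small_config(seed=seed, paralog_rate=0.0, **overrides)
    profiles, truth = __import__("gutmap.synthetic", fromlist=["x"]) \
        .make_profiles(cfg)
    from gutmap.synthetic import sample_counts
    datasets = sample_counts(profiles, cfg, truth=truth)
    blocks, col_meta_parts = [], []
    row_sets = []
    zscored = {}
    for ds in datasets:
        _, z = run_preprocess(ds)
        zscored[ds.species] = z
        row_sets.append({g.split("_", 1)[1] for g in z.values.index})
    common = sorted(set.intersection(*row_sets))
    cols, meta = [], []
    for sp in cfg.species_ids:
        z = zscored[sp]
        m = z.meta.sort_values("ap_rank")
        sub = z.values.loc[[f"{sp}_{og}" for og in common], m.index]
        blocks.append(sub.to_numpy())
        for _, row in m.iterrows():
            cols.append(f"{sp}_{row['segment']}")
            meta.append((sp, row["segment"], int(row["ap_rank"])))
    values = pd.DataFrame(np.hstack(blocks), index=common, columns=cols)
    col_meta = pd.DataFrame(meta, index=cols,
                            columns=["species", "segment", "ap_rank"])
    row_meta = pd.DataFrame({
        "tf_flag": [truth.tf_flag[og] for og in common],
        "override_flag": False,
    }, index=common)
    return IntegratedMatrix(values, col_meta, row_meta), truth


def profile_matrix(seed=0, jitter=0.05, noise=0.5, n_per_module=20,
                   n_species=3, n_segments=8, extra_archetypes=False):
    """Z-scored noiseless profiles + N(0, noise) as an IntegratedMatrix.

    Bypasses the count layer: the planted mean profiles are z-scored per
    species and perturbed with additive Gaussian noise, the scale on which
    downstream recovery guarantees are stated.
    """
    kwargs = dict(
        n_species=n_species,
        segments_per_species=(n_segments,) * n_species,
        n_orthogroups=(n_per_module * 5 if not extra_archetypes
                       else n_per_module * 5 + 60),
        module_spec=[(m, c, 0.15, n_per_module, jitter)
                     for m, c, *_ in SMALL_MODULES],
        frac_block=0.0 if not extra_archetypes else 0.1,
        frac_gradient=0.0 if not extra_archetypes else 0.1,
        frac_terminal=0.0,
        seed=seed,
    )
    cfg = SyntheticConfig(**kwargs)
    profiles, truth = make_profiles(cfg)
    rng = np.random.default_rng(seed + 5000)
    blocks, cols, meta = [], [], []
    for sp in cfg.species_ids:
        P = profiles[sp].to_numpy()
        sd = P.std(1, ddof=1, keepdims=True)
        z = np.where(sd > 0, (P - P.mean(1, keepdims=True)) /
                     np.where(sd > 0, sd, 1.0), 0.0)
        blocks.append(z + rng.normal(0.0, noise, z.shape))
        for j in range(P.shape[1]):
            cols.append(f"{sp}_seg{j + 1}")
            meta.append((sp, f"seg{j + 1}", j + 1))
    ogs = sorted(truth.archetype)
    values = pd.DataFrame(np.hstack(blocks), index=ogs, columns=cols)
    col_meta = pd.DataFrame(meta, index=cols,
                            columns=["species", "segment", "ap_rank"])
    row_meta = pd.DataFrame({"tf_flag": False, "override_flag": False},
                            index=ogs)
    return IntegratedMatrix(values, col_meta, row_meta), truth
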