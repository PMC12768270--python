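"""Per-species count preprocessing.

Stages, in order: low-expression filtering on raw counts, library-size
normalization to log2(CPM + 1), removal of replicate batch effects by linear
residualization, replicate collapsing to one column per segment, and row-wise
z-scoring.  Variance-based gene selection (`top_variant`) operates on
segment-level (pre-z-score) values.

The batch-removal step mirrors the removeBatchEffect contract: segment
effects are kept in the model while sum-to-zero-coded batch effects are
estimated jointly and subtracted, so planted additive batch offsets are
removed exactly and gene means are preserved.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset


def filter_low_expression(ds: ExpressionDataset, min_count: int = 10,
                          min_samples: int | None = None) -> ExpressionDataset:
    """Keep genes with >= `min_count` raw counts in >= `min_samples` samples.

    `min_samples` defaults to the number of replicates, the convention of
    requiring detection in at least one full replicate's worth of samples.
    Gene order is preserved.
    """
    ds.require_stage("raw")
    if min_samples is None:
        min_samples = ds.n_replicates
    if min_samples > ds.values.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    keep = (ds.values >= min_count).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return ds.advance(ds.values.loc[keep], "filtered")


def normalize(ds: ExpressionDataset, method: str = "log2cpm") -> ExpressionDataset:
    """Library-size normalization.

    ``log2cpm`` (default): log2(CPM + 1) per sample.  ``sqrtcpm``: a
    mean-variance-flattening alternative, sqrt(CPM) (Anscombe-style square
    root anchoring the variance of count-like data).  Both are monotone in
    counts within a sample.
    """
    ds.require_stage("filtered")
    libsize = ds.values.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {list(zero.index)}")
    cpm = ds.values / libsize * 1e6
    if method == "log2cpm":
        vals = np.log2(cpm + 1.0)
    elif method == "sqrtcpm":
        vals = np.sqrt(cpm)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return ds.advance(vals, "normalized")


def _design(labels: pd.Series) -> np.ndarray:
    """Full-rank indicator design (drop-first dummy coding)."""
    levels = sorted(labels.unique())
    return np.column_stack([
        (labels == lv).to_numpy(float) for lv in levels[1:]
    ]) if len(levels) > 1 else np.empty((len(labels), 0))


def remove_batch(ds: ExpressionDataset,
                 batch: pd.Series | None = None) -> ExpressionDataset:
    """Subtract per-gene least-squares batch effects, keeping segment effects.

    Fits value ~ intercept + segment + batch (batch sum-to-zero coded) per
    gene and subtracts the fitted batch component.  With a single batch
    level this is the identity.  Raises if batch is confounded with segment
    (joint design not full rank).
    """
    ds.require_stage("normalized")
    if batch is None:
        batch = ds.meta["replicate"]
    levels = sorted(batch.unique())
    if len(levels) < 2:
        return ds.advance(ds.values.copy(), "batch_removed")
    seg = _design(ds.meta["segment"])
    # sum-to-zero coding: last level = -(sum of others), so the subtracted
    # batch term has zero mean over balanced designs and gene means survive
    B = np.column_stack([
        (batch == lv).to_numpy(float) - (batch == levels[-1]).to_numpy(float)
        for lv in levels[:-1]
    ])
    X = np.column_stack([np.ones(len(batch)), seg, B])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("batch is confounded with segment; cannot remove")
    Y = ds.values.to_numpy().T            # samples x genes
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    batch_coef = coef[1 + seg.shape[1]:]
    corrected = (Y - B @ batch_coef).T
    return ds.advance(pd.DataFrame(corrected, index=ds.values.index,
                                   columns=ds.values.columns), "batch_removed")


def collapse_replicates(ds: ExpressionDataset) -> ExpressionDataset:
    """One column per segment: mean over replicates, AP order preserved."""
    ds.require_stage("batch_removed")
    meta = ds.meta.sort_values("ap_rank")
    segs = meta.drop_duplicates("segment")
    cols, data = [], []
    for _, row in segs.iterrows():
        samples = ds.meta.index[ds.meta["segment"] == row["segment"]]
        cols.append(f"{row['species']}_{row['segment']}")
        data.append(ds.values[samples].mean(axis=1))
    values = pd.concat(data, axis=1)
    values.columns = cols
    new_meta = pd.DataFrame({
        "species": segs["species"].to_numpy(),
        "segment": segs["segment"].to_numpy(),
        "ap_rank": segs["ap_rank"].to_numpy(),
        "replicate": "pooled",
    }, index=cols)
    return ds.advance(values, "segment_level", meta=new_meta)


def zscore_rows(ds: ExpressionDataset, ddof: int = 1) -> ExpressionDataset:
    """Row z-scores: (value - row mean) / row sd (sample sd by default).

    Constant rows become all-zero and are recorded in
    ``flags['constant_rows']``.
    """
    ds.require_stage("segment_level")
    arr = ds.values.to_numpy(float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd[constant] = 1.0
    z = (arr - mean) / sd
    z[constant] = 0.0
    return ds.advance(
        pd.DataFrame(z, index=ds.values.index, columns=ds.values.columns),
        "zscored",
        constant_rows=list(ds.values.index[constant]),
    )


def top_variant(ds: ExpressionDataset, k: int = 2000) -> ExpressionDataset:
    """The k genes of highest across-segment variance (pre-z-score values).

    Ties are broken by gene id lexicographic order (smaller id ranks
    first).  Returns a dataset at the same stage with the selected genes in
    variance order.
    """
    ds.require_stage("segment_level", "zscored")
    if ds.stage == "zscored":
        source = ds.flags.get("variance_source")
        if source is None:
            raise ValueError(
                "top_variant on z-scored data needs pre-z-score values; "
                "call it at segment_level or store flags['variance_source']")
        var = source
    else:
        var = ds.values.var(axis=1, ddof=1)
    if k > len(var):
        warnings.warn(f"k={k} exceeds {len(var)} genes; keeping all",
                      stacklevel=2)
        k = len(var)
    ranked = var.to_frame("var").assign(gene=var.index)
    ranked = ranked.sort_values(["var", "gene"], ascending=[False, True])
    keep = ranked.index[:k]
    out = ds.copy()
    out.values = ds.values.loc[keep]
    return out


def run_preprocess(ds: ExpressionDataset, min_count: int = 10,
                   min_samples: int | None = None,
                   method: str = "log2cpm", ddof: int = 1,
                   ) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Full per-species chain; returns (segment_level, zscored) datasets."""
    ds = filter_low_expression(ds, min_count=min_count, min_samples=min_samples)
    ds = normalize(ds, method=method)
    ds = remove_batch(ds)
    seg = collapse_replicates(ds)
    return seg, zscore_rows(seg, ddof=ddof)
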