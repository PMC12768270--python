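"""Core data container for one species' segment-resolved expression data.

An :class:`ExpressionDataset` holds a gene x sample matrix together with the
sample metadata (species, anatomical segment label, 1-based anteroposterior
rank, replicate/batch id) and a *stage* tag recording where in the
preprocessing pipeline the values currently sit.  Stages advance strictly in
the order ``raw -> filtered -> normalized -> batch_removed -> segment_level
-> zscored``; each preprocessing operation checks the tag of its input, which
makes accidental double-processing (e.g. z-scoring twice) a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STAGES = (
    "raw",
    "filtered",
    "normalized",
    "batch_removed",
    "segment_level",
    "zscored",
)

#: metadata columns every dataset must carry
META_COLUMNS = ("species", "segment", "ap_rank", "replicate")


class StageError(RuntimeError):
    """Raised when an operation is applied to a dataset at the wrong stage."""


@dataclass
class ExpressionDataset:
    """One species' expression matrix plus sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes (rows, indexed by gene id) x samples (columns).  Raw counts at
        stage ``raw``; transformed values afterwards.
    meta : pandas.DataFrame
        One row per sample (index matches ``values.columns``) with columns
        ``species``, ``segment``, ``ap_rank`` (1-based integer along the gut
        tube), ``replicate``.
    stage : str
        Current pipeline stage.
    flags : dict
        Free-form per-gene annotations (e.g. genes whose z-score row was
        constant and therefore zeroed).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    stage: str = "raw"
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("sample columns and metadata index do not match")
        species = self.meta["species"].unique()
        if len(species) != 1:
            raise ValueError("a dataset must contain exactly one species")
        self._check_ap_ranks()

    def _check_ap_ranks(self) -> None:
        ranks = sorted(self.meta["ap_rank"].unique())
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(
                f"AP ranks must be contiguous 1..n, got {ranks}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def species(self) -> str:
        return str(self.meta["species"].iloc[0])

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_segments(self) -> int:
        return int(self.meta["ap_rank"].nunique())

    @property
    def n_replicates(self) -> int:
        return int(self.meta["replicate"].nunique())

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"operation requires stage in {allowed}, dataset is at "
                f"{self.stage!r}"
            )

    def advance(self, values: pd.DataFrame, stage: str,
                meta: pd.DataFrame | None = None, **flags) -> "ExpressionDataset":
        """Return a new dataset at `stage` carrying `values` (and new flags)."""
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise StageError(
                f"cannot move from {self.stage!r} to earlier/equal stage {stage!r}"
            )
        new_flags = dict(self.flags)
        new_flags.update(flags)
        return replace(self, values=values, stage=stage,
                       meta=self.meta if meta is None else meta,
                       flags=new_flags)

    def segment_order(self) -> pd.Index:
        """Sample (or segment) columns sorted by AP rank, stable in replicate."""
        order = self.meta.sort_values(["ap_rank", "replicate"]).index
        return pd.Index(order)

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(self.values.copy(), self.meta.copy(),
                                 self.stage, dict(self.flags))


def concat_loggable(ds: ExpressionDataset) -> str:
    """One-line description used by the pipeline log."""
    return (f"{ds.species}: {ds.values.shape[0]} genes x "
            f"{ds.values.shape[1]} samples [{ds.stage}]")


def validate_counts(values: pd.DataFrame) -> None:
    """Raise if a raw count matrix contains negatives or non-finite entries."""
    arr = values.to_numpy()
    if not np.isfinite(arr).all():
        raise ValueError("count matrix contains non-finite values")
    if (arr < 0).any():
        raise ValueError("count matrix contains negative values")
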