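"""AP-association screening and terminal-marker classification.

For each orthogroup and species, the z-score profile over gut segments is
regressed on an orthogonal polynomial basis of AP rank (degree 3 by
default, reduced when a species has few segments) and tested against the
intercept-only model with an exact F-test.  Orthogroups significant (BH
q < threshold, adjusted within species) in *every* species are flagged
conserved AP-associated -- the cross-species intersection logic that, on
real data, narrows shared TF orthogroups down to the conserved AP set.

Terminal markers (genes peaking at a gut terminus) are classified per
species from the fitted trend: ``anterior`` / ``posterior`` if the primary
peak falls in the first / last tercile of AP ranks, ``both`` when a
secondary local maximum in the opposite tercile reaches at least half of
the primary amplitude above the profile mean, else ``internal``.  A gene is
a cross-species terminal marker when it is terminal in every species but
not pinned to the same single end everywhere -- the hallmark of markers
that are anterior in some species and posterior in others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TrendFit:
    """OLS fit of a segment profile on an orthogonal polynomial of AP rank."""

    F: float
    p: float
    r2: float
    fitted: np.ndarray
    degree: int


def _orth_poly(ranks: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis (excluding the constant column)."""
    x = np.asarray(ranks, float)
    V = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    return Q[:, 1:degree + 1]


def fit_ap_trend(profile: np.ndarray, ap_ranks: np.ndarray,
                 degree: int = 3) -> TrendFit:
    """F-test of a degree-`degree` polynomial AP trend against a flat model.

    The degree is reduced to n - 2 when fewer than degree + 2 segments are
    available.  A constant profile returns F = 0, p = 1.  The F statistic
    is invariant to affine transforms of the profile.
    """
    y = np.asarray(profile, float)
    x = np.asarray(ap_ranks, float)
    n = len(y)
    if n != len(x):
        raise ValueError("profile and ap_ranks differ in length")
    degree = min(degree, n - 2)
    if degree < 1:
        raise ValueError("need at least 3 segments to test a trend")
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst <= 0:
        return TrendFit(0.0, 1.0, 0.0, np.full(n, y.mean()), degree)
    B = _orth_poly(x, degree)
    coef = B.T @ yc                       # B orthonormal
    fitted = B @ coef + y.mean()
    ssr = float(coef @ coef)
    sse = max(sst - ssr, 0.0)
    df1, df2 = degree, n - degree - 1
    if df2 <= 0 or sse <= 0:
        return TrendFit(np.inf, 0.0, 1.0, fitted, degree)
    F = (ssr / df1) / (sse / df2)
    p = float(stats.f.sf(F, df1, df2))
    return TrendFit(float(F), p, ssr / sst, fitted, degree)


@dataclass
class APAssociationResult:
    """Per-orthogroup, per-species trend statistics and the conserved set."""

    stats: pd.DataFrame                # orthogroup x species multi-stat table
    conserved: pd.Series               # orthogroup -> bool
    terminal: pd.DataFrame             # orthogroup x species terminal labels
    cross_species_terminal: pd.Series  # orthogroup -> bool
    q_threshold: float
    min_species: int | None = None

    @property
    def conserved_set(self) -> list[str]:
        return sorted(self.conserved.index[self.conserved])

    @property
    def terminal_set(self) -> list[str]:
        return sorted(
            self.cross_species_terminal.index[self.cross_species_terminal])


def classify_terminal_profile(fitted: np.ndarray,
                              secondary_ratio: float = 0.5) -> str:
    """Terminal label of one species' fitted AP profile."""
    y = np.asarray(fitted, float)
    n = len(y)
    peak = int(np.argmax(y))
    third = n / 3.0
    tercile = 0 if peak < third else (2 if peak >= 2 * third else 1)
    amp = y[peak] - y.mean()
    if tercile == 1 or amp <= 0:
        return "internal"
    primary = "anterior" if tercile == 0 else "posterior"
    # local maxima strictly inside or at the ends
    opp = (np.arange(n) >= 2 * third) if primary == "anterior" \
        else (np.arange(n) < third)
    is_max = np.ones(n, bool)
    is_max[1:] &= y[1:] >= y[:-1]
    is_max[:-1] &= y[:-1] >= y[1:]
    cand = np.flatnonzero(opp & is_max)
    if cand.size and (y[cand].max() - y.mean()) >= secondary_ratio * amp:
        return "both"
    return primary


def screen_conserved(im, q_threshold: float = 0.05, degree: int = 3,
                     tf_only: bool = False, min_species: int | None = None,
                     secondary_ratio: float = 0.5) -> APAssociationResult:
    """Screen an IntegratedMatrix for conserved AP-associated orthogroups.

    BH adjustment is applied within each species across all tested
    orthogroups.  ``conserved`` requires q < `q_threshold` in every species
    (or in at least `min_species` when given).  With ``tf_only``, the screen
    is restricted to TF-flagged rows.
    """
    values = im.values
    if tf_only:
        values = values.loc[im.row_meta["tf_flag"]]
    species = im.species
    if len(values) == 0:
        raise ValueError("no orthogroups to screen")
    records = {}
    fitted_store: dict[str, dict[str, np.ndarray]] = {}
    for sp in species:
        cols = im.col_meta.index[im.col_meta["species"] == sp]
        ranks = im.col_meta.loc[cols, "ap_rank"].to_numpy(float)
        Fs, ps, r2s = [], [], []
        fitted_store[sp] = {}
        for og in values.index:
            fit = fit_ap_trend(values.loc[og, cols].to_numpy(float),
                               ranks, degree)
            Fs.append(fit.F)
            ps.append(fit.p)
            r2s.append(fit.r2)
            fitted_store[sp][og] = fit.fitted
        q = multipletests(ps, method="fdr_bh")[1]
        records[(sp, "F")] = Fs
        records[(sp, "p")] = ps
        records[(sp, "q")] = q
        records[(sp, "r2")] = r2s
    table = pd.DataFrame(records, index=values.index)
    table.columns = pd.MultiIndex.from_tuples(table.columns,
                                              names=["species", "stat"])
    sig = pd.DataFrame({sp: table[(sp, "q")] < q_threshold for sp in species})
    need = len(species) if min_species is None else min_species
    conserved = sig.sum(axis=1) >= need

    term = pd.DataFrame({
        sp: [classify_terminal_profile(fitted_store[sp][og], secondary_ratio)
             for og in values.index]
        for sp in species
    }, index=values.index)
    is_terminal = term.isin(["anterior", "posterior", "both"]).all(axis=1)
    same_single_end = term.apply(
        lambda row: len(set(row)) == 1 and row.iloc[0] in
        ("anterior", "posterior"), axis=1)
    cross_terminal = is_terminal & ~same_single_end

    return APAssociationResult(
        stats=table,
        conserved=conserved,
        terminal=term,
        cross_species_terminal=cross_terminal,
        q_threshold=q_threshold,
        min_species=min_species,
    )
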