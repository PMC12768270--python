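"""Conserved AP module extraction and positional placement.

Orthogroups in the conserved AP-associated set are correlated gene-to-gene
(Spearman, over all species' segments pooled), R2E-seriated, and cut into k
contiguous modules by seriation-guided agglomerative clustering.  k can be
fixed or chosen automatically as the maximizer of mean within-module
correlation minus mean between-adjacent-module correlation over k = 2..8.
Each module's per-species placement (segment of peak mean profile, its
compartment, and a deviation flag when a species' peak compartment departs
from the cross-species majority) summarizes anteriorisations and shifts of
the module along the gut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seriate import SeriationResult, seriate, constrained_cluster


@dataclass
class ModuleSet:
    """Contiguous modules along the gene seriation order."""

    modules: list[list[str]]             # member orthogroups per module
    order: SeriationResult               # gene seriation
    k: int
    quality: pd.Series                   # k -> selection criterion (auto mode)
    profiles: dict = field(default_factory=dict)  # module -> species -> mean z

    @property
    def membership(self) -> pd.Series:
        return pd.Series({og: m for m, members in enumerate(self.modules)
                          for og in members}, name="module")


def _gene_spearman(values: pd.DataFrame) -> np.ndarray:
    rho = stats.spearmanr(values.to_numpy(), axis=1).statistic
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 1.0)
    return rho


def _pooled_peaks(im, values: pd.DataFrame, smooth: int = 3) -> np.ndarray:
    """Per-gene relative AP peak position, averaged over species.

    Each species' profile is smoothed with a short moving average, and the
    argmax is refined by parabolic interpolation around the maximum so the
    estimate is not quantized to the segment grid (essential for species
    with only 6-10 segments).
    """
    kernel = np.ones(smooth) / smooth
    per_sp = []
    for sp in im.species:
        cols = im.col_meta.index[im.col_meta["species"] == sp]
        ranks = im.col_meta.loc[cols, "ap_rank"].to_numpy()
        order = np.argsort(ranks)
        block = values[cols].to_numpy(float)[:, order]
        n = block.shape[1]
        peaks = np.empty(len(block))
        for gi, row in enumerate(block):
            sm = np.convolve(row, kernel, mode="same")
            i = int(sm.argmax())
            x = float(i)
            if 0 < i < n - 1:
                denom = sm[i - 1] - 2 * sm[i] + sm[i + 1]
                if denom < 0:
                    x = i + 0.5 * (sm[i - 1] - sm[i + 1]) / denom
            peaks[gi] = x / max(n - 1, 1)
        per_sp.append(peaks)
    return np.mean(per_sp, axis=0)


def _auto_k(peaks: np.ndarray, k_range, seed: int = 0) -> int:
    """Module count by BIC of a 1-D Gaussian mixture on peak positions.

    Modules are positional clusters along the AP axis, so their count is
    the number of mixture components best supported by the pooled per-gene
    peak positions.  A contrast of within- vs between-module correlation
    is not usable for this: it is maximized by coarse 2-way splits
    whenever distant modules anticorrelate, which z-scored profiles
    guarantee.
    """
    from sklearn.mixture import GaussianMixture

    X = np.asarray(peaks, float).reshape(-1, 1)
    bic = {}
    for k in k_range:
        if k >= len(X):
            break
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=4)
        bic[k] = float(gm.fit(X).bic(X))
    if not bic:
        return min(k_range)
    return int(min(bic, key=bic.get))


def extract_modules(im, k: int | str = "auto", k_range=range(2, 9),
                    anchor=None) -> ModuleSet:
    """Cut the conserved AP set into contiguous modules along the seriation.

    `im` is an IntegratedMatrix restricted to the conserved AP-associated
    orthogroups (rows in any order; the result is order-invariant because
    correlation and seriation ignore input order up to the deterministic
    tie rules).
    """
    values = im.values.sort_index()      # input-order invariance
    ogs = list(values.index)
    if len(ogs) < 3:
        raise ValueError("need at least 3 orthogroups to extract modules")
    R = _gene_spearman(values)
    order = seriate(values.to_numpy(), axis="rows", item_ids=ogs,
                    anchor=anchor)
    peaks = _pooled_peaks(im, values)
    if k == "auto":
        usable = [kk for kk in k_range if 2 * kk <= len(ogs)]
        if not usable:
            raise ValueError("too few orthogroups for the auto-k range")
        k_use = _auto_k(peaks, usable)
        qs = pd.Series({k_use: 1.0})
    else:
        k_use = int(k)
        qs = pd.Series(dtype=float)
    blocks = constrained_cluster(order, R, k_use)
    modules = [[ogs[i] for i in b] for b in blocks]

    profiles: dict[int, dict[str, pd.Series]] = {}
    for m, members in enumerate(modules):
        profiles[m] = {}
        for sp in im.species:
            cols = im.col_meta.index[im.col_meta["species"] == sp]
            sub = values.loc[members, cols]
            prof = sub.mean(axis=0)
            prof.index = im.col_meta.loc[cols, "ap_rank"].to_numpy()
            profiles[m][sp] = prof

    ms = ModuleSet(modules=modules, order=order, k=k_use, quality=qs,
                   profiles=profiles)
    return _orient_ap(ms)


def _orient_ap(ms: ModuleSet) -> ModuleSet:
    """Order modules anterior->posterior (reverse if median peaks decrease)."""
    peaks = []
    for m in range(len(ms.modules)):
        ranks = [prof.index[np.argmax(prof.to_numpy())]
                 for prof in ms.profiles[m].values()]
        peaks.append(float(np.median(ranks)))
    if len(peaks) > 1 and peaks[0] > peaks[-1]:
        ms.modules = ms.modules[::-1]
        ms.profiles = {m: ms.profiles[len(ms.modules) - 1 - m]
                       for m in range(len(ms.modules))}
    return ms


def module_position(ms: ModuleSet, calls: dict) -> pd.DataFrame:
    """Per-module, per-species placement relative to compartment calls.

    `calls` maps species -> CompartmentCall.  Returns a table with the peak
    segment of the module's mean profile, the compartment containing it
    (anterior/posterior of that species' boundary), and a flag when the
    species' peak compartment deviates from the cross-species majority.
    """
    rows = []
    for m in range(len(ms.modules)):
        compartments = {}
        for sp, prof in ms.profiles[m].items():
            peak_rank = int(prof.index[np.argmax(prof.to_numpy())])
            comp = ("anterior" if peak_rank < calls[sp].boundary
                    else "posterior")
            compartments[sp] = (peak_rank, comp)
        comps = [c for _, c in compartments.values()]
        majority = max(set(comps), key=comps.count)
        for sp, (peak_rank, comp) in compartments.items():
            rows.append({
                "module": m,
                "species": sp,
                "peak_rank": peak_rank,
                "compartment": comp,
                "majority_compartment": majority,
                "deviates": comp != majority,
            })
    return pd.DataFrame(rows)
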