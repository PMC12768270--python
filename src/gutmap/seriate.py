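"""Rank-2 Elliptical (R2E) seriation and seriation-guided clustering.

R2E orders the items of a Robinson-structured similarity matrix (one whose
values decay monotonically away from the diagonal under the correct
ordering) by a simple fixed point of the Pearson correlation operator:
starting from the item correlation matrix, repeatedly take the correlation
matrix *of the correlation matrix's rows* until the effective rank drops to
2.  The left singular vectors of the resulting matrix lie on an ellipse in a
two-dimensional subspace; their angular position along that ellipse is the
seriation.  The linear order is cut at the largest angular gap, and its
direction fixed either by an anchor item (forced into the first half) or by
a deterministic lexicographic rule, so reruns are reproducible without
manual inspection.

The effective rank of a matrix is the number of eigenvalues above a small
threshold, exp(-13) by default (1e-13 is available for callers who prefer a
decimal cutoff); on expression data a handful of iterations suffices to
reach rank 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default eigenvalue cutoff for the effective rank (natural exponent)
RANK_THRESHOLD = float(np.exp(-13.0))


class SeriationError(RuntimeError):
    pass


@dataclass
class SeriationResult:
    """Outcome of an R2E seriation.

    Attributes
    ----------
    permutation : list[int]
        0-based index order of the items.
    item_ids : list
        Item identifiers in original input order.
    angles : numpy.ndarray
        Per-item ellipse angle (radians, in input order).
    iterations_used : int
        Correlation iterations performed before reaching rank <= 2.
    rank_trajectory : list[int]
        Effective rank after each iteration (element 0 = starting matrix).
    start_gap : float
        Size (radians) of the largest angular gap, where the order is cut.
    direction : int
        +1 if the angular order was kept, -1 if reversed.
    anchor_used : item id or None
    """

    permutation: list[int]
    item_ids: list
    angles: np.ndarray
    iterations_used: int
    rank_trajectory: list[int]
    start_gap: float
    direction: int
    anchor_used: object = None

    @property
    def ordered_ids(self) -> list:
        return [self.item_ids[i] for i in self.permutation]

    def rank_of(self) -> dict:
        """item id -> position in the seriation order."""
        return {self.item_ids[i]: pos for pos, i in enumerate(self.permutation)}


def effective_rank(M: np.ndarray, threshold: float = RANK_THRESHOLD) -> int:
    """Number of eigenvalues of the symmetric matrix `M` above `threshold`."""
    M = np.asarray(M, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise SeriationError("effective_rank requires a square matrix")
    if not np.allclose(M, M.T, atol=1e-8):
        raise SeriationError("matrix is not symmetric")
    if threshold <= 0:
        raise SeriationError("threshold must be positive")
    eig = np.linalg.eigvalsh((M + M.T) / 2.0)
    return int((eig > threshold).sum())


def _corr_rows(X: np.ndarray, iteration: int) -> np.ndarray:
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise SeriationError(
            f"constant row(s) {bad.tolist()} at correlation iteration {iteration}")
    return np.corrcoef(X)


def iterate_correlation(X: np.ndarray, threshold: float = RANK_THRESHOLD,
                        max_iter: int = 50) -> tuple[np.ndarray, list[int]]:
    """Iterate R -> corr(rows of R) from corr(rows of X) until rank <= 2.

    Returns the first matrix of effective rank <= 2 and the rank
    trajectory (rank after 0, 1, ... iterations).  Items are rows of `X`.
    """
    X = np.asarray(X, float)
    if X.shape[0] < 3:
        raise SeriationError("need at least 3 items to seriate")
    R = _corr_rows(X, 0)
    trajectory = [effective_rank(R, threshold)]
    it = 0
    while trajectory[-1] > 2:
        if it >= max_iter:
            raise SeriationError(
                f"rank did not reach 2 within {max_iter} iterations; "
                f"trajectory={trajectory}")
        it += 1
        R = _corr_rows(R, it)
        trajectory.append(effective_rank(R, threshold))
    return R, trajectory


def elliptical_order(R2: np.ndarray, item_ids=None, anchor=None,
                     threshold: float = RANK_THRESHOLD,
                     iterations_used: int = 0,
                     rank_trajectory: list[int] | None = None,
                     ) -> SeriationResult:
    """Order items by angular position of their rank-2 left singular vectors.

    The sorted angles are cut at the largest circular gap (the series starts
    immediately after it).  Direction: if `anchor` is given, it is forced
    into the first half of the order; otherwise the order whose first item
    id is lexicographically smaller than its last is chosen.
    """
    R2 = np.asarray(R2, float)
    n = R2.shape[0]
    if item_ids is None:
        item_ids = list(range(n))
    item_ids = list(item_ids)
    if effective_rank(R2, threshold) > 2:
        raise SeriationError(
            "input has effective rank > 2; run iterate_correlation first")
    U, _, _ = np.linalg.svd(R2)
    angles = np.arctan2(U[:, 1], U[:, 0])
    order = np.argsort(angles, kind="stable")
    sorted_ang = angles[order]
    gaps = np.diff(np.append(sorted_ang, sorted_ang[0] + 2 * np.pi))
    cut = int(np.argmax(gaps))          # gap between sorted[cut] and sorted[cut+1]
    start_gap = float(gaps[cut])
    perm = np.roll(order, -(cut + 1))   # series starts just after the gap

    direction = 1
    if anchor is not None:
        if anchor not in item_ids:
            raise SeriationError(f"anchor {anchor!r} not among items")
        pos = list(perm).index(item_ids.index(anchor))
        if pos >= (n + 1) // 2:
            perm, direction = perm[::-1], -1
    else:
        if str(item_ids[perm[0]]) > str(item_ids[perm[-1]]):
            perm, direction = perm[::-1], -1

    return SeriationResult(
        permutation=[int(i) for i in perm],
        item_ids=item_ids,
        angles=angles,
        iterations_used=iterations_used,
        rank_trajectory=rank_trajectory or [2],
        start_gap=start_gap,
        direction=direction,
        anchor_used=anchor,
    )


def seriate(X: np.ndarray, axis: str = "rows", item_ids=None, anchor=None,
            threshold: float = RANK_THRESHOLD, max_iter: int = 50,
            ) -> SeriationResult:
    """Full R2E seriation of the rows (or columns) of a data matrix."""
    X = np.asarray(X, float)
    if axis == "columns":
        X = X.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    R2, trajectory = iterate_correlation(X, threshold, max_iter)
    return elliptical_order(R2, item_ids=item_ids, anchor=anchor,
                            threshold=threshold,
                            iterations_used=len(trajectory) - 1,
                            rank_trajectory=trajectory)


def constrained_cluster(order: SeriationResult | list[int], D: np.ndarray,
                        k: int) -> list[list[int]]:
    """Partition the seriation order into k contiguous blocks.

    Agglomerative average-linkage merging restricted to adjacent blocks
    along the seriation order; distance = 1 - correlation.  Returns blocks
    as lists of original item indices, in seriation order.
    """
    perm = order.permutation if isinstance(order, SeriationResult) else list(order)
    n = len(perm)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError("k exceeds the number of items")
    D = np.asarray(D, float)
    dist = 1.0 - D
    blocks = [[i] for i in perm]
    while len(blocks) > k:
        costs = [
            float(dist[np.ix_(blocks[b], blocks[b + 1])].mean())
            for b in range(len(blocks) - 1)
        ]
        b = int(np.argmin(costs))
        blocks[b:b + 2] = [blocks[b] + blocks[b + 1]]
    return blocks


@dataclass
class GAPBundle:
    """Generalized Association Plot: the three matrices of Fig-style summaries
    (segment correlations, item correlations, expression) under consistent
    seriation orderings."""

    segment_corr: np.ndarray
    item_corr: np.ndarray
    expression: np.ndarray
    item_order: SeriationResult
    segment_order: SeriationResult
    item_ids: list = field(default_factory=list)
    segment_ids: list = field(default_factory=list)


def build_gap(expression: np.ndarray, item_corr: np.ndarray,
              segment_corr: np.ndarray, item_order: SeriationResult,
              segment_order: SeriationResult,
              item_ids=None, segment_ids=None) -> GAPBundle:
    """Package expression + correlation matrices under the two seriation orders.

    Performs no new computation; matrices are permuted copies consistent
    with the supplied orderings.
    """
    expression = np.asarray(expression, float)
    ip = np.asarray(item_order.permutation)
    sp = np.asarray(segment_order.permutation)
    if expression.shape != (len(ip), len(sp)):
        raise ValueError("expression shape does not match the two orderings")
    if np.asarray(item_corr).shape != (len(ip), len(ip)):
        raise ValueError("item correlation matrix does not conform")
    if np.asarray(segment_corr).shape != (len(sp), len(sp)):
        raise ValueError("segment correlation matrix does not conform")
    return GAPBundle(
        segment_corr=np.asarray(segment_corr)[np.ix_(sp, sp)],
        item_corr=np.asarray(item_corr)[np.ix_(ip, ip)],
        expression=expression[np.ix_(ip, sp)],
        item_order=item_order,
        segment_order=segment_order,
        item_ids=item_order.ordered_ids,
        segment_ids=segment_order.ordered_ids,
    )
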