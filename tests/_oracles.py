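"""Independent oracles shared by the unit and acceptance tests.

These deliberately avoid the package's own code paths: Robinson violations
are counted directly from the permuted matrix, and the full-enumeration
oracle scores every permutation of the items.
"""

import itertools

import numpy as np


def robinson_correlation(n, rng, decay_low=0.15, decay_high=0.6):
    """Random perfect Robinson correlation matrix (similarity decays with
    band distance, random per-offset decrements)."""
    steps = rng.uniform(decay_low, decay_high, n - 1)
    levels = np.concatenate([[1.0], 1.0 - np.cumsum(steps) / steps.sum()])
    levels = 1.0 - (1.0 - levels) * rng.uniform(0.9, 1.0)
    R = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            R[i, j] = levels[abs(i - j)]
    return R


def robinson_violations(M, perm):
    """Robinson monotonicity violations of similarity matrix M under perm."""
    P = M[np.ix_(list(perm), list(perm))]
    n = len(perm)
    v = 0
    for i in range(n):
        row = P[i]
        v += int((np.diff(row[i:]) > 1e-12).sum())
        v += int((np.diff(row[:i + 1]) < -1e-12).sum())
    return v


def all_permutations(n):
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def violations_all_perms(M, perms):
    """Vectorized Robinson-violation counts for every permutation.

    Returns an integer array of shape (n_perms,).
    """
    n = M.shape[0]
    P = M[perms[:, :, None], perms[:, None, :]]      # (n_perms, n, n)
    D = np.diff(P, axis=2)                           # along each row
    cols = np.arange(n - 1)
    viol = np.zeros(len(perms), dtype=np.int64)
    for i in range(n):
        right = cols >= i       # D[:, i, j] spans P[i, j] -> P[i, j+1]
        left = cols < i
        viol += (D[:, i, right] > 1e-12).sum(axis=1)
        viol += (D[:, i, left] < -1e-12).sum(axis=1)
    return viol
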