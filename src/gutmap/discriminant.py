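"""Sparse partial least squares discriminant analysis (sPLS-DA), from
first principles.

Given an integrated z-score matrix X (features x samples) and a class label
per sample (an imputed segment-identity grouping), each component extracts a
feature weight vector maximizing covariance between feature scores and the
one-hot class indicators, hard-thresholded to the top `keepX` entries by
absolute weight (the lasso-style keepX semantics of the mixOmics family),
then deflates X against the component scores.  Samples are classified by
the nearest class centroid in component-score space.

The "optimal sufficient discriminant set" is chosen by cross-validation:
leave-one-species-out by default (samples within a species are not
exchangeable), falling back to stratified k-fold when fewer than two
species are present; the chosen keepX is the smallest whose balanced error
is within a tolerance of the minimum over the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DiscriminantModel:
    """Fitted sPLS-DA model.

    ``weights`` is features x ncomp (each column: exactly keepX nonzeros,
    unit norm); ``scores`` is samples x ncomp; ``centroids`` maps class ->
    centroid in score space.
    """

    weights: pd.DataFrame
    scores: pd.DataFrame
    centroids: pd.DataFrame
    keepX: list[int]
    classes: list
    feature_ids: list
    selected: list[list[str]] = field(default_factory=list)
    optimal_keepX: int | None = None
    cv_errors: pd.Series | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new feature x sample data onto the component space."""
        return np.asarray(X, float).T @ self.weights.to_numpy()

    def predict(self, X: np.ndarray) -> np.ndarray:
        T = self.transform(X)
        C = self.centroids.to_numpy()
        d = ((T[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        return np.asarray(self.classes, object)[d.argmin(axis=1)]


def _one_hot(y) -> tuple[np.ndarray, list]:
    classes = sorted(set(y))
    Y = np.column_stack([(np.asarray(y) == c).astype(float) for c in classes])
    return Y, classes


def _sparse_weight(Xc: np.ndarray, Yc: np.ndarray, keepX: int) -> np.ndarray:
    """Top keepX-sparse unit covariance direction: first left singular
    vector of Xc @ Yc, hard-thresholded and renormalized."""
    M = Xc @ Yc
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    w = U[:, 0]
    if keepX < 1:
        raise ValueError("keepX must be >= 1")
    if keepX < len(w):
        cut = np.argsort(np.abs(w))[:-keepX]
        w = w.copy()
        w[cut] = 0.0
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate component: all weights thresholded away")
    return w / norm


def fit_splsda(X: pd.DataFrame | np.ndarray, y, keepX: int | list[int],
               ncomp: int = 2) -> DiscriminantModel:
    """Fit an sPLS-DA model on X (features x samples) and labels y.

    `keepX` is the number of features retained per component (scalar or
    one value per component); values above the feature count are clipped
    with a warning.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.index)
        sample_ids = list(X.columns)
        Xa = X.to_numpy(float)
    else:
        Xa = np.asarray(X, float)
        feature_ids = list(range(Xa.shape[0]))
        sample_ids = list(range(Xa.shape[1]))
    y = np.asarray(y)
    if len(y) != Xa.shape[1]:
        raise ValueError("labels do not match sample count")
    Y, classes = _one_hot(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if min(np.bincount([classes.index(c) for c in y])) < 2:
        raise ValueError("every class needs at least 2 samples")
    p, n = Xa.shape
    keep = list(keepX) if isinstance(keepX, (list, tuple)) else [keepX] * ncomp
    if len(keep) != ncomp:
        raise ValueError("keepX must have one value per component")
    keep = [min(k, p) for k in keep]
    if any(k > p for k in (keepX if isinstance(keepX, (list, tuple))
                           else [keepX])):
        warnings.warn("keepX exceeds the feature count; clipped", stacklevel=2)

    Xc = Xa - Xa.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    W = np.zeros((p, ncomp))
    T = np.zeros((n, ncomp))
    Xd = Xc.copy()
    for c in range(ncomp):
        w = _sparse_weight(Xd, Yc, keep[c])
        t = Xd.T @ w
        W[:, c] = w
        T[:, c] = t
        denom = float(t @ t)
        if denom > 0:
            loadings = Xd @ t / denom
            Xd = Xd - np.outer(loadings, t)

    comp_names = [f"comp{c + 1}" for c in range(ncomp)]
    scores = pd.DataFrame(T, index=sample_ids, columns=comp_names)
    centroids = pd.DataFrame(
        [T[np.asarray(y) == cls].mean(axis=0) for cls in classes],
        index=classes, columns=comp_names)
    weights = pd.DataFrame(W, index=feature_ids, columns=comp_names)
    selected = [[feature_ids[i] for i in np.flatnonzero(W[:, c])]
                for c in range(ncomp)]
    return DiscriminantModel(
        weights=weights, scores=scores, centroids=centroids, keepX=keep,
        classes=classes, feature_ids=feature_ids, selected=selected)


def _balanced_error(y_true: np.ndarray, y_pred: np.ndarray, classes) -> float:
    errs = []
    for c in classes:
        mask = y_true == c
        if mask.any():
            errs.append(float((y_pred[mask] != c).mean()))
    return float(np.mean(errs))


def cv_select_keepX(X: pd.DataFrame, y, grid, species=None, ncomp: int = 1,
                    tolerance: float = 0.02, n_folds: int = 5,
                    seed: int = 0) -> tuple[int, pd.Series]:
    """Choose keepX by cross-validated balanced classification error.

    Folds are leave-one-species-out when a `species` label per sample is
    given with >= 2 species; otherwise a seeded stratified k-fold is used
    (with a warning).  Returns the smallest keepX whose error is within
    `tolerance` of the grid minimum, plus the full error curve.
    """
    y = np.asarray(y)
    n = len(y)
    if species is not None:
        species = np.asarray(species)
    if species is None or len(set(species)) < 2:
        warnings.warn("fewer than 2 species; using stratified k-fold CV",
                      stacklevel=2)
        rng = np.random.default_rng(seed)
        folds = np.zeros(n, int)
        for c in set(y):
            idx = np.flatnonzero(y == c)
            folds[idx] = rng.permutation(len(idx)) % n_folds
        fold_ids = [folds == f for f in range(n_folds)]
    else:
        fold_ids = [species == sp for sp in sorted(set(species))]
    classes = sorted(set(y))
    errors = {}
    for keepX in grid:
        fold_errs = []
        for test in fold_ids:
            train = ~test
            if len(set(y[train])) < 2 or not test.any():
                continue
            Xtr = X.iloc[:, np.flatnonzero(train)] if isinstance(X, pd.DataFrame) \
                else X[:, train]
            Xte = X.iloc[:, np.flatnonzero(test)] if isinstance(X, pd.DataFrame) \
                else X[:, test]
            try:
                model = fit_splsda(Xtr, y[train], keepX, ncomp=ncomp)
            except ValueError:
                continue
            pred = model.predict(np.asarray(Xte, float))
            fold_errs.append(_balanced_error(y[test], pred, classes))
        errors[keepX] = float(np.mean(fold_errs)) if fold_errs else np.nan
    curve = pd.Series(errors, name="balanced_error")
    best = curve.min()
    ok = curve.index[curve <= best + tolerance]
    chosen = int(min(ok))
    return chosen, curve


def rank_markers(model: DiscriminantModel) -> pd.DataFrame:
    """Marker table ranked by |weight| on component 1, then component 2.

    Zero-weight features are omitted; ``in_optimal_set`` flags the top
    `optimal_keepX` component-1 markers when CV selection was run.
    """
    W = model.weights
    keys = [W.iloc[:, 0].abs()]
    if W.shape[1] > 1:
        keys.append(W.iloc[:, 1].abs())
    df = pd.DataFrame({
        "feature": W.index,
        "weight1": W.iloc[:, 0],
        "abs1": keys[0],
        "abs2": keys[1] if len(keys) > 1 else 0.0,
    })
    df = df[(df[["abs1", "abs2"]].to_numpy() != 0).any(axis=1)]
    df = df.sort_values(["abs1", "abs2", "feature"],
                        ascending=[False, False, True]).reset_index(drop=True)
    optimal = set()
    if model.optimal_keepX is not None:
        comp1 = df[df["abs1"] > 0]
        optimal = set(comp1["feature"].iloc[:model.optimal_keepX])
    df["in_optimal_set"] = df["feature"].isin(optimal)
    return df.drop(columns=["abs1", "abs2"])
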