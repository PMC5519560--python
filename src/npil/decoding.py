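"""Direction discrimination from population activity.

The decoder is the optimal linear (Fisher) discriminant under Gaussian
equal-covariance assumptions: ``w = Sigma^+ (mu1 - mu0)`` with a shared
pooled covariance inverted by pseudo-inverse (singular values below
``1e-8 x sigma_max`` are dropped), evaluated by stratified 10-fold
cross-validation.  Single-feature discriminability uses d' with the
pooled-variance denominator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .roi import make_neuropil_annulus

__all__ = [
    "PopulationVector",
    "cv_linear_decoding_accuracy",
    "population_size_sweep",
    "rank_filter_columns",
    "patch_size_sweep",
    "dprime",
    "dprime_spatial_shuffle_test",
]

logger = logging.getLogger(__name__)

RANK_TOL = 1e-8


@dataclass(frozen=True)
class PopulationVector:
    """Trial x feature response matrix with binary direction labels."""

    X: np.ndarray
    y: np.ndarray
    contrast: float | None = None
    feature_ids: tuple | None = None

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on trial count")
        if not np.all(np.isfinite(X)):
            raise ValueError("missing entries in the population matrix")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2 or counts.min() < 2:
            raise ValueError("need exactly 2 classes with >= 2 trials each")


class _FisherLDA:
    """Two-class Fisher discriminant with pseudo-inverse pooled covariance."""

    def __init__(self, rcond: float = RANK_TOL, rng: np.random.Generator | None = None):
        self.rcond = rcond
        self.rng = rng or np.random.default_rng(0)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_FisherLDA":
        self.classes_ = np.unique(y)
        X0 = X[y == self.classes_[0]]
        X1 = X[y == self.classes_[1]]
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        n0, n1 = len(X0), len(X1)
        if n0 + n1 > 2 and X.shape[1] >= 1:
            S = ((n0 - 1) * np.cov(X0, rowvar=False).reshape(X.shape[1], -1)
                 + (n1 - 1) * np.cov(X1, rowvar=False).reshape(X.shape[1], -1)) / (n0 + n1 - 2)
        else:
            S = np.eye(X.shape[1])
        Sinv = np.linalg.pinv(S, rcond=self.rcond, hermitian=True)
        if np.linalg.matrix_rank(S, tol=self.rcond * max(np.linalg.norm(S, 2), 1e-300)) < S.shape[0]:
            logger.info("singular pooled covariance: pseudo-inverse used")
        self.w_ = Sinv @ (mu1 - mu0)
        self.b_ = -0.5 * float(self.w_ @ (mu0 + mu1)) + np.log(n1 / n0)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        score = X @ self.w_ + self.b_
        pred = np.where(score > 0, self.classes_[1], self.classes_[0])
        ties = score == 0
        if np.any(ties):  # boundary ties broken by seeded coin flip
            flip = self.rng.integers(0, 2, size=int(ties.sum()))
            pred[ties] = np.where(flip == 1, self.classes_[1], self.classes_[0])
        return pred


def cv_linear_decoding_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    *,
    rcond: float = RANK_TOL,
) -> float:
    """Mean stratified k-fold cross-validated Fisher-LDA accuracy.

    Deterministic for a fixed seed (fold shuffling and tie-breaks both
    derive from it).
    """
    pv = PopulationVector(X, y)
    X, y = pv.X, pv.y
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        if np.unique(y[train]).size < 2:
            raise ValueError("a class is absent from a training fold")
        clf = _FisherLDA(rcond=rcond, rng=rng).fit(X[train], y[train])
        accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
    return float(np.mean(accs))


def population_size_sweep(
    X: np.ndarray,
    y: np.ndarray,
    sizes,
    *,
    resamples: int = 1000,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Decoding accuracy versus population-vector size.

    For each size ``n``, draws ``resamples`` random feature subsets without
    replacement, decodes each with cross-validation, and reports the mean
    and SEM over resamples.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    rows = []
    for n in sizes:
        if n > p:
            raise ValueError(f"requested population size {n} exceeds {p} features")
        accs = np.empty(resamples)
        for i in range(resamples):
            cols = rng.choice(p, size=n, replace=False)
            accs[i] = cv_linear_decoding_accuracy(
                X[:, cols], y, folds=folds, seed=int(rng.integers(2**31 - 1))
            )
        sem = float(accs.std(ddof=1) / np.sqrt(resamples)) if resamples > 1 else 0.0
        rows.append({"n": int(n), "accuracy": float(accs.mean()), "sem": sem})
    return pd.DataFrame(rows)


def rank_filter_columns(X: np.ndarray, tol_factor: float = RANK_TOL) -> list[int]:
    """Greedy column filter: keep a column only if it raises the matrix rank.

    Rank counts singular values above ``tol_factor x sigma_max``.  With
    strongly overlapping neuropil patches some columns become (numerically)
    linear combinations of earlier ones; the linear decoder needs full
    column rank, so those are dropped.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    kept: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        smax = float(np.linalg.norm(cand, 2))
        if smax == 0:
            continue
        r = int(np.linalg.matrix_rank(cand, tol=tol_factor * smax))
        if r > rank:
            kept.append(j)
            rank = r
    if not kept:
        raise ValueError("all columns degenerate: nothing to decode")
    return kept


def patch_size_sweep(
    pixel_responses: np.ndarray,
    centers,
    radii_list,
    pixel_size: float,
    y: np.ndarray,
    *,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Decoding accuracy as a function of neuropil-patch (annulus) size.

    For each (r_in, r_out), builds one feature per cell-centered annulus by
    averaging ``pixel_responses`` (trials x H x W) over the annulus mask,
    drops rank-redundant patches, and decodes the direction labels.
    """
    pixel_responses = np.asarray(pixel_responses, dtype=float)
    _, H, W = pixel_responses.shape
    rows = []
    for r_in, r_out in radii_list:
        feats = []
        for c in centers:
            try:
                mask = make_neuropil_annulus(c, (H, W), pixel_size, r_in=r_in, r_out=r_out)
            except ValueError:
                logger.info("empty annulus at center %s for size %s skipped", c, (r_in, r_out))
                continue
            feats.append(pixel_responses[:, mask].mean(axis=1))
        Xs = np.column_stack(feats)
        kept = rank_filter_columns(Xs)
        acc = cv_linear_decoding_accuracy(Xs[:, kept], y, folds=folds, seed=seed)
        rows.append(
            {"r_in": r_in, "r_out": r_out, "n_patches": len(kept), "accuracy": acc}
        )
    return pd.DataFrame(rows)


def dprime(x_h: np.ndarray, x_v: np.ndarray) -> float:
    """d' = (mean(x_h) - mean(x_v)) / sqrt(0.5 (var(x_h) + var(x_v))).

    Sample variances.  Zero pooled variance gives 0 for equal means and
    signed infinity (with a warning) otherwise.
    """
    x_h = np.asarray(x_h, dtype=float)
    x_v = np.asarray(x_v, dtype=float)
    if x_h.size < 2 or x_v.size < 2:
        raise ValueError("need at least 2 trials per class")
    num = float(x_h.mean() - x_v.mean())
    denom = float(np.sqrt(0.5 * (x_h.var(ddof=1) + x_v.var(ddof=1))))
    if denom == 0:
        if num == 0:
            return 0.0
        warnings.warn("zero variance with unequal means: d' is infinite", UserWarning)
        return float(np.sign(num) * np.inf)
    return num / denom


def dprime_spatial_shuffle_test(
    cell_map: np.ndarray,
    np_map: np.ndarray,
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Spatial correlation of cell vs neuropil d' maps against a shuffle null.

    Pearson r between the paired d' vectors; the null permutes the spatial
    order of cells, destroying the cell-to-patch pairing while preserving
    both d' multisets.  Returns (r, z, p) with z standardized against the
    null and a two-sided permutation p-value with the +1 correction.
    """
    cell_map = np.asarray(cell_map, dtype=float)
    np_map = np.asarray(np_map, dtype=float)
    if cell_map.shape != np_map.shape or cell_map.size < 3:
        raise ValueError("need matched d' maps with at least 3 ROIs")
    n = cell_map.size
    zc = (cell_map - cell_map.mean()) / cell_map.std()
    zn = (np_map - np_map.mean()) / np_map.std()
    r_obs = float(zc @ zn / n)
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_shuffles, n)), axis=1)
    r_null = zc[perms] @ zn / n
    z = (r_obs - r_null.mean()) / r_null.std()
    p = (1.0 + np.count_nonzero(np.abs(r_null) >= abs(r_obs))) / (n_shuffles + 1.0)
    return r_obs, float(z), float(p)
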