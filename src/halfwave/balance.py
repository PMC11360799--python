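"""Multi-class SMOTE and ADASYN oversampling to the largest class count.

Both methods grow every minority class until all class counts equal the
largest class's count; originals are always preserved verbatim and synthetic
samples are flagged.

* **SMOTE** interpolates: a synthetic point is ``x + lam * (x_nb - x)`` for a
  random same-class nearest neighbour ``x_nb`` and ``lam ~ U[0, 1]``, i.e. it
  lies on the segment joining the seed and the neighbour.
* **ADASYN** adapts where the points go: each minority sample i receives a
  share of the class budget proportional to ``r_i``, the fraction of
  other-class samples among its k nearest neighbours over the whole set, so
  harder boundary regions get more synthesis.  Each generated point is a
  SMOTE-style interpolation plus a small Gaussian jitter with per-feature
  scale ``sigma * sd(feature)``.

All randomness flows through a seeded generator, so runs are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .neighbors import distance_matrix_gram

__all__ = [
    "BalanceConfig",
    "smote_oversample",
    "adasyn_oversample",
    "balance",
    "MajoritySMOTE",
    "MajorityADASYN",
]


@dataclass(frozen=True)
class BalanceConfig:
    """Oversampling configuration; the target is always the largest class."""

    method: str = "adasyn"
    k_neighbors: int = 5
    seed: int | None = None
    sigma: float = 0.01

    def __post_init__(self) -> None:
        if self.method not in ("smote", "adasyn"):
            raise ValueError(f"unknown balance method {self.method!r}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _class_indices(y: np.ndarray) -> dict:
    # deterministic order: sorted unique labels
    return {c: np.flatnonzero(y == c) for c in np.unique(y)}


def _within_class_neighbors(Xc: np.ndarray, k: int) -> np.ndarray:
    """Row i: indices (into Xc's rows) of the k nearest same-class neighbours."""
    D = distance_matrix_gram(Xc.T).D
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k]

def _interpolate(
    Xc: np.ndarray, nb: np.ndarray, seeds: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """SMOTE interpolation for the given seed rows of Xc."""
    out = np.empty((seeds.size, Xc.shape[1]), dtype=float)
    k = nb.shape[1]
    for t, i in enumerate(seeds):
        j = nb[i, rng.integers(k)]
        lam = rng.uniform()
        out[t] = Xc[i] + lam * (Xc[j] - Xc[i])
    return out


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    random_state: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equalize class counts to the majority by SMOTE interpolation.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
    y : ndarray of shape (n_samples,)
    k_neighbors : int
        Same-class neighbour pool size; clipped to class size - 1.
    random_state : int, Generator or None

    Returns
    -------
    X_out, y_out, is_synthetic
        Originals first (verbatim, in input order), then synthetic rows;
        ``is_synthetic`` flags the appended rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(random_state)
    groups = _class_indices(y)
    target = max(len(ix) for ix in groups.values())

    new_X, new_y = [], []
    for c, ix in groups.items():
        deficit = target - len(ix)
        if deficit == 0:
            continue
        Xc = X[ix]
        if len(ix) == 1:
            warnings.warn(
                f"class {c!r} has a single sample; duplicating it "
                f"{deficit} times (degenerate interpolation)"
            )
            new_X.append(np.repeat(Xc, deficit, axis=0))
            new_y.append(np.repeat(y[ix], deficit))
            continue
        k = min(k_neighbors, len(ix) - 1)
        nb = _within_class_neighbors(Xc, k)
        seeds = rng.integers(len(ix), size=deficit)
        new_X.append(_interpolate(Xc, nb, seeds, rng))
        new_y.append(np.full(deficit, c, dtype=y.dtype))

    return _assemble(X, y, new_X, new_y)


def adasyn_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    sigma: float = 0.01,
    random_state: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equalize class counts to the majority by ADASYN adaptive synthesis.

    Per minority class, sample i's weight is the fraction of other-class
    samples among its ``k_neighbors`` nearest neighbours over all classes;
    the class's synthetic budget is split by largest-remainder rounding of
    the normalized weights.  A class whose samples see no foreign neighbours
    at all falls back to uniform weights with a warning.  Generated points
    are same-class interpolations plus Gaussian jitter of per-feature scale
    ``sigma * sd``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(random_state)
    groups = _class_indices(y)
    target = max(len(ix) for ix in groups.values())

    feat_sd = X.std(axis=0)
    D_all = distance_matrix_gram(X.T).D
    np.fill_diagonal(D_all, np.inf)
    k_all = min(k_neighbors, X.shape[0] - 1)
    nn_all = np.argsort(D_all, axis=1, kind="stable")[:, :k_all]

    new_X, new_y = [], []
    for c, ix in groups.items():
        deficit = target - len(ix)
        if deficit == 0:
            continue
        Xc = X[ix]
        if len(ix) == 1:
            warnings.warn(
                f"class {c!r} has a single sample; duplicating it "
                f"{deficit} times (degenerate interpolation)"
            )
            pts = np.repeat(Xc, deficit, axis=0) + _jitter(
                rng, (deficit, X.shape[1]), sigma, feat_sd
            )
            new_X.append(pts)
            new_y.append(np.full(deficit, c, dtype=y.dtype))
            continue

        r = np.array([np.mean(y[nn_all[i]] != c) for i in ix])
        if r.sum() == 0:
            warnings.warn(
                f"class {c!r} is perfectly isolated (all r_i = 0); "
                "falling back to uniform ADASYN weights"
            )
            w = np.full(len(ix), 1.0 / len(ix))
        else:
            w = r / r.sum()
        counts = _largest_remainder(w * deficit, deficit)

        k = min(k_neighbors, len(ix) - 1)
        nb = _within_class_neighbors(Xc, k)
        seeds = np.repeat(np.arange(len(ix)), counts)
        pts = _interpolate(Xc, nb, seeds, rng)
        pts = pts + _jitter(rng, pts.shape, sigma, feat_sd)
        new_X.append(pts)
        new_y.append(np.full(deficit, c, dtype=y.dtype))

    return _assemble(X, y, new_X, new_y)


def _jitter(
    rng: np.random.Generator,
    shape: tuple[int, int],
    sigma: float,
    feat_sd: np.ndarray,
) -> np.ndarray:
    """Zero-mean Gaussian jitter, clipped at 3 sigma per feature.

    The clip bounds the perturbation so every synthetic point stays within
    the class bounding box inflated by 3*sigma*sd(feature).
    """
    z = np.clip(rng.normal(0.0, 1.0, shape), -3.0, 3.0)
    return z * (sigma * feat_sd)


def _largest_remainder(quota: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to ``total``; ties broken by lower index."""
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short > 0:
        frac = quota - base
        order = np.lexsort((np.arange(quota.size), -frac))
        base[order[:short]] += 1
    return base


def _assemble(X, y, new_X, new_y):
    if new_X:
        X_out = np.vstack([X] + new_X)
        y_out = np.concatenate([y] + new_y)
    else:
        X_out, y_out = X.copy(), y.copy()
    flags = np.zeros(X_out.shape[0], dtype=bool)
    flags[X.shape[0]:] = True
    return X_out, y_out, flags


def balance(
    X: np.ndarray, y: np.ndarray, cfg: BalanceConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dispatch to :func:`smote_oversample` or :func:`adasyn_oversample`."""
    if cfg.method == "smote":
        return smote_oversample(X, y, cfg.k_neighbors, cfg.seed)
    return adasyn_oversample(X, y, cfg.k_neighbors, cfg.sigma, cfg.seed)


class _MajorityResampler(BaseEstimator):
    """Shared fit_resample shell for the two oversamplers."""

    def __init__(self, k_neighbors: int = 5, random_state: int | None = None):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        X_out, y_out, flags = self._resample(np.asarray(X, float), np.asarray(y))
        self.synthetic_mask_ = flags
        return X_out, y_out


class MajoritySMOTE(_MajorityResampler):
    """SMOTE oversampler equalizing all classes to the largest class count."""

    def _resample(self, X, y):
        return smote_oversample(X, y, self.k_neighbors, self.random_state)


class MajorityADASYN(_MajorityResampler):
    """ADASYN oversampler equalizing all classes to the largest class count."""

    def __init__(
        self,
        k_neighbors: int = 5,
        sigma: float = 0.01,
        random_state: int | None = None,
    ):
        super().__init__(k_neighbors=k_neighbors, random_state=random_state)
        self.sigma = sigma

    def _resample(self, X, y):
        return adasyn_oversample(
            X, y, self.k_neighbors, self.sigma, self.random_state
        )
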