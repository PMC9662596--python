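"""Laplacian-kernel kernel ridge regression.

The prediction for a molecule i is ŷ_i = Σ_j k(X_i, X_j^train)·α_j with
k(X, X') = exp(−‖X − X'‖₁/σ). The coefficients α solve the regularized
linear system (K + λI)α = y; labels computed from quantum chemistry are
noiseless to machine precision, so λ defaults to the tiny value 1e−12 and
acts only as a numerical stabilizer. The kernel width σ is selected by
grid-search cross validation within each training set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import scipy.linalg
from sklearn.metrics.pairwise import manhattan_distances
from sklearn.model_selection import KFold

from .represent import RepVector

__all__ = [
    "DEFAULT_LAMBDA",
    "DEFAULT_SIGMAS",
    "HyperGrid",
    "KernelModel",
    "laplacian_kernel",
    "krr_train",
    "krr_predict",
    "select_sigma",
    "select_sigma_from_distances",
    "mae",
    "save_model",
    "load_model",
]

#: Default regularization for noiseless labels.
DEFAULT_LAMBDA = 1e-12

#: Default σ candidates: powers of two spanning the large L1 distances that
#: spectral representation vectors produce (typically 10³–10⁵ for small
#: organics with the default radial/angular grids).
DEFAULT_SIGMAS = tuple(float(2**p) for p in range(4, 19))


def as_matrix(X: Union[np.ndarray, Sequence]) -> np.ndarray:
    """Stack RepVectors / 1-D arrays into a 2-D (n, d) float matrix."""
    if isinstance(X, np.ndarray) and X.ndim == 2:
        return np.asarray(X, dtype=float)
    rows = [np.asarray(x.values if isinstance(x, RepVector) else x, dtype=float).ravel()
            for x in X]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"representation vectors of unequal length: {sorted(lengths)}")
    return np.vstack(rows)


@dataclass(frozen=True)
class HyperGrid:
    """σ candidates plus the cross-validation layout used to pick one."""

    sigmas: tuple[float, ...] = DEFAULT_SIGMAS
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sigmas) == 0:
            raise ValueError("sigma grid must be non-empty")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("all sigma candidates must be positive")
        if self.folds < 2:
            raise ValueError("need at least 2 CV folds")


@dataclass
class KernelModel:
    """A trained KRR model: training vectors, coefficients and kernel width."""

    X_train: np.ndarray
    alpha: np.ndarray
    sigma: float
    lam: float = DEFAULT_LAMBDA
    label: str = ""

    def __post_init__(self) -> None:
        self.X_train = as_matrix(self.X_train)
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        if len(self.alpha) != len(self.X_train):
            raise ValueError("alpha length must match the training set size")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")

    @property
    def n_train(self) -> int:
        return len(self.alpha)


def laplacian_kernel(A, B, sigma: float) -> np.ndarray:
    """k_ij = exp(−‖A_i − B_j‖₁ / σ); entries in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a, b = as_matrix(A), as_matrix(B)
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"vector length mismatch: {a.shape[1]} vs {b.shape[1]}")
    return np.exp(-manhattan_distances(a, b) / sigma)


def _solve_kernel_system(K: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """(K + λI)α = y by Cholesky; jitter escalation (λ×10, 3 tries) then
    least-squares as last resort."""
    n = len(y)
    lam_eff = lam
    for _ in range(4):
        try:
            c, low = scipy.linalg.cho_factor(
                K + lam_eff * np.eye(n), lower=True, check_finite=False
            )
            return scipy.linalg.cho_solve((c, low), y, check_finite=False)
        except scipy.linalg.LinAlgError:
            lam_eff = max(lam_eff, 1e-14) * 10.0
            warnings.warn(
                f"kernel factorization failed; retrying with jitter {lam_eff:g}",
                RuntimeWarning,
                stacklevel=3,
            )
    alpha, *_ = np.linalg.lstsq(K + lam * np.eye(n), y, rcond=None)
    return alpha


def krr_train(X, y, sigma: float, lam: float = DEFAULT_LAMBDA, label: str = "") -> KernelModel:
    """Fit α on training vectors and labels (eV)."""
    x = as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    if len(x) != len(yv):
        raise ValueError(f"{len(x)} training vectors but {len(yv)} labels")
    if len(yv) < 1:
        raise ValueError("need at least one training point")
    if not np.all(np.isfinite(yv)):
        raise ValueError("non-finite training labels")
    K = laplacian_kernel(x, x, sigma)
    alpha = _solve_kernel_system(K, yv, lam)
    return KernelModel(X_train=x, alpha=alpha, sigma=sigma, lam=lam, label=label)


def krr_predict(model: KernelModel, X_test) -> np.ndarray:
    """ŷ_i = Σ_j k(X_i, X_j^train)·α_j."""
    xt = as_matrix(X_test)
    if xt.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"test vector length {xt.shape[1]} != training length {model.X_train.shape[1]}"
        )
    return laplacian_kernel(xt, model.X_train, model.sigma) @ model.alpha


def mae(yhat, y) -> float:
    """Mean absolute error in eV."""
    a = np.asarray(yhat, dtype=float).ravel()
    b = np.asarray(y, dtype=float).ravel()
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("mae of empty arrays is undefined")
    return float(np.mean(np.abs(a - b)))


def select_sigma_from_distances(
    D: np.ndarray, y, grid: HyperGrid, lam: float = DEFAULT_LAMBDA
) -> float:
    """Pick the σ minimizing mean CV MAE, given the precomputed L1 distance
    matrix of the training set. Ties break toward the smallest σ; the fold
    count is clamped to the training-set size for very small sets."""
    yv = np.asarray(y, dtype=float).ravel()
    n = len(yv)
    folds = min(grid.folds, n)
    if folds < 2:
        raise ValueError(f"{n} training points cannot support cross validation")
    kf = KFold(n_splits=folds, shuffle=True, random_state=grid.seed)
    folds = list(kf.split(np.arange(n)))
    best_sigma, best_score = None, np.inf
    for sigma in sorted(grid.sigmas):
        K = np.exp(-D / sigma)
        score = 0.0
        for tr, va in folds:
            alpha = _solve_kernel_system(K[np.ix_(tr, tr)], yv[tr], lam)
            score += mae(K[np.ix_(va, tr)] @ alpha, yv[va])
        score /= len(folds)
        if score < best_score:
            best_sigma, best_score = sigma, score
    return float(best_sigma)


def select_sigma(X, y, grid: HyperGrid, lam: float = DEFAULT_LAMBDA) -> float:
    """Grid-search CV selection of σ from representation vectors."""
    x = as_matrix(X)
    return select_sigma_from_distances(manhattan_distances(x, x), y, grid, lam)


def save_model(model: KernelModel, path) -> None:
    """Serialize to <path>.npz (arrays) + <path>.json (scalars)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), X_train=model.X_train, alpha=model.alpha)
    path.with_suffix(".json").write_text(
        json.dumps(
            {"sigma": model.sigma, "lam": model.lam, "label": model.label,
             "n_train": model.n_train},
            indent=2,
        )
    )


def load_model(path) -> KernelModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arrays = np.load(path.with_suffix(".npz"))
    return KernelModel(
        X_train=arrays["X_train"], alpha=arrays["alpha"],
        sigma=meta["sigma"], lam=meta["lam"], label=meta.get("label", ""),
    )
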