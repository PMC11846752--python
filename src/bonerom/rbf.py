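"""Radial basis function interpolation over the implant-pose space.

Six kernel families are supported (``r`` the Euclidean distance between
normalised parameter points, ``a > 0`` the shape parameter):

====================  =============================
Gaussian (G)          ``exp(-(a r)^2)``
Multiquadric (MQ)     ``sqrt(1 + (a r)^2)``
Inverse MQ (IMQ)      ``1 / sqrt(1 + (a r)^2)``
Matern C0 (MC0)       ``exp(-a r)``
Matern C2 (MC2)       ``exp(-a r) (1 + a r)``
Matern C4 (MC4)       ``exp(-a r) (3 + 3 a r + (a r)^2)``
====================  =============================

G, IMQ and the Matern family are strictly positive definite; MQ is only
conditionally positive definite, so it should be used with polynomial
augmentation.  Augmentation appends a degree-1 tail
``h(mu) = eta . [1, mu_1, ..., mu_np]`` plus the usual moment side
conditions, which also buys exact reproduction of affine functions.

Parameter inputs are normalised per-dimension to [0, 1] (min-max from the
training bounds) before any distance is computed, removing the influence of
heterogeneous units (mm vs degrees).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "KERNELS",
    "STRICTLY_POSITIVE_DEFINITE",
    "kernel_eval",
    "normalize_params",
    "denormalize_params",
    "RBFInterpolant",
    "fit_rbf",
    "predict_weights",
    "shape_parameter_sweep",
]

KERNELS = {
    "G": lambda r, a: np.exp(-((a * r) ** 2)),
    "MQ": lambda r, a: np.sqrt(1.0 + (a * r) ** 2),
    "IMQ": lambda r, a: 1.0 / np.sqrt(1.0 + (a * r) ** 2),
    "MC0": lambda r, a: np.exp(-a * r),
    "MC2": lambda r, a: np.exp(-a * r) * (1.0 + a * r),
    "MC4": lambda r, a: np.exp(-a * r) * (3.0 + 3.0 * a * r + (a * r) ** 2),
}

#: kernels whose interpolation matrix is symmetric positive definite for
#: distinct centers; MQ is only conditionally positive definite
STRICTLY_POSITIVE_DEFINITE = frozenset({"G", "IMQ", "MC0", "MC2", "MC4"})

_COND_WARN_THRESHOLD = 1e12


def kernel_eval(kernel: str, r, a: float):
    """Evaluate a kernel family at distance(s) ``r >= 0``."""
    if kernel not in KERNELS:
        raise KeyError(f"unknown kernel {kernel!r}; choose from {sorted(KERNELS)}")
    if a <= 0 or not np.isfinite(a):
        raise ValueError("shape parameter must be positive and finite")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    return KERNELS[kernel](r, a)


def normalize_params(P: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Affine map of each parameter dimension to [0, 1].

    ``P`` has parameter vectors as rows (n_samples x n_p); ``bounds`` is
    (n_p, 2) with lower < upper per dimension.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(hi <= lo):
        bad = np.flatnonzero(hi <= lo)
        raise ValueError(
            f"degenerate parameter dimension(s) {bad.tolist()}: lower bound "
            "equals upper bound -- remove the constant parameter"
        )
    return (P - lo) / (hi - lo)


def denormalize_params(P_hat: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    return np.atleast_2d(np.asarray(P_hat, dtype=float)) * (hi - lo) + lo


def _poly_tail(P_hat: np.ndarray) -> np.ndarray:
    """Degree-1 polynomial basis [1, mu_1, ..., mu_np] evaluated row-wise."""
    return np.column_stack([np.ones(len(P_hat)), P_hat])


class RBFInterpolant(RegressorMixin, BaseEstimator):
    """Scattered-data RBF interpolator of reduced coordinates over pose space.

    Parameters
    ----------
    kernel : str, default "MC0"
        One of ``G, MQ, IMQ, MC0, MC2, MC4``.
    shape : float, default 1e-4
        Shape parameter ``a``; small values flatten the kernels (risking
        ill-conditioning), large values narrow them.
    augment : bool, default True
        Append the degree-1 polynomial tail with moment side conditions.
    bounds : (n_p, 2) array, optional
        Normalisation bounds; defaults to the per-dimension min/max of the
        training inputs.

    Attributes
    ----------
    centers_ : (n_s, n_p) array of normalised training parameters.
    coef_ : (n_outputs, n_s) RBF coefficient matrix A.
    poly_coef_ : (n_outputs, n_p + 1) tail coefficients eta (augmented only).
    condition_ : float, 1-norm condition estimate of the linear system.
    """

    def __init__(self, kernel: str = "MC0", shape: float = 1e-4,
                 augment: bool = True, bounds=None):
        self.kernel = kernel
        self.shape = shape
        self.augment = augment
        self.bounds = bounds

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if len(X) != len(y):
            raise ValueError("X and y must have the same number of rows")
        if self.kernel == "MQ" and not self.augment:
            warnings.warn(
                "MQ is only conditionally positive definite; use augment=True",
                stacklevel=2,
            )
        if self.bounds is None:
            b = np.column_stack([X.min(axis=0), X.max(axis=0)])
        else:
            b = np.asarray(self.bounds, dtype=float)
        self.bounds_ = b
        Xh = normalize_params(X, b)
        D = cdist(Xh, Xh)
        off_diag = D + np.diag(np.full(len(Xh), np.inf))
        if np.any(off_diag < 1e-14):
            raise ValueError("duplicate training centers after normalisation")
        B = kernel_eval(self.kernel, D, self.shape)
        n_s, n_p = Xh.shape
        if self.augment:
            if n_s <= n_p + 1:
                raise ValueError(
                    "augmented fit needs more centers than polynomial terms"
                )
            Pm = _poly_tail(Xh)
            A = np.block([[B, Pm], [Pm.T, np.zeros((n_p + 1, n_p + 1))]])
            rhs = np.vstack([y, np.zeros((n_p + 1, y.shape[1]))])
        else:
            A = B
            rhs = y
        self.condition_ = float(np.linalg.cond(A, 1))
        if self.condition_ > _COND_WARN_THRESHOLD:
            warnings.warn(
                f"ill-conditioned RBF system (cond ~ {self.condition_:.2e}); "
                "consider a larger shape parameter",
                stacklevel=2,
            )
        sol = np.linalg.solve(A, rhs)
        self.centers_ = Xh
        self.coef_ = sol[:n_s].T
        self.poly_coef_ = sol[n_s:].T if self.augment else None
        self.n_features_in_ = n_p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xh = normalize_params(X, self.bounds_)
        if np.any((Xh < -1e-9) | (Xh > 1.0 + 1e-9)):
            warnings.warn(
                "evaluating the interpolant outside the training bounds "
                "(extrapolation)",
                stacklevel=2,
            )
        Phi = kernel_eval(self.kernel, cdist(Xh, self.centers_), self.shape)
        out = Phi @ self.coef_.T
        if self.poly_coef_ is not None:
            out = out + _poly_tail(Xh) @ self.poly_coef_.T
        return out


def fit_rbf(S_r: np.ndarray, P: np.ndarray, kernel: str = "MC0",
            shape: float = 1e-4, augmented: bool = True,
            bounds=None) -> RBFInterpolant:
    """Fit reduced coordinates (n x n_s, column-snapshot convention) over
    training poses ``P`` (n_p x n_s columns)."""
    interp = RBFInterpolant(kernel=kernel, shape=shape, augment=augmented,
                            bounds=bounds)
    return interp.fit(np.asarray(P).T, np.asarray(S_r).T)


def predict_weights(interp: RBFInterpolant, pose_vec) -> np.ndarray:
    """Reduced weights ``w(mu)`` for one pose parameter vector."""
    return interp.predict(np.atleast_2d(pose_vec))[0]


def shape_parameter_sweep(train, holdout, families=None, a_grid=None,
                          bounds=None):
    """Grid search of kernel family, shape parameter and augmentation flag.

    ``train``/``holdout`` are ``(P, Y)`` pairs with parameter vectors as rows
    and target vectors as rows.  Returns ``(table, selection)`` where
    ``table`` is a pandas DataFrame with one MAE per (family, a, augmented)
    cell (NaN for singular fits) and ``selection`` the argmin row as a dict
    (ties broken toward smaller ``a``).
    """
    import pandas as pd

    P_tr, Y_tr = train
    P_ho, Y_ho = holdout
    families = list(families or sorted(KERNELS))
    a_grid = np.asarray(
        a_grid if a_grid is not None else np.logspace(-4, 1, 11), dtype=float)
    rows = []
    for fam in families:
        for a in a_grid:
            for aug in (False, True):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        interp = RBFInterpolant(
                            kernel=fam, shape=float(a), augment=aug,
                            bounds=bounds).fit(P_tr, Y_tr)
                        pred = interp.predict(P_ho)
                    mae = float(np.mean(np.abs(pred - Y_ho)))
                except (np.linalg.LinAlgError, ValueError):
                    mae = np.nan
                rows.append({"kernel": fam, "a": float(a), "augmented": aug,
                             "mae": mae})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["mae"]).sort_values(["mae", "a"],
                                                     kind="stable")
    if valid.empty:
        raise RuntimeError("every sweep cell failed to fit")
    selection = valid.iloc[0].to_dict()
    return table, selection
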