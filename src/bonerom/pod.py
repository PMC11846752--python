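"""Proper orthogonal decomposition of snapshot matrices.

Snapshots (converged nodal BMD fields, one per implant pose) are collected
column-wise in ``S`` (N x n_s).  A thin SVD ``S = U Sigma Z^T`` yields
orthonormal spatial modes; the retained count ``n`` is the smallest number
whose squared singular values capture strictly more than an energy fraction
``kappa`` of the total.  No mean-centring is applied -- the decomposition
acts on the raw snapshot matrix.

The estimator :class:`PODReducer` follows the scikit-learn transformer
protocol with samples as rows (``X`` of shape (n_samples, n_features)); the
module-level functions keep the column-snapshot convention of the
surrounding pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PODBasis",
    "PODReducer",
    "compute_pod",
    "truncation_error",
    "reduce",
    "reconstruct",
]


@dataclass
class PODBasis:
    """Truncated POD basis.

    ``modes`` (N x n) are orthonormal; ``singular_values`` is the full
    descending list (length min(N, n_s)); ``energy_tol`` the kappa used for
    truncation.
    """

    modes: np.ndarray
    singular_values: np.ndarray
    energy_tol: float

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def captured_energy(self) -> float:
        s2 = self.singular_values**2
        return float(s2[: self.n_modes].sum() / s2.sum())

    def energy_table(self):
        """Singular values with cumulative energy fraction and truncation
        error per mode count (for CSV export / energy-decay plots)."""
        import pandas as pd

        s = self.singular_values
        s2 = s**2
        return pd.DataFrame({
            "mode": np.arange(1, len(s) + 1),
            "singular_value": s,
            "energy_fraction": np.cumsum(s2) / s2.sum(),
            "truncation_error": [
                truncation_error(s, n) for n in range(1, len(s) + 1)
            ],
        })


def _fix_mode_signs(V: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-magnitude entry of each
    mode is made positive (first occurrence breaks ties)."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def select_mode_count(singular_values: np.ndarray, kappa: float) -> int:
    """Smallest n with ``sum_{i<=n} s_i^2 / sum s_i^2 > kappa`` (strict)."""
    if not 0 < kappa <= 1:
        raise ValueError("kappa must lie in (0, 1]")
    s2 = np.asarray(singular_values, dtype=float) ** 2
    total = s2.sum()
    if total == 0:
        raise ValueError("all-zero snapshot matrix")
    frac = np.cumsum(s2) / total
    above = np.flatnonzero(frac > kappa)
    # kappa = 1 exactly can only be exceeded by numerical round-up; fall back
    # to the full rank if the strict inequality is never met
    return int(above[0]) + 1 if len(above) else len(s2)


def compute_pod(S: np.ndarray, kappa: float = 0.9999) -> PODBasis:
    """Thin SVD of the column-snapshot matrix with energy truncation."""
    S = np.asarray(S, dtype=float)
    if not np.all(np.isfinite(S)):
        raise ValueError("snapshot matrix contains NaN/Inf")
    U, s, _ = np.linalg.svd(S, full_matrices=False)
    n = select_mode_count(s, kappa)
    V = _fix_mode_signs(U[:, :n])
    return PODBasis(modes=V, singular_values=s, energy_tol=kappa)


def truncation_error(singular_values: np.ndarray, n: int) -> float:
    """Relative tail energy ``sqrt(sum_{i>n} s_i^2 / sum s_i^2)``.

    Equals the relative Frobenius error of the rank-n POD reconstruction.
    """
    s2 = np.asarray(singular_values, dtype=float) ** 2
    if not 1 <= n <= len(s2):
        raise ValueError("n out of range")
    return float(np.sqrt(s2[n:].sum() / s2.sum()))


def reduce(V: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Reduced snapshot matrix ``S_r = V^T S`` (n x n_s)."""
    return np.asarray(V).T @ np.asarray(S)


def reconstruct(V: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Full field(s) ``V w`` from reduced coordinates."""
    return np.asarray(V) @ np.asarray(w)


class PODReducer(TransformerMixin, BaseEstimator):
    """SVD-based orthogonal decomposition with an energy truncation rule.

    Parameters
    ----------
    energy_tol : float, default 0.9999
        Fraction kappa of squared-singular-value energy the retained modes
        must strictly exceed.

    Attributes
    ----------
    components_ : (n_modes_, n_features) array
        Orthonormal modes (rows), deterministic sign convention.
    singular_values_ : (min(n_samples, n_features),) array
        Full descending singular value list.
    n_modes_ : int
        Retained mode count.
    """

    def __init__(self, energy_tol: float = 0.9999):
        self.energy_tol = energy_tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2D array with at least 2 snapshots")
        basis = compute_pod(X.T, kappa=self.energy_tol)
        self.components_ = basis.modes.T
        self.singular_values_ = basis.singular_values
        self.n_modes_ = basis.n_modes
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        return np.asarray(X, dtype=float) @ self.components_.T

    def inverse_transform(self, W):
        check_is_fitted(self, "components_")
        return np.asarray(W, dtype=float) @ self.components_

    def truncation_error_(self, n: int | None = None) -> float:
        check_is_fitted(self, "components_")
        return truncation_error(self.singular_values_, n or self.n_modes_)

    def basis(self) -> PODBasis:
        check_is_fitted(self, "components_")
        return PODBasis(
            modes=self.components_.T,
            singular_values=self.singular_values_,
            energy_tol=self.energy_tol,
        )
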