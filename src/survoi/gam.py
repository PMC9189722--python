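"""Penalized tensor-product cubic spline smoother.

A small Gaussian-response GAM sufficient for regressing simulated net
benefits on two summary statistics: cubic B-spline marginal bases (default
dimension 5 per margin, interior knots at data quantiles), a tensor-product
design, second-order difference penalties applied marginally, and smoothing
parameters chosen by minimising the GCV score.  The coefficient posterior
covariance uses the usual Bayesian form sigma^2 (X'X + S_lambda)^{-1}, which
is what coefficient-resampling standard errors are drawn from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline

__all__ = ["TensorSplineFit", "fit_tensor_spline"]


def _bspline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Clamped cubic B-spline basis with ``df`` functions (df >= 4)."""
    lo, hi = float(np.min(x)), float(np.max(x))
    n_interior = df - 4
    if n_interior > 0:
        qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        # strictly increasing interior knots; collapse duplicates
        interior = np.unique(interior[(interior > lo) & (interior < hi)])
    else:
        interior = np.array([])
    knots = np.r_[[lo] * 4, interior, [hi] * 4]
    return BSpline.design_matrix(np.clip(x, lo, hi), knots, 3).toarray()


def _basis_dim(x: np.ndarray, df: int) -> int:
    n_unique = len(np.unique(x))
    if n_unique < 2:
        return 1
    return int(min(df, n_unique))


def _marginal(x: np.ndarray, df: int) -> np.ndarray:
    d = _basis_dim(x, df)
    if d == 1:
        return np.ones((len(x), 1))
    if d < 4:
        # too few distinct values for a cubic basis: polynomial design
        return np.vander(x, d, increasing=True)
    return _bspline_basis(x, d)


def _diff_penalty(m: int) -> np.ndarray:
    if m < 3:
        return np.zeros((m, m))
    D = np.diff(np.eye(m), 2, axis=0)
    return D.T @ D


@dataclass(frozen=True)
class TensorSplineFit:
    design: np.ndarray
    coef: np.ndarray
    cov_coef: np.ndarray
    fitted: np.ndarray
    edf: float
    sigma2: float
    gcv: float
    lambdas: tuple[float, float]

    def resample_fitted(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """(n_draws, n_obs) fitted-value replicates from the coefficient law."""
        cov = 0.5 * (self.cov_coef + self.cov_coef.T)
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < 0:
            cov = cov + (abs(eig.min()) + 1e-12) * np.eye(len(cov))
        beta = rng.multivariate_normal(self.coef, cov, size=n_draws, method="svd")
        return beta @ self.design.T


def fit_tensor_spline(y: np.ndarray, x1: np.ndarray, x2: np.ndarray,
                      df: int = 5) -> TensorSplineFit:
    """Fit y ~ te(x1, x2) with GCV-selected smoothing parameters."""
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n = len(y)
    if not (len(x1) == len(x2) == n):
        raise ValueError("y, x1, x2 must have equal length")
    B1, B2 = _marginal(x1, df), _marginal(x2, df)
    m1, m2 = B1.shape[1], B2.shape[1]
    X = np.einsum("ij,ik->ijk", B1, B2).reshape(n, m1 * m2)
    # drop numerically empty columns (keeps the solve well posed)
    keep = (X != 0).any(axis=0)
    if not keep.all():
        warnings.warn("tensor basis is rank deficient; dropping empty columns")
    S1 = np.kron(_diff_penalty(m1), np.eye(m2))[np.ix_(keep, keep)]
    S2 = np.kron(np.eye(m1), _diff_penalty(m2))[np.ix_(keep, keep)]
    X = X[:, keep]
    p = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y
    ridge = 1e-9 * (np.trace(XtX) / max(p, 1)) * np.eye(p)

    def solve(loglam: np.ndarray):
        l1, l2 = np.exp(loglam)
        A = XtX + l1 * S1 + l2 * S2 + ridge
        beta = np.linalg.solve(A, Xty)
        edf = float(np.trace(np.linalg.solve(A, XtX)))
        rss = float(np.sum((y - X @ beta) ** 2))
        return A, beta, edf, rss

    def gcv(loglam: np.ndarray) -> float:
        if np.max(np.abs(loglam)) > 30.0:  # keep the solve well conditioned
            return np.inf
        try:
            _, _, edf, rss = solve(loglam)
        except np.linalg.LinAlgError:
            return np.inf
        denom = max(n - edf, 1e-8)
        return n * rss / denom**2

    if p == 1 or (S1.any() == False and S2.any() == False):  # noqa: E712
        best = np.array([0.0, 0.0])
    else:
        r = optimize.minimize(gcv, np.array([0.0, 0.0]), method="Nelder-Mead",
                              options=dict(xatol=1e-3, fatol=1e-10, maxiter=400))
        best = r.x
    A, beta, edf, rss = solve(best)
    fitted = X @ beta
    sigma2 = rss / max(n - edf, 1.0)
    cov_coef = sigma2 * np.linalg.inv(A)
    return TensorSplineFit(design=X, coef=beta, cov_coef=cov_coef, fitted=fitted,
                           edf=edf, sigma2=sigma2, gcv=gcv(best),
                           lambdas=tuple(np.exp(best)))
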