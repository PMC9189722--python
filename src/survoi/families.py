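"""Two-parameter parametric survival families on an unconstrained parameter scale.

Four candidate families are supported: Weibull, Gamma, log-normal and
log-logistic.  Each has a shape-like and a scale-like natural parameter.
All model fitting, uncertainty propagation and posterior sampling happen on
a *transformed* (unconstrained) scale so that a bivariate normal is a sensible
description of parameter beliefs:

==============  =====================  ============================
family          natural (shape, scale)  transformed vector ``theta``
==============  =====================  ============================
weibull         shape ``k``, scale ``lam``    ``(log k, log lam)``
gamma           shape ``alpha``, rate ``beta``  ``(log alpha, log beta)``
lognormal       sdlog ``sigma``, meanlog ``mu``  ``(log sigma, mu)``
loglogistic     shape ``a``, scale ``b``      ``(log a, log b)``
==============  =====================  ============================

The log-normal ``mu`` is already unconstrained, so it is left untransformed;
every positivity-constrained parameter is log-transformed.  The log-logistic
survivor function is ``S(t) = 1 / (1 + (t/b)**a)``.

Time is measured in months throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import integrate, stats

__all__ = [
    "FAMILIES",
    "ParamVector",
    "frozen_dist",
    "to_natural",
    "to_transformed",
    "survivor",
    "hazard",
    "cdf",
    "quantile",
    "log_density",
    "rmst",
    "rmst_batch",
    "survivor_batch",
    "sample_truncated",
    "sample_truncated_batch",
]

FAMILIES: tuple[str, ...] = ("weibull", "gamma", "lognormal", "loglogistic")

NATURAL_PARAM_NAMES: dict[str, tuple[str, str]] = {
    "weibull": ("shape", "scale"),
    "gamma": ("shape", "rate"),
    "lognormal": ("sdlog", "meanlog"),
    "loglogistic": ("shape", "scale"),
}


def _check_family(family: str) -> str:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return family


@dataclass(frozen=True)
class ParamVector:
    """A survival model: family name plus 2-vector on the transformed scale."""

    family: str
    values: tuple[float, float]

    def __post_init__(self) -> None:
        _check_family(self.family)
        vals = tuple(float(v) for v in self.values)
        if len(vals) != 2 or not all(np.isfinite(vals)):
            raise ValueError(f"theta must be a finite 2-vector, got {self.values!r}")
        object.__setattr__(self, "values", vals)

    @property
    def natural(self) -> tuple[float, float]:
        return to_natural(self.family, self.values)

    @classmethod
    def from_natural(cls, family: str, shape_like: float, scale_like: float) -> "ParamVector":
        return cls(family, to_transformed(family, (shape_like, scale_like)))


def to_natural(family: str, theta: Iterable[float]) -> tuple[float, float]:
    """Map a transformed 2-vector to the natural (constrained) scale."""
    _check_family(family)
    t0, t1 = (float(v) for v in theta)
    if family == "lognormal":
        return (np.exp(t0), t1)  # (sdlog, meanlog)
    return (np.exp(t0), np.exp(t1))


def to_transformed(family: str, natural: Iterable[float]) -> tuple[float, float]:
    """Inverse of :func:`to_natural`."""
    _check_family(family)
    n0, n1 = (float(v) for v in natural)
    if n0 <= 0:
        raise ValueError(f"shape-like parameter must be positive, got {n0}")
    if family == "lognormal":
        return (np.log(n0), n1)
    if n1 <= 0:
        raise ValueError(f"scale-like parameter must be positive, got {n1}")
    return (np.log(n0), np.log(n1))


def frozen_dist(params: ParamVector):
    """scipy.stats frozen distribution for a parameter vector."""
    a, b = params.natural
    f = params.family
    if f == "weibull":
        return stats.weibull_min(c=a, scale=b)
    if f == "gamma":
        return stats.gamma(a=a, scale=1.0 / b)
    if f == "lognormal":
        return stats.lognorm(s=a, scale=np.exp(b))
    return stats.fisk(c=a, scale=b)


def survivor(params: ParamVector, t):
    """S(t); vectorized in ``t``.  Requires t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survivor requires t >= 0")
    return frozen_dist(params).sf(t)


def cdf(params: ParamVector, t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("cdf requires t >= 0")
    return frozen_dist(params).cdf(t)


def log_density(params: ParamVector, t):
    """log f(t); vectorized in ``t``.  Requires t > 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("log_density requires t > 0")
    return frozen_dist(params).logpdf(t)


def hazard(params: ParamVector, t):
    """h(t) = f(t) / S(t); vectorized in ``t``.  Requires t > 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard requires t > 0")
    d = frozen_dist(params)
    return np.exp(d.logpdf(t) - d.logsf(t))


def quantile(params: ParamVector, p):
    """Inverse CDF; requires 0 < p < 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("quantile requires 0 < p < 1")
    return frozen_dist(params).ppf(p)


def rmst(params: ParamVector, horizon: float) -> float:
    """Restricted mean survival time: area under S(t) on [0, horizon].

    Adaptive quadrature (absolute tolerance 1e-8).  Units: life-months.
    """
    horizon = float(horizon)
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if horizon == 0:
        return 0.0
    d = frozen_dist(params)
    val, _ = integrate.quad(d.sf, 0.0, horizon, epsabs=1e-8, limit=400)
    return float(val)


# --- vectorized operations over many parameter draws ------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(160)
_GL_U = 0.5 * (_GL_NODES + 1.0)
_GL_W = 0.5 * _GL_WEIGHTS


def _sf_matrix(family: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """S(t_j; theta_i) for a (n,2) matrix of transformed draws and grid t."""
    _check_family(family)
    a = np.exp(theta[:, 0])[:, None]
    t = t[None, :]
    if family == "weibull":
        lam = np.exp(theta[:, 1])[:, None]
        with np.errstate(divide="ignore"):
            return np.exp(-(t / lam) ** a)
    if family == "gamma":
        beta = np.exp(theta[:, 1])[:, None]
        return stats.gamma.sf(t, a=a, scale=1.0 / beta)
    if family == "lognormal":
        mu = theta[:, 1][:, None]
        return stats.lognorm.sf(t, s=a, scale=np.exp(mu))
    b = np.exp(theta[:, 1])[:, None]
    return stats.fisk.sf(t, c=a, scale=b)


def survivor_batch(family: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Survivor matrix (n_draws, n_times) for transformed draws ``theta``."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    return _sf_matrix(family, theta, np.asarray(t, dtype=float))


def rmst_batch(family: str, theta: np.ndarray, horizon: float,
               block: int = 20000) -> np.ndarray:
    """RMST for each row of a (n, 2) matrix of transformed parameter draws.

    Gauss-Legendre quadrature on the substitution t = horizon * u**2, which
    removes the slope singularity of S at zero for shape parameters below 1.
    Agrees with :func:`rmst` to ~1e-9 for the parameter ranges used here.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    horizon = float(horizon)
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if horizon == 0:
        return np.zeros(len(theta))
    tt = horizon * _GL_U**2
    jac_w = 2.0 * horizon * _GL_U * _GL_W
    out = np.empty(len(theta))
    for i in range(0, len(theta), block):
        out[i : i + block] = _sf_matrix(family, theta[i : i + block], tt) @ jac_w
    return out


def _isf_batch(family: str, theta: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Inverse survivor T = S^{-1}(s) with per-row transformed params."""
    a = np.exp(theta[:, 0])[:, None]
    if family == "weibull":
        lam = np.exp(theta[:, 1])[:, None]
        return lam * (-np.log(s)) ** (1.0 / a)
    if family == "gamma":
        beta = np.exp(theta[:, 1])[:, None]
        return stats.gamma.isf(s, a=a, scale=1.0 / beta)
    if family == "lognormal":
        mu = theta[:, 1][:, None]
        return stats.lognorm.isf(s, s=a, scale=np.exp(mu))
    b = np.exp(theta[:, 1])[:, None]
    return b * (1.0 / s - 1.0) ** (1.0 / a)


def sample_truncated(params: ParamVector, t1: float, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` survival times conditional on survival beyond ``t1``.

    Inverse-CDF construction: with v ~ U(0,1), T = S^{-1}(v * S(t1)) follows
    the left-truncated distribution exactly.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    t1 = float(t1)
    if t1 < 0:
        raise ValueError("t1 must be non-negative")
    theta = np.asarray(params.values, dtype=float)[None, :]
    s1 = float(_sf_matrix(params.family, theta, np.array([t1]))[0, 0])
    if s1 <= 0.0 or not np.isfinite(s1):
        raise ValueError(f"survivor({t1}) is numerically zero; truncation is degenerate")
    v = rng.random(n)
    return _isf_batch(params.family, theta, (v * s1)[None, :])[0]


def sample_truncated_batch(family: str, theta: np.ndarray, t1: float, n: int,
                           rng: np.random.Generator) -> np.ndarray:
    """(n_draws, n) matrix of truncated samples, one row per parameter draw."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    s1 = _sf_matrix(family, theta, np.array([float(t1)]))
    if np.any(s1 <= 0.0):
        raise ValueError("survivor(t1) is numerically zero for some draws")
    v = rng.random((len(theta), n))
    return _isf_batch(family, theta, v * s1)
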