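"""Maximum-likelihood fitting of candidate families to censored survival data.

The likelihood for right-censored data is the usual product of density terms
for events and survivor terms for censored observations.  Rows with a
non-zero entry time contribute left-truncated terms: the likelihood of such
an observation is divided by S(entry), so that events before the entry time
are impossible by construction and the data already observed up to the entry
time are not double-counted.

Parameter beliefs after the fit are summarised as a bivariate normal on the
transformed scale: mean at the MLE, covariance from the inverse observed
information (central finite differences of the log-likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .datasets import SurvivalDataset
from .families import FAMILIES, ParamVector, to_transformed

__all__ = ["FittedModel", "ModelSet", "log_likelihood", "fit_mle",
           "fit_all_families", "aic_weights"]


def _loglik_terms(family: str, theta: np.ndarray, times: np.ndarray,
                  events: np.ndarray, entry: np.ndarray) -> np.ndarray:
    pv = ParamVector(family, tuple(theta))
    from .families import frozen_dist

    d = frozen_dist(pv)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        terms = np.where(events == 1, d.logpdf(times), d.logsf(times))
        if np.any(entry > 0):
            terms = terms - np.where(entry > 0, d.logsf(entry), 0.0)
    return terms


def log_likelihood(dataset: SurvivalDataset, params: ParamVector) -> float:
    """Log-likelihood of a (possibly left-truncated) censored dataset."""
    if np.any((dataset.events == 1) & (dataset.times <= 0)):
        raise ValueError("event times must be positive")
    terms = _loglik_terms(params.family, np.asarray(params.values),
                          dataset.times, dataset.events, dataset.entry)
    return float(np.sum(terms))


@dataclass(frozen=True)
class FittedModel:
    """An MLE fit of one family: transformed-scale mean, covariance, AIC."""

    family: str
    mle: ParamVector
    cov: np.ndarray
    loglik: float
    n_params: int = 2

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (2, 2):
            raise ValueError("cov must be 2x2")
        cov = 0.5 * (cov + cov.T)
        if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
            raise ValueError("covariance is not positive semi-definite")
        cov.setflags(write=False)
        object.__setattr__(self, "cov", cov)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def _initial_theta(family: str, dataset: SurvivalDataset) -> np.ndarray:
    """Moment-flavoured starting values robust to heavy censoring."""
    t = dataset.times
    ev = dataset.events
    # crude scale guess: mean time inflated for the censored fraction
    frac = max(ev.mean(), 1.0 / len(t))
    scale = float(np.mean(t) / frac)
    scale = min(max(scale, 1e-3), 1e5)
    if family == "lognormal":
        obs = t[ev == 1]
        mu = float(np.log(scale))
        sd = float(np.std(np.log(obs))) if len(obs) > 2 else 1.0
        return np.array(to_transformed("lognormal", (max(sd, 0.2), mu)))
    if family == "gamma":
        return np.array(to_transformed("gamma", (1.0, 1.0 / scale)))
    return np.array(to_transformed(family, (1.0, scale)))


def _fd_gradient(f, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    g = np.empty(len(x))
    for i in range(len(x)):
        e = np.zeros(len(x)); e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def _fd_hessian(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    m = len(x)
    H = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h
            ej = np.zeros(m); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def fit_mle(dataset: SurvivalDataset, family: str,
            grad_tol: float = 1e-4) -> FittedModel:
    """Fit one family by maximum likelihood on the transformed scale.

    Nelder-Mead from moment-based starting values, polished with BFGS; up to
    three jittered restarts if the gradient norm check fails.  The covariance
    is the inverse observed information at the MLE.
    """
    if dataset.n_events < 1:
        raise ValueError("cannot fit a survival model to a dataset with no events")

    def nll(theta: np.ndarray) -> float:
        terms = _loglik_terms(family, theta, dataset.times, dataset.events,
                              dataset.entry)
        val = -np.sum(terms)
        return float(val) if np.isfinite(val) else 1e12

    x0 = _initial_theta(family, dataset)
    best = None
    rng = np.random.default_rng(0)
    for attempt in range(4):
        start = x0 if attempt == 0 else x0 + rng.normal(scale=0.5, size=2)
        r = optimize.minimize(nll, start, method="Nelder-Mead",
                              options=dict(xatol=1e-12, fatol=1e-13, maxiter=8000))
        r = optimize.minimize(nll, r.x, method="BFGS",
                              options=dict(gtol=1e-10, maxiter=500))
        # Newton polish: drives the finite-difference gradient to its noise floor
        x = r.x
        for _ in range(5):
            g = _fd_gradient(nll, x)
            if np.linalg.norm(g) < 1e-6:
                break
            try:
                step = np.linalg.solve(_fd_hessian(nll, x), g)
            except np.linalg.LinAlgError:
                break
            if nll(x - step) <= nll(x) + 1e-9 * max(abs(nll(x)), 1.0):
                x = x - step
            else:
                break
        r.x, r.fun = x, nll(x)
        if best is None or r.fun < best.fun:
            best = r
        if np.linalg.norm(_fd_gradient(nll, best.x)) <= grad_tol:
            break
    else:
        raise RuntimeError(
            f"MLE for {family} did not converge: grad norm "
            f"{np.linalg.norm(_fd_gradient(nll, best.x)):.2e}, nll {best.fun:.6f}")

    H = _fd_hessian(nll, best.x)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise RuntimeError(f"singular observed information for {family}") from exc
    if np.min(np.linalg.eigvalsh(cov)) < 0:
        cov = cov + (abs(np.min(np.linalg.eigvalsh(cov))) + 1e-10) * np.eye(2)
    return FittedModel(family=family, mle=ParamVector(family, tuple(best.x)),
                       cov=cov, loglik=-best.fun)


def aic_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights exp(-AIC/2), normalised; computed with max-subtraction."""
    a = np.asarray(aics, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one AIC value")
    if not np.all(np.isfinite(a)):
        raise ValueError("AIC values must be finite")
    w = np.exp(-0.5 * (a - a.min()))
    return w / w.sum()


@dataclass(frozen=True)
class ModelSet:
    """Candidate fits for one arm with AIC-based prior model probabilities."""

    fits: tuple[FittedModel, ...]
    prior_weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.prior_weights, dtype=float)
        if len(w) != len(self.fits):
            raise ValueError("one weight per fitted model required")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")
        w.setflags(write=False)
        object.__setattr__(self, "prior_weights", w)
        object.__setattr__(self, "fits", tuple(self.fits))

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(f.family for f in self.fits)

    @property
    def aics(self) -> np.ndarray:
        return np.array([f.aic for f in self.fits])

    def __getitem__(self, family: str) -> FittedModel:
        for f in self.fits:
            if f.family == family:
                return f
        raise KeyError(family)


def fit_all_families(dataset: SurvivalDataset,
                     families: Sequence[str] = FAMILIES) -> ModelSet:
    """Fit every candidate family and attach AIC-based prior weights."""
    fits = tuple(fit_mle(dataset, fam) for fam in families)
    return ModelSet(fits=fits, prior_weights=aic_weights([f.aic for f in fits]))
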