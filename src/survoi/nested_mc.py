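"""Nested Monte Carlo EVSI with MCMC posterior sampling and bridge sampling.

This is the computationally expensive reference method against which the
regression estimator is validated.  For each outer draw k a follow-up
dataset is simulated per arm.  The posterior of the survival parameters
given that dataset combines

* the bivariate-normal belief p(theta | x) held at t1 (acting as the prior:
  the data observed before t1 enter only through it, avoiding double
  counting), and
* the left-truncated likelihood of the simulated follow-up data.

Random-walk Metropolis with a proposal scaled from the prior covariance
samples this 2-D target; the inner expectation of net benefit is the mean
restricted mean survival time over the posterior draws.

For model averaging the same is done under each candidate family, the
marginal likelihood of the simulated data under each family is estimated by
iterative (Meng-Wong) bridge sampling, posterior model probabilities follow
by Bayes' theorem from the AIC-based prior weights, and the inner net
benefits are averaged with those posterior probabilities before maximising
over decisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .evsi_regression import EVSIEstimate
from .families import rmst_batch
from .fitting import FittedModel, ModelSet
from .future_data import FutureDataset, draw_params, generate_followup

__all__ = ["PosteriorSample", "posterior_sample", "inner_value",
           "bridge_marginal_likelihood", "posterior_model_probs",
           "nested_mc_evsi", "nested_mc_model_averaged"]


@dataclass(frozen=True)
class PosteriorSample:
    family: str
    draws: np.ndarray          # (J, 2) post-warmup, transformed scale
    acceptance_rate: float
    rhat: np.ndarray           # split-chain diagnostic per coordinate

    def __post_init__(self) -> None:
        if len(self.draws) < 100:
            raise ValueError("need at least 100 post-warmup draws")


def _logpdf_logsf(family: str, theta: np.ndarray, t: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(m, n) log-density and log-survivor matrices; theta rows broadcast."""
    a = np.exp(theta[:, 0])[:, None]  # shape-like, always log-transformed
    t = t[None, :]
    if family == "weibull":
        lam = np.exp(theta[:, 1])[:, None]
        z = t / lam
        logsf = -(z**a)
        logpdf = np.log(a) - np.log(lam) + (a - 1) * np.log(z) + logsf
        return logpdf, logsf
    if family == "gamma":
        beta = np.exp(theta[:, 1])[:, None]
        return (sps.gamma.logpdf(t, a=a, scale=1.0 / beta),
                sps.gamma.logsf(t, a=a, scale=1.0 / beta))
    if family == "lognormal":
        mu = theta[:, 1][:, None]
        return (sps.lognorm.logpdf(t, s=a, scale=np.exp(mu)),
                sps.lognorm.logsf(t, s=a, scale=np.exp(mu)))
    b = np.exp(theta[:, 1])[:, None]
    z = t / b
    logsf = -np.log1p(z**a)
    logpdf = np.log(a) - np.log(b) + (a - 1) * np.log(z) + 2 * logsf
    return logpdf, logsf


def _lt_loglik(family: str, theta: np.ndarray, fd: FutureDataset) -> np.ndarray:
    """Left-truncated log-likelihood of the follow-up data, vectorized over
    rows of theta (shape (m, 2)); empty datasets contribute 0."""
    theta = np.atleast_2d(theta)
    m = len(theta)
    if len(fd) == 0:
        return np.zeros(m)
    ev_mask = fd.events == 1
    ev_times = fd.times[ev_mask]
    # censored rows share the cut-off time t2, so group them
    cens_times, cens_counts = np.unique(fd.times[~ev_mask], return_counts=True)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out = np.zeros(m)
        if len(ev_times):
            logpdf, _ = _logpdf_logsf(family, theta, ev_times)
            out += logpdf.sum(axis=1)
        if len(cens_times):
            _, logsf_c = _logpdf_logsf(family, theta, cens_times)
            out += logsf_c @ cens_counts
        _, logsf_t1 = _logpdf_logsf(family, theta, np.array([fd.t1]))
        out = out - len(fd) * logsf_t1[:, 0]
    return np.where(np.isfinite(out), out, -np.inf)


def _log_target(fit: FittedModel, fd: FutureDataset, theta: np.ndarray,
                prior_mean: np.ndarray, prior_prec: np.ndarray,
                prior_logdet: float) -> np.ndarray:
    d = theta - prior_mean
    log_prior = -0.5 * np.einsum("ij,jk,ik->i", d, prior_prec, d) \
        - 0.5 * prior_logdet - np.log(2 * np.pi)
    return log_prior + _lt_loglik(fit.family, theta, fd)


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """chains: (n_chains, n_iter, dim) -> split-chain R-hat per dim."""
    c, n, dim = chains.shape
    half = n // 2
    segs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n2 = segs.shape[0], half
    means = segs.mean(axis=1)                    # (m, dim)
    variances = segs.var(axis=1, ddof=1)         # (m, dim)
    W = variances.mean(axis=0)
    B = n2 * means.var(axis=0, ddof=1)
    var_hat = (n2 - 1) / n2 * W + B / n2
    return np.sqrt(var_hat / np.maximum(W, 1e-300))


def posterior_sample(fit: FittedModel, fd: FutureDataset, j: int,
                     rng: np.random.Generator, n_chains: int = 4,
                     warmup: int = 500, rhat_tol: float = 1.05,
                     thin: int = 4) -> PosteriorSample:
    """Random-walk Metropolis sample of p(theta | x, x~) of size >= j.

    Chains are thinned (default every 4th step) so the kept draws are close
    to independent and the split-chain diagnostic is informative.
    """
    prior_mean = np.asarray(fit.mle.values)
    cov = np.asarray(fit.cov)
    prior_prec = np.linalg.inv(cov)
    sign, prior_logdet = np.linalg.slogdet(cov)
    keep = -(-j // n_chains)  # ceil
    prop_cov = (2.4**2 / 2.0) * cov
    L = np.linalg.cholesky(prop_cov + 1e-12 * np.eye(2))
    scale = np.ones(n_chains)

    cur = prior_mean + rng.standard_normal((n_chains, 2)) @ np.linalg.cholesky(
        cov + 1e-12 * np.eye(2)).T
    cur_lp = _log_target(fit, fd, cur, prior_mean, prior_prec, prior_logdet)
    acc_count = 0
    total = 0
    out = np.empty((n_chains, keep, 2))
    for it in range(warmup + keep * thin):
        step = (rng.standard_normal((n_chains, 2)) @ L.T) * scale[:, None]
        prop = cur + step
        prop_lp = _log_target(fit, fd, prop, prior_mean, prior_prec, prior_logdet)
        accept = np.log(rng.random(n_chains)) < prop_lp - cur_lp
        cur[accept] = prop[accept]
        cur_lp[accept] = prop_lp[accept]
        if it < warmup:
            # stochastic approximation toward ~23% acceptance
            scale *= np.exp((accept.astype(float) - 0.234) / np.sqrt(1.0 + it))
        else:
            post_it = it - warmup
            if post_it % thin == thin - 1:
                out[:, post_it // thin] = cur
            acc_count += int(accept.sum())
            total += n_chains
    rhat = _split_rhat(out)
    if np.any(rhat > rhat_tol):
        # short kept chains make the diagnostic noisy: one retry with longer,
        # more thinned chains before declaring failure
        if thin <= 8:
            return posterior_sample(fit, fd, j, rng, n_chains=n_chains,
                                    warmup=2 * warmup, rhat_tol=rhat_tol,
                                    thin=4 * thin)
        raise RuntimeError(f"MCMC did not converge: split R-hat {rhat}")
    return PosteriorSample(fit.family, out.reshape(-1, 2)[:j],
                           acc_count / max(total, 1), rhat)


def inner_value(sample: PosteriorSample, horizon: float) -> float:
    """Posterior-mean net benefit: average RMST over the inner draws."""
    return float(rmst_batch(sample.family, sample.draws, horizon).mean())


def _mvn_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    return sps.multivariate_normal(mean=mean, cov=cov, allow_singular=True).logpdf(x)


def bridge_marginal_likelihood(fit: FittedModel, fd: FutureDataset,
                               posterior: PosteriorSample,
                               rng: np.random.Generator | None = None,
                               tol: float = 1e-10, max_iter: int = 1000
                               ) -> float:
    """Log marginal likelihood log p(x~ | M, x) by iterative bridge sampling.

    The integrand is the left-truncated likelihood of x~ times the
    bivariate-normal prior p(theta | x).  The bridge proposal is a normal
    matched to the first two moments of the posterior draws; the optimal
    (Meng-Wong) bridge function is iterated to convergence.  An empty
    follow-up dataset has marginal likelihood exactly 1.
    """
    if len(fd) == 0:
        return 0.0
    rng = np.random.default_rng(0) if rng is None else rng
    draws = posterior.draws
    n1 = len(draws)
    prop_mean = draws.mean(axis=0)
    prop_cov = np.cov(draws.T) + 1e-12 * np.eye(2)
    n2 = n1
    prop = rng.multivariate_normal(prop_mean, prop_cov, size=n2)

    prior_mean = np.asarray(fit.mle.values)
    prior_cov = np.asarray(fit.cov)

    def log_q(theta: np.ndarray) -> np.ndarray:  # unnormalized posterior
        return (_mvn_logpdf(theta, prior_mean, prior_cov)
                + _lt_loglik(fit.family, theta, fd))

    l1 = log_q(draws) - _mvn_logpdf(draws, prop_mean, prop_cov)   # at posterior
    l2 = log_q(prop) - _mvn_logpdf(prop, prop_mean, prop_cov)     # at proposal
    lstar = np.median(l1)
    s1 = n1 / (n1 + n2)
    s2 = n2 / (n1 + n2)
    r = 1.0  # running estimate of Z / exp(lstar)
    for _ in range(max_iter):
        num = np.exp(l2 - lstar) / (s1 * np.exp(l2 - lstar) + s2 * r)
        den = 1.0 / (s1 * np.exp(l1 - lstar) + s2 * r)
        r_new = (num.mean()) / (den.mean())
        if abs(r_new - r) <= tol * abs(r_new):
            r = r_new
            break
        r = r_new
    else:
        raise RuntimeError("bridge sampling iteration did not converge")
    return float(np.log(r) + lstar)


def posterior_model_probs(log_margliks: Sequence[float],
                          prior_weights: Sequence[float]) -> np.ndarray:
    """Posterior model probabilities from log marginal likelihoods (Bayes)."""
    lm = np.asarray(log_margliks, dtype=float)
    pw = np.asarray(prior_weights, dtype=float)
    with np.errstate(divide="ignore"):
        logpost = lm + np.log(pw)
    if np.all(np.isneginf(logpost)):
        raise ValueError("all models have zero posterior probability")
    logpost = logpost - np.max(logpost[np.isfinite(logpost)])
    post = np.exp(np.where(np.isneginf(logpost), -np.inf, logpost))
    post[~np.isfinite(post)] = 0.0
    return post / post.sum()


def _se_guard(values: np.ndarray) -> float:
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def nested_mc_evsi(arm_fits: Sequence[FittedModel], n_at_risk: Sequence[int],
                   t1: float, t2: float, horizon: float, k: int, j: int,
                   seed: int | np.random.SeedSequence, n_chains: int = 4,
                   warmup: int = 500) -> EVSIEstimate:
    """Single-model nested Monte Carlo EVSI for one follow-up extension."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)
    theta_outer = [draw_params(fit, k, rng) for fit in arm_fits]
    nb_outer = np.column_stack([
        rmst_batch(fit.family, th, horizon)
        for fit, th in zip(arm_fits, theta_outer)])
    baseline = float(nb_outer.mean(axis=0).max())

    max_inner = np.empty(k)
    failures = 0
    for kk in range(k):
        inner = np.empty(len(arm_fits))
        for d, (fit, n2) in enumerate(zip(arm_fits, n_at_risk)):
            pv = type(fit.mle)(fit.family, tuple(theta_outer[d][kk]))
            fd = generate_followup(pv, n2, t1, t2, rng, k_index=kk)
            try:
                post = posterior_sample(fit, fd, j, rng, n_chains=n_chains,
                                        warmup=warmup)
            except RuntimeError:
                failures += 1
                if failures > max(1, k // 100):
                    raise
                inner[d] = np.nan
                continue
            inner[d] = inner_value(post, horizon)
        max_inner[kk] = np.nanmax(inner)
    if failures:
        warnings.warn(f"{failures} outer draws skipped after MCMC failure")
        max_inner = max_inner[np.isfinite(max_inner)]
    value = float(max_inner.mean() - baseline)
    return EVSIEstimate(value, _se_guard(max_inner), "nested_mc", t2 - t1,
                        False, k, j)


def nested_mc_model_averaged(arm_model_sets: Sequence[ModelSet],
                             n_at_risk: Sequence[int], t1: float, t2: float,
                             horizon: float, k: int, j: int,
                             seed: int | np.random.SeedSequence,
                             n_chains: int = 4, warmup: int = 500
                             ) -> EVSIEstimate:
    """Model-averaged nested Monte Carlo EVSI for one follow-up extension.

    With a single candidate family per arm this reduces exactly to the
    single-model estimator: the bridge factor cancels in Bayes' theorem, so
    the computation is delegated (same draws, same estimate).
    """
    if all(len(ms.fits) == 1 for ms in arm_model_sets):
        est = nested_mc_evsi([ms.fits[0] for ms in arm_model_sets], n_at_risk,
                             t1, t2, horizon, k, j, seed, n_chains=n_chains,
                             warmup=warmup)
        return EVSIEstimate(est.value, est.se, est.method, est.extension,
                            True, est.k, est.j)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)
    from .future_data import draw_model_then_params

    idx_theta = [draw_model_then_params(ms, k, rng) for ms in arm_model_sets]
    nb_cols = []
    for (idx, theta), ms in zip(idx_theta, arm_model_sets):
        nb = np.empty(k)
        for i, fit in enumerate(ms.fits):
            sel = idx == i
            if sel.any():
                nb[sel] = rmst_batch(fit.family, theta[sel], horizon)
        nb_cols.append(nb)
    baseline = float(np.column_stack(nb_cols).mean(axis=0).max())

    max_inner = np.empty(k)
    for kk in range(k):
        nb_d = np.empty(len(arm_model_sets))
        for d, (ms, n2) in enumerate(zip(arm_model_sets, n_at_risk)):
            idx, theta = idx_theta[d]
            gen_fit = ms.fits[int(idx[kk])]
            pv = type(gen_fit.mle)(gen_fit.family, tuple(theta[kk]))
            fd = generate_followup(pv, n2, t1, t2, rng, k_index=kk)
            inner = np.empty(len(ms.fits))
            logml = np.empty(len(ms.fits))
            for r, fit in enumerate(ms.fits):
                post = posterior_sample(fit, fd, j, rng, n_chains=n_chains,
                                        warmup=warmup)
                inner[r] = inner_value(post, horizon)
                logml[r] = bridge_marginal_likelihood(fit, fd, post, rng)
            probs = posterior_model_probs(logml, ms.prior_weights)
            nb_d[d] = float(probs @ inner)
        max_inner[kk] = nb_d.max()
    value = float(max_inner.mean() - baseline)
    return EVSIEstimate(value, _se_guard(max_inner), "nested_mc", t2 - t1,
                        True, k, j)
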