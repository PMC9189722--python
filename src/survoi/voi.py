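"""EVPI and the expected net benefit of sampling (ENBS) layer.

EVPI is the ceiling on any EVSI: the value of resolving all parameter (and,
in the model-averaged case, model) uncertainty before deciding.  The ENBS
layer turns per-decision EVSI values into population quantities, builds
marginal benefit and marginal cost curves over the length of additional
follow-up, and locates the optimal extension under two access policies:
approval with research (AWR: patients receive the new technology while data
accumulate; continuing costs only) and only in research (OIR: approval is
withheld, so the forgone net benefit of the better technology adds to the
marginal cost).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .families import rmst_batch
from .fitting import FittedModel, ModelSet
from .future_data import draw_model_then_params, draw_params

__all__ = ["ENBSConfig", "evpi", "evpi_from_models", "population_evsi",
           "enbs_curves"]


def evpi(nb_draws: np.ndarray) -> float:
    """EVPI from a (K, D) matrix of net-benefit draws.

    mean of per-draw maxima minus maximum of per-option means; non-negative
    by construction up to floating point.
    """
    nb = np.asarray(nb_draws, dtype=float)
    if nb.ndim != 2 or len(nb) < 2:
        raise ValueError("nb_draws must be a (K, D) matrix with K >= 2")
    return float(nb.max(axis=1).mean() - nb.mean(axis=0).max())


def evpi_from_models(arm_models: Sequence[FittedModel | ModelSet],
                     horizon: float, k: int,
                     seed: int | np.random.SeedSequence) -> float:
    """Monte-Carlo EVPI from fitted parameter (and model) beliefs.

    Each arm contributes an independent column of net-benefit draws: RMST at
    parameters drawn from the bivariate normal (single model) or from the
    AIC-weighted mixture over families (model-averaged).
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)
    cols = []
    for model in arm_models:
        if isinstance(model, ModelSet):
            idx, theta = draw_model_then_params(model, k, rng)
            nb = np.empty(k)
            for i, fit in enumerate(model.fits):
                sel = idx == i
                if sel.any():
                    nb[sel] = rmst_batch(fit.family, theta[sel], horizon)
        else:
            nb = rmst_batch(model.family, draw_params(model, k, rng), horizon)
        cols.append(nb)
    return evpi(np.column_stack(cols))


@dataclass(frozen=True)
class ENBSConfig:
    trial_cost_rate: float = 5.0      # life-months per month of follow-up
    accrual: float = 5.0              # new patients treated per month
    horizon_years: float = 10.0       # decision relevance horizon
    reporting_delay: float = 0.0      # months between data cut and decision

    def __post_init__(self) -> None:
        if min(self.trial_cost_rate, self.accrual, self.reporting_delay) < 0:
            raise ValueError("rates and delays must be non-negative")
        if self.horizon_years <= 0:
            raise ValueError("horizon must be positive")


def population_evsi(per_decision_evsi: float, config: ENBSConfig,
                    extension: float) -> float:
    """Scale per-patient EVSI to the population affected by the decision.

    The affected population is everyone who starts treatment between the
    (delayed) decision and the end of the decision horizon: accrual x
    (horizon - extension - reporting delay), with no discounting by default.
    """
    months = config.horizon_years * 12.0 - extension - config.reporting_delay
    if months < 0:
        raise ValueError("extension exceeds the decision horizon")
    return per_decision_evsi * config.accrual * months


def _pava_increasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares monotone increasing fit."""
    y = y.astype(float).copy()
    w = np.ones_like(y)
    blocks = [[i] for i in range(len(y))]
    vals = list(y)
    wts = list(w)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1] + 1e-12:
            tot = wts[i] + wts[i + 1]
            vals[i] = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / tot
            wts[i] = tot
            blocks[i].extend(blocks[i + 1])
            del vals[i + 1], wts[i + 1], blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out = np.empty_like(y)
    for v, b in zip(vals, blocks):
        out[b] = v
    return out


def enbs_curves(extensions: Sequence[float], evsi_values: Sequence[float],
                config: ENBSConfig, incremental_nb: float,
                evpi_value: float | None = None):
    """Monthly marginal benefit/cost curves and policy optima.

    ``extensions`` are the follow-up extensions (months) at which EVSI was
    computed; the EVSI curve is interpolated monthly with a monotone cubic
    through (0, 0), after isotonic smoothing if the inputs are non-monotone
    (with a warning).  ``incremental_nb`` is the current-information
    incremental net benefit of the optimal technology (life-months per
    patient), which prices the access withheld under OIR.

    Returns a dict with the monthly grid and, per policy, the optimal
    extension: the largest month whose marginal benefit still covers the
    marginal cost.
    """
    ext = np.asarray(extensions, dtype=float)
    ev = np.asarray(evsi_values, dtype=float)
    if np.any(np.diff(ext) <= 0):
        raise ValueError("extensions must be strictly increasing")
    if np.any(np.diff(ev) < 0):
        warnings.warn("EVSI values are not monotone; applying isotonic smoothing")
        ev = _pava_increasing(ev)
    xs = np.r_[0.0, ext]
    ys = np.r_[0.0, ev]
    if evpi_value is not None:
        ys = np.minimum(ys, evpi_value)
    interp = PchipInterpolator(xs, ys)
    months = np.arange(0.0, ext.max() + 1.0)
    evsi_m = interp(months)
    pop = np.array([population_evsi(v, config, m)
                    for v, m in zip(evsi_m, months)])
    mb = np.diff(pop)                       # marginal benefit per extra month
    mc_awr = np.full_like(mb, config.trial_cost_rate)
    mc_oir = mc_awr + config.accrual * max(incremental_nb, 0.0)

    def optimum(mc: np.ndarray) -> float:
        ok = np.nonzero(mb >= mc)[0]
        return float(ok[-1] + 1) if len(ok) else 0.0

    return {
        "month": months[1:],
        "population_evsi": pop[1:],
        "marginal_benefit": mb,
        "marginal_cost_awr": mc_awr,
        "marginal_cost_oir": mc_oir,
        "optimum_awr": optimum(mc_awr),
        "optimum_oir": optimum(mc_oir),
    }
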