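"""Regression-based EVSI for extending follow-up of an ongoing trial.

The estimator avoids nested simulation.  For each arm d and outer draw k we
store the net benefit NB(d, theta_d^(k)) (the restricted mean survival time
of the drawn model) together with the summary statistics (e_d^(k), y_d^(k))
of the simulated follow-up dataset generated from the same draw.  Smoothing
NB on the two statistics with a tensor-product spline estimates the
conditional mean g_d(x~) = E[NB(d, theta) | summary of x~]; the EVSI is then

    EVSI = (1/K) sum_k max_d ghat_d^(k)  -  max_d (1/K) sum_k NB(d, theta^(k)).

The same machinery serves the single-model case (parameters drawn from one
fitted family) and the model-averaged case (a family drawn per outer sample
with the AIC-based prior weights, then its parameters); only the outer draw
scheme differs.

Standard errors come from resampling the spline coefficients of each arm's
smoother from their asymptotic normal law and recomputing the EVSI
functional for each replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .families import rmst_batch
from .fitting import FittedModel, ModelSet
from .future_data import draw_model_then_params, draw_params, simulate_followup_batch
from .gam import TensorSplineFit, fit_tensor_spline

__all__ = ["ArmDraws", "NBTable", "EVSIEstimate", "build_nb_table",
           "current_info_value", "fit_smooth", "evsi_gam", "run_scenario"]


@dataclass(frozen=True)
class ArmDraws:
    """Outer-loop draws for one arm: net benefits plus follow-up summaries."""

    label: str
    nb: np.ndarray            # NB(d, theta^(k)), life-months
    events: np.ndarray        # e^(k)
    person_time: np.ndarray   # y^(k), months from t1
    model_index: np.ndarray | None = None


@dataclass(frozen=True)
class NBTable:
    arms: tuple[ArmDraws, ...]
    t1: float
    t2: float
    horizon: float
    model_averaged: bool

    @property
    def k(self) -> int:
        return len(self.arms[0].nb)


@dataclass(frozen=True)
class EVSIEstimate:
    value: float
    se: float
    method: str               # "gam" or "nested_mc"
    extension: float          # t2 - t1, months
    model_averaged: bool
    k: int
    j: int = 0


def build_nb_table(arm_models: Sequence[FittedModel | ModelSet],
                   n_at_risk: Sequence[int], t1: float, t2: float,
                   horizon: float, k: int, rng: np.random.Generator,
                   labels: Sequence[str] = ("new_treatment", "standard_care"),
                   ) -> NBTable:
    """Simulate K outer draws per arm and tabulate NB and summary statistics.

    ``arm_models`` holds one FittedModel (single-model run) or one ModelSet
    (model-averaged run) per arm; ``n_at_risk`` the number of patients alive
    at t1 in each arm.  RNG stream order per arm: parameters (and model
    indices), then survival samples.
    """
    arms = []
    model_averaged = isinstance(arm_models[0], ModelSet)
    for model, n2, label in zip(arm_models, n_at_risk, labels):
        if isinstance(model, ModelSet):
            idx, theta = draw_model_then_params(model, k, rng)
            nb = np.empty(k)
            ev = np.empty(k)
            pt = np.empty(k)
            for i, fit in enumerate(model.fits):
                sel = idx == i
                if not sel.any():
                    continue
                nb[sel] = rmst_batch(fit.family, theta[sel], horizon)
                ev[sel], pt[sel] = simulate_followup_batch(
                    fit.family, theta[sel], n2, t1, t2, rng)
            arms.append(ArmDraws(label, nb, ev, pt, idx))
        else:
            theta = draw_params(model, k, rng)
            nb = rmst_batch(model.family, theta, horizon)
            ev, pt = simulate_followup_batch(model.family, theta, n2, t1, t2, rng)
            arms.append(ArmDraws(label, nb, ev, pt))
    return NBTable(tuple(arms), t1, t2, horizon, model_averaged)


def current_info_value(nb_table: NBTable) -> tuple[int, float]:
    """Optimal arm under current information and its expected net benefit.

    Ties break toward the lower arm index.
    """
    means = np.array([arm.nb.mean() for arm in nb_table.arms])
    best = int(np.argmax(means))
    return best, float(means[best])


def fit_smooth(nb: np.ndarray, events: np.ndarray, person_time: np.ndarray,
               df: int = 5) -> TensorSplineFit:
    """Smooth one arm's net benefits on its two summary statistics."""
    if len(nb) < 50:
        raise ValueError("need at least 50 outer draws to fit the smoother")
    return fit_tensor_spline(nb, events, person_time, df=df)


def evsi_gam(nb_table: NBTable, n_se_draws: int = 1000,
             rng: np.random.Generator | None = None,
             df: int = 5) -> EVSIEstimate:
    """EVSI point estimate and coefficient-resampling standard error."""
    rng = np.random.default_rng(0) if rng is None else rng
    fits = [fit_smooth(a.nb, a.events, a.person_time, df=df)
            for a in nb_table.arms]
    ghat = np.column_stack([f.fitted for f in fits])
    _, baseline = current_info_value(nb_table)
    value = float(np.mean(ghat.max(axis=1)) - baseline)
    if len(nb_table.arms) == 1:
        return EVSIEstimate(0.0, 0.0, "gam", nb_table.t2 - nb_table.t1,
                            nb_table.model_averaged, nb_table.k)
    reps = np.stack([f.resample_fitted(n_se_draws, rng) for f in fits])  # (D,B,K)
    rep_first = reps.max(axis=0).mean(axis=1)           # (B,)
    rep_base = reps.mean(axis=2).max(axis=0)            # (B,)
    se = float(np.std(rep_first - rep_base, ddof=1))
    return EVSIEstimate(value, se, "gam", nb_table.t2 - nb_table.t1,
                        nb_table.model_averaged, nb_table.k)


def run_scenario(arm_models: Sequence[FittedModel | ModelSet],
                 n_at_risk: Sequence[int], t1: float, extensions: Sequence[float],
                 horizon: float, k: int, seed: int | np.random.SeedSequence,
                 n_se_draws: int = 1000,
                 labels: Sequence[str] = ("new_treatment", "standard_care"),
                 ) -> list[EVSIEstimate]:
    """GAM EVSI for several proposed extensions of follow-up.

    The outer parameter (and model) draws are shared across extensions, so
    the EVSI curve in the extension is smooth in the common Monte Carlo
    noise; only the simulated follow-up data are redrawn per extension, each
    from its own child RNG stream of ``seed``.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    root, *children = ss.spawn(len(extensions) + 1)
    rng = np.random.default_rng(root)

    outer = []  # per arm: (model, theta, model_index, nb)
    model_averaged = isinstance(arm_models[0], ModelSet)
    for model in arm_models:
        if isinstance(model, ModelSet):
            idx, theta = draw_model_then_params(model, k, rng)
            nb = np.empty(k)
            for i, fit in enumerate(model.fits):
                sel = idx == i
                if sel.any():
                    nb[sel] = rmst_batch(fit.family, theta[sel], horizon)
        else:
            idx = None
            theta = draw_params(model, k, rng)
            nb = rmst_batch(model.family, theta, horizon)
        outer.append((model, theta, idx, nb))

    out = []
    for ext, child in zip(extensions, children):
        ext_rng = np.random.default_rng(child)
        arms = []
        for (model, theta, idx, nb), n2, label in zip(outer, n_at_risk, labels):
            if idx is None:
                ev, pt = simulate_followup_batch(model.family, theta, n2, t1,
                                                 t1 + ext, ext_rng)
            else:
                ev = np.empty(k)
                pt = np.empty(k)
                for i, fit in enumerate(model.fits):
                    sel = idx == i
                    if sel.any():
                        ev[sel], pt[sel] = simulate_followup_batch(
                            fit.family, theta[sel], n2, t1, t1 + ext, ext_rng)
            arms.append(ArmDraws(label, nb, ev, pt, idx))
        table = NBTable(tuple(arms), t1, t1 + ext, horizon, model_averaged)
        out.append(evsi_gam(table, n_se_draws=n_se_draws, rng=ext_rng))
    return out
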