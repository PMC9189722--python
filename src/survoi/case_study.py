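"""Deterministic synthetic case-study datasets for the two-arm trial examples.

Two scenarios are provided, one with a monotonically increasing hazard of
death and one with a monotonically decreasing hazard.  Each arm enrols 200
participants at time zero and is administratively censored at ``t1 = 12``
months, with no loss to follow-up.

The survival times in an arm are generated *deterministically* rather than by
random sampling, so that the case studies carry no simulation noise of their
own: each arm's times are the 200 evenly spaced centred quantiles
(probabilities (i - 0.5) / 200) of an equal-weight mixture of a Weibull and a
Gamma distribution.  Using a two-component generating mixture means that none
of the four candidate families is exactly correct, which is the situation the
model-averaged analysis is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .datasets import SurvivalDataset
from .families import ParamVector, frozen_dist, quantile

__all__ = ["SCENARIOS", "CaseStudyConfig", "quantile_spaced_times",
           "mixture_quantile_times", "build_case_dataset"]

# generating parameters per scenario and arm: (weibull shape, weibull scale,
# gamma shape, gamma rate)
SCENARIOS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "increasing": {
        "new_treatment": (1.10, 70.0, 1.80, 0.04),
        "standard_care": (1.10, 50.0, 1.80, 0.04),
    },
    "decreasing": {
        "new_treatment": (0.60, 80.0, 0.80, 0.01),
        "standard_care": (0.60, 57.0, 0.80, 0.01),
    },
}


@dataclass(frozen=True)
class CaseStudyConfig:
    scenario: str = "increasing"
    n_per_arm: int = 200
    t1: float = 12.0
    horizon: float = 240.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {sorted(SCENARIOS)}")
        if not 0 < self.t1 < self.horizon:
            raise ValueError("need 0 < t1 < horizon")


def quantile_spaced_times(params: ParamVector, n_quantiles: int = 100) -> np.ndarray:
    """Times at the centred probability grid (i - 0.5)/n of one distribution.

    For ``n_quantiles = 100`` the grid is 0.005, 0.015, ..., 0.995: evenly
    spaced quantiles that avoid 0 and 1.
    """
    if n_quantiles < 1:
        raise ValueError("n_quantiles must be >= 1")
    p = (np.arange(n_quantiles) + 0.5) / n_quantiles
    return np.asarray(quantile(params, p), dtype=float)


def mixture_quantile_times(weibull: ParamVector, gamma: ParamVector,
                           n: int = 200) -> np.ndarray:
    """Centred quantiles of the equal-weight Weibull/Gamma mixture."""
    dw, dg = frozen_dist(weibull), frozen_dist(gamma)

    def F(t: float) -> float:
        return 0.5 * dw.cdf(t) + 0.5 * dg.cdf(t)

    p = (np.arange(n) + 0.5) / n
    return np.array([brentq(lambda t, pp=pp: F(t) - pp, 1e-12, 1e7,
                            xtol=1e-13, rtol=8.9e-16) for pp in p])


def _build_arm(spec: tuple[float, float, float, float], config: CaseStudyConfig,
               label: str) -> SurvivalDataset:
    k, lam, alpha, beta = spec
    times = mixture_quantile_times(
        ParamVector.from_natural("weibull", k, lam),
        ParamVector.from_natural("gamma", alpha, beta),
        config.n_per_arm)
    events = (times < config.t1).astype(int)
    observed = np.where(events == 1, times, config.t1)
    return SurvivalDataset(observed, events, np.zeros_like(observed), label)


def build_case_dataset(config: CaseStudyConfig | str,
                       ) -> tuple[SurvivalDataset, SurvivalDataset]:
    """Both arms of a scenario: (new_treatment, standard_care)."""
    if isinstance(config, str):
        config = CaseStudyConfig(scenario=config)
    arms = SCENARIOS[config.scenario]
    return (_build_arm(arms["new_treatment"], config, "new_treatment"),
            _build_arm(arms["standard_care"], config, "standard_care"))
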