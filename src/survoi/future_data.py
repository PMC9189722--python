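"""Simulation of plausible follow-up datasets on the interval (t1, t2].

For each of K outer draws we sample survival-model parameters (and, in the
model-averaged case, first a model) from the beliefs held at the interim
cut-off t1, then simulate continued follow-up of the n2 patients still alive
at t1: each patient's residual survival time is drawn from the fitted model
left-truncated at t1, and administratively censored at the proposed new
cut-off t2.  Each simulated dataset is summarised by two statistics: the
number of observed events and the total additional person-time at risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .families import ParamVector, sample_truncated_batch
from .fitting import FittedModel, ModelSet

__all__ = ["FutureDataset", "SummaryStats", "draw_params",
           "draw_model_then_params", "generate_followup", "summarize",
           "simulate_followup_batch"]


@dataclass(frozen=True)
class FutureDataset:
    """One simulated follow-up dataset for one arm."""

    times: np.ndarray   # absolute months in (t1, t2]
    events: np.ndarray  # 1 = death observed in (t1, t2], 0 = censored at t2
    t1: float
    t2: float
    source_params: ParamVector | None = None
    k_index: int = -1

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=int)
        if len(times) != len(events):
            raise ValueError("times and events must have equal length")
        if np.any(times <= self.t1) or np.any(times > self.t2):
            raise ValueError("all follow-up times must lie in (t1, t2]")
        times.setflags(write=False)
        events.setflags(write=False)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self):
        """Audit view: one row per simulated patient (k, time, event)."""
        import pandas as pd

        return pd.DataFrame({"k": self.k_index, "time": self.times,
                             "event": self.events})


@dataclass(frozen=True)
class SummaryStats:
    events_count: int
    person_time: float  # months at risk accrued after t1


def draw_params(fit: FittedModel, k: int, rng: np.random.Generator) -> np.ndarray:
    """K draws from the bivariate normal parameter belief (transformed scale)."""
    cov = np.asarray(fit.cov)
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < 0:
        if eig.min() < -1e-10:
            raise ValueError("covariance is not positive semi-definite")
        cov = cov + (abs(eig.min()) + 1e-12) * np.eye(2)
    return rng.multivariate_normal(np.asarray(fit.mle.values), cov, size=k,
                                   method="cholesky" if eig.min() > 0 else "svd")


def draw_model_then_params(model_set: ModelSet, k: int,
                           rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Sample a model index with the prior weights, then its parameters.

    Returns (model_indices, theta_matrix) of shapes (k,) and (k, 2).
    """
    idx = rng.choice(len(model_set.fits), size=k, p=model_set.prior_weights)
    theta = np.empty((k, 2))
    for i, fit in enumerate(model_set.fits):
        sel = idx == i
        n = int(sel.sum())
        if n:
            theta[sel] = draw_params(fit, n, rng)
    return idx, theta


def generate_followup(params: ParamVector, n2: int, t1: float, t2: float,
                      rng: np.random.Generator, k_index: int = -1) -> FutureDataset:
    """Simulate one follow-up dataset: truncated sampling then censoring at t2."""
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    raw = sample_truncated_batch(params.family,
                                 np.asarray(params.values)[None, :], t1, n2, rng)[0]
    events = raw <= t2
    times = np.where(events, raw, t2)
    return FutureDataset(times, events.astype(int), t1, t2, params, k_index)


def summarize(fd: FutureDataset) -> SummaryStats:
    """Events and additional person-time (measured from t1) in one dataset."""
    return SummaryStats(int(fd.events.sum()), float(np.sum(fd.times - fd.t1)))


def simulate_followup_batch(family: str, theta: np.ndarray, n2: int, t1: float,
                            t2: float, rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Summary statistics for K simulated datasets, one per parameter draw.

    Returns (events, person_time) arrays of length K; person-time is measured
    from t1.  Row k uses parameter draw theta[k].
    """
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    raw = sample_truncated_batch(family, theta, t1, n2, rng)
    events = raw <= t2
    times = np.where(events, raw, t2)
    return events.sum(axis=1).astype(float), (times - t1).sum(axis=1)
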