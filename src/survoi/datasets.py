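"""Individual-patient survival data for one trial arm.

A dataset holds one row per participant: the observed time in months, an
event indicator (1 = death observed, 0 = administratively censored), and an
entry (left-truncation) time.  Entry is 0 for data collected from the start
of the trial; follow-up data collected on patients already alive at the
interim cut-off ``t1`` carry ``entry = t1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset", "read_csv", "write_csv"]


@dataclass(frozen=True)
class SurvivalDataset:
    times: np.ndarray
    events: np.ndarray
    entry: np.ndarray = None  # type: ignore[assignment]
    arm_label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=int)
        entry = (np.zeros_like(times) if self.entry is None
                 else np.asarray(self.entry, dtype=float))
        if not (len(times) == len(events) == len(entry)):
            raise ValueError("times, events and entry must have equal length")
        if not np.all((events == 0) | (events == 1)):
            raise ValueError("events must be 0/1")
        if np.any(times <= entry):
            raise ValueError("every observed time must exceed its entry time")
        for name, arr in (("times", times), ("events", events), ("entry", entry)):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def at_risk(self, t: float) -> int:
        """Participants still under observation and event-free just before t.

        A subject with an event at exactly t is counted at risk at t; a
        subject censored at exactly t is also still at risk at t.
        """
        t = float(t)
        if t < 0:
            raise ValueError("t must be non-negative")
        alive = (self.times > t) | ((self.times == t) & (self.events == 0))
        return int(np.sum(alive))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "event": self.events,
            "entry": self.entry,
            "arm": self.arm_label,
        })


def read_csv(path: str | Path, arm: str | None = None) -> SurvivalDataset:
    """Read a dataset from a headered CSV with columns time, event, entry, arm.

    If the file holds several arms, ``arm`` selects one.
    """
    df = pd.read_csv(path)
    required = {"time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected at least columns {sorted(required)}")
    if "arm" in df.columns and arm is not None:
        df = df[df["arm"] == arm]
        if df.empty:
            raise ValueError(f"{path}: no rows for arm {arm!r}")
    entry = df["entry"].to_numpy(float) if "entry" in df.columns else None
    label = arm if arm is not None else (
        str(df["arm"].iloc[0]) if "arm" in df.columns else "")
    return SurvivalDataset(df["time"].to_numpy(float),
                           df["event"].to_numpy(int), entry, label)


def write_csv(dataset: SurvivalDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)
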