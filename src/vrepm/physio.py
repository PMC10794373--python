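"""Autonomic and endocrine summaries.

Physiological channels (skin conductance level in microsiemens, heart rate
in bpm, respiratory rate in breaths/min) are reduced to a baseline mean
plus consecutive 30-s task-window means: a 30-s baseline and a 300-s task
yield 11 interval means.  Skin conductance is natural-log transformed at
the interval-mean level before statistics.  Salivary alpha-amylase enters
as a T0/T1/T2 triplet (U/mL) with a 25 U/mL detection limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import UsageError, DataError

CHANNELS = ("SCL", "HR", "RESP")
AMYLASE_DETECTION_LIMIT = 25.0  # U/mL


@dataclass
class PhysioSeries:
    """One channel's timestamped readings for one session.

    ``t`` is seconds from task onset; negative timestamps are baseline.
    """

    channel: str
    t: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise ValueError("t and values must have equal length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise DataError("timestamps must be strictly increasing")

    @classmethod
    def from_frame(cls, channel: str, df: pd.DataFrame) -> "PhysioSeries":
        return cls(channel, df["t"].to_numpy(), df["value"].to_numpy())


@dataclass
class IntervalSummary:
    """Ordered interval means: baseline first, then consecutive task windows."""

    channel: str
    interval_means: np.ndarray
    window: float
    baseline_window: float
    transform: str = "identity"  # or "ln"
    missing_intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.interval_means = np.asarray(self.interval_means, dtype=float)

    @property
    def n_intervals(self) -> int:
        return self.interval_means.size

    def labels(self) -> list[str]:
        labs = ["baseline"]
        for k in range(self.n_intervals - 1):
            labs.append(f"{int(k * self.window)}-{int((k + 1) * self.window)}s")
        return labs


def interval_means(
    series: PhysioSeries,
    baseline_window: float = 30.0,
    task_duration: float = 300.0,
    window: float = 30.0,
) -> IntervalSummary:
    """Reduce a channel to baseline + consecutive task-window means.

    Windows are half-open [start, end) so no sample is double-counted; an
    empty window yields NaN and is recorded in ``missing_intervals``.
    """
    n_task = int(round(task_duration / window))
    edges = [(-baseline_window, 0.0)] + [(k * window, (k + 1) * window) for k in range(n_task)]
    means = np.empty(len(edges))
    missing = []
    for i, (lo, hi) in enumerate(edges):
        sel = (series.t >= lo) & (series.t < hi)
        if not sel.any():
            means[i] = math.nan
            missing.append(i)
        else:
            means[i] = float(series.values[sel].mean())
    return IntervalSummary(
        series.channel, means, window, baseline_window, missing_intervals=missing
    )


def log_transform(summary: IntervalSummary) -> IntervalSummary:
    """Natural-log transform of skin conductance interval means."""
    if summary.channel != "SCL":
        raise UsageError("ln transform is defined for the SCL channel only")
    if summary.transform == "ln":
        raise UsageError("summary is already ln-transformed")
    means = summary.interval_means
    nonpos = np.flatnonzero(~np.isnan(means) & (means <= 0))
    if nonpos.size:
        raise UsageError(f"non-positive SCL mean in interval {int(nonpos[0])}")
    return replace(summary, interval_means=np.log(means), transform="ln")


@dataclass(frozen=True)
class AmylaseTriplet:
    """Salivary alpha-amylase before (T0), directly after (T1) and 15 min
    after (T2) behavioral testing, U/mL."""

    T0: float
    T1: float
    T2: float

    def __post_init__(self) -> None:
        for name in ("T0", "T1", "T2"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0")

    def below_detection(self) -> dict[str, bool]:
        return {k: getattr(self, k) < AMYLASE_DETECTION_LIMIT for k in ("T0", "T1", "T2")}


def amylase_deltas(triplet: AmylaseTriplet) -> tuple[float, float]:
    """(T1 - T0, T2 - T0); NaN when any used sample is below detection."""
    flags = triplet.below_detection()
    d1 = math.nan if flags["T0"] or flags["T1"] else triplet.T1 - triplet.T0
    d2 = math.nan if flags["T0"] or flags["T2"] else triplet.T2 - triplet.T0
    return d1, d2


def interval_table(summaries: dict) -> pd.DataFrame:
    """Wide per-session interval table from {(participant, exposure): IntervalSummary}."""
    rows = []
    for (pid, exposure), s in summaries.items():
        row = {"participant_id": pid, "exposure": exposure, "channel": s.channel}
        for lab, v in zip(s.labels(), s.interval_means):
            row[lab] = v
        rows.append(row)
    return pd.DataFrame(rows)
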