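"""Behavioral markers of approach-avoidance on the plus-maze.

All metrics operate on the task segment (t >= 0) of a uniformly resampled
trajectory.  Open-arm dwell time, open-arm entries and the two latencies are
the anxiety-related outcomes; closed-arm time/entries, total distance and
average velocities index locomotion.  Dwell sums assign one sample period
dt to the zone of each sample; latencies that never occur are censored at
the task duration and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .geometry import MazeGeometry, ZoneKind, classify_zones
from .trajectory import Trajectory

_ZONE_CODE = {ZoneKind.CENTER: 0, ZoneKind.OPEN: 1, ZoneKind.CLOSED: 2}


@dataclass(frozen=True)
class BehavioralSummary:
    """Per-session behavioral markers.

    Times in seconds, distance in metres, velocities in cm/s.  A velocity is
    NaN when no step had both endpoints inside the zone; a censored latency
    equals the task duration with the corresponding flag set.
    """

    time_open: float
    time_closed: float
    time_center: float
    entries_open: int
    entries_closed: int
    latency_first_open: float
    latency_end_exploration: float
    total_distance: float
    mean_velocity_open: float
    mean_velocity_closed: float
    censored_latency_first: bool
    censored_latency_end: bool

    def to_dict(self) -> dict:
        return asdict(self)


def _task_arrays(traj: Trajectory, geom: MazeGeometry):
    seg = traj.task_segment()
    if seg.empty:
        raise InsufficientDataError("trajectory has no task samples (t >= 0)")
    x = seg["x"].to_numpy()
    z = seg["z"].to_numpy()
    return seg["t"].to_numpy(), x, z, classify_zones(x, z, geom)


def dwell_times(traj: Trajectory, geom: MazeGeometry) -> tuple[float, float, float]:
    """(time_open, time_closed, time_center): dt per sample, summed per zone."""
    dt = traj.dt
    _, _, _, code = _task_arrays(traj, geom)
    return (
        float(np.count_nonzero(code == 1) * dt),
        float(np.count_nonzero(code == 2) * dt),
        float(np.count_nonzero(code == 0) * dt),
    )


def count_entries(traj: Trajectory, geom: MazeGeometry, zone_kind: ZoneKind) -> int:
    """Number of entries into arms of ``zone_kind``.

    An entry is a consecutive sample pair whose first sample is not on an
    arm of the given type and whose second sample is, pooling both arms of
    the type into one count.
    """
    if zone_kind is ZoneKind.CENTER:
        raise ValueError("entries are defined for OPEN or CLOSED arms only")
    _, _, _, code = _task_arrays(traj, geom)
    if code.size < 2:
        raise InsufficientDataError("need at least 2 task samples")
    k = _ZONE_CODE[zone_kind]
    inz = code == k
    return int(np.count_nonzero(~inz[:-1] & inz[1:]))


def latency_first_open(traj: Trajectory, geom: MazeGeometry) -> tuple[float, bool]:
    """Time of the first open-arm sample; censored at task duration if none."""
    t, _, _, code = _task_arrays(traj, geom)
    idx = np.flatnonzero(code == 1)
    if idx.size == 0:
        return float(traj.session.task_duration), True
    return float(t[idx[0]]), False


def latency_end_exploration(traj: Trajectory, geom: MazeGeometry) -> tuple[float, bool]:
    """Time of first reaching the distal end of an open arm (|z| >= end_threshold)."""
    t, _, z, _ = _task_arrays(traj, geom)
    idx = np.flatnonzero(np.abs(z) >= geom.end_threshold)
    if idx.size == 0:
        return float(traj.session.task_duration), True
    return float(t[idx[0]]), False


def total_distance(traj: Trajectory) -> float:
    """Horizontal-plane path length over the task segment, in metres."""
    seg = traj.task_segment()
    if len(seg) < 2:
        raise InsufficientDataError("need at least 2 task samples")
    dx = np.diff(seg["x"].to_numpy())
    dz = np.diff(seg["z"].to_numpy())
    return float(np.hypot(dx, dz).sum() / 100.0)


def mean_velocity(traj: Trajectory, geom: MazeGeometry, zone_kind: ZoneKind) -> float:
    """Mean per-step speed (cm/s) over steps with BOTH endpoints in the zone type.

    Returns NaN when no step qualifies.
    """
    if zone_kind is ZoneKind.CENTER:
        raise ValueError("velocities are defined for OPEN or CLOSED arms only")
    dt = traj.dt
    _, x, z, code = _task_arrays(traj, geom)
    if code.size < 2:
        raise InsufficientDataError("need at least 2 task samples")
    k = _ZONE_CODE[zone_kind]
    both = (code[:-1] == k) & (code[1:] == k)
    if not both.any():
        return math.nan
    speeds = np.hypot(np.diff(x), np.diff(z))[both] / dt
    return float(speeds.mean())


def summarize(traj: Trajectory, geom: MazeGeometry) -> BehavioralSummary:
    """Assemble all behavioral markers for one session."""
    t_open, t_closed, t_center = dwell_times(traj, geom)
    lat_first, cens_first = latency_first_open(traj, geom)
    lat_end, cens_end = latency_end_exploration(traj, geom)
    return BehavioralSummary(
        time_open=t_open,
        time_closed=t_closed,
        time_center=t_center,
        entries_open=count_entries(traj, geom, ZoneKind.OPEN),
        entries_closed=count_entries(traj, geom, ZoneKind.CLOSED),
        latency_first_open=lat_first,
        latency_end_exploration=lat_end,
        total_distance=total_distance(traj),
        mean_velocity_open=mean_velocity(traj, geom, ZoneKind.OPEN),
        mean_velocity_closed=mean_velocity(traj, geom, ZoneKind.CLOSED),
        censored_latency_first=cens_first,
        censored_latency_end=cens_end,
    )


def cohort_metrics_table(trajectories, geom: MazeGeometry) -> pd.DataFrame:
    """Score many sessions into a cohort table (one row per session).

    ``trajectories`` is an iterable of resampled :class:`Trajectory`; row keys
    come from each trajectory's session metadata.
    """
    rows = []
    for traj in trajectories:
        row = {
            "participant_id": traj.session.participant_id,
            "exposure": traj.session.exposure,
            "epm_version": traj.session.epm_version,
        }
        row.update(summarize(traj, geom).to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
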