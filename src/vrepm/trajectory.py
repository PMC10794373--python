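"""Reading, validation, resampling and writing of head-pose sessions.

A session is a stream of timestamped headset poses in the maze frame:
time in seconds from task onset (baseline samples carry negative time),
position in cm, orientation as yaw/pitch/roll in degrees.  The canonical
sampling rate is 5 Hz, so each sample contributes dt = 0.2 s to any
dwell-time sum.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, InsufficientDataError

POSE_COLUMNS = ["t", "x", "y", "z", "rx", "ry", "rz"]
DEFAULT_RATE_HZ = 5.0


@dataclass(frozen=True)
class SessionMeta:
    """Metadata identifying one participant-session."""

    participant_id: str
    exposure: int = 1  # 1 = first testing, 2 = second testing
    epm_version: str = "Sea"  # Sea | Desert | VideoGame
    task_duration: float = 300.0  # s of exploration after scene change
    baseline_duration: float = 30.0  # s of pre-task baseline recording

    def __post_init__(self) -> None:
        if self.exposure not in (1, 2):
            raise ValueError("exposure must be 1 or 2")
        if self.task_duration <= 0 or self.baseline_duration < 0:
            raise ValueError("invalid durations")


@dataclass
class QualityReport:
    """Per-session data-quality accounting produced during ingest/resample."""

    n_rows_read: int = 0
    n_dropped_nonfinite: int = 0
    gaps_over_1s: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


class Trajectory:
    """An ordered pose stream for one session.

    Wraps a DataFrame with columns ``t, x, y, z, rx, ry, rz``; timestamps
    strictly increasing.  ``sample_rate`` is set once the stream is on a
    uniform grid (None for raw, irregular input).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        session: SessionMeta,
        sample_rate: float | None = None,
        quality: QualityReport | None = None,
    ) -> None:
        missing = [c for c in POSE_COLUMNS if c not in data.columns]
        if missing:
            raise FormatError(f"missing pose columns: {missing}")
        data = data.loc[:, POSE_COLUMNS].reset_index(drop=True)
        t = data["t"].to_numpy()
        if len(t) and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise DataError(f"timestamps not strictly increasing at row {bad}")
        self.data = data
        self.session = session
        self.sample_rate = sample_rate
        self.quality = quality if quality is not None else QualityReport(n_rows_read=len(data))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.data[["x", "y", "z"]].to_numpy()

    @property
    def dt(self) -> float:
        if self.sample_rate is None:
            raise InsufficientDataError("trajectory is not on a uniform grid; resample first")
        return 1.0 / self.sample_rate

    def task_segment(self) -> pd.DataFrame:
        """Samples belonging to the exploration task (t >= 0)."""
        return self.data[self.data["t"] >= 0]


def read_trajectory(path, metadata: SessionMeta) -> Trajectory:
    """Read a delimited-text pose file (header ``t,x,y,z,rx,ry,rz``).

    Rows containing non-finite values are dropped and counted in the
    trajectory's quality report; duplicated or decreasing timestamps raise a
    :class:`DataError` naming the first offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[POSE_COLUMNS].astype(float)
    finite = np.isfinite(df.to_numpy()).all(axis=1)
    quality = QualityReport(n_rows_read=len(df), n_dropped_nonfinite=int((~finite).sum()))
    if quality.n_dropped_nonfinite:
        quality.notes.append(f"{quality.n_dropped_nonfinite} non-finite rows dropped")
    df = df[finite].reset_index(drop=True)
    t = df["t"].to_numpy()
    if len(t) > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise DataError(f"{path}: non-monotone timestamp at data row {int(bad[0]) + 1}")
    return Trajectory(df, metadata, quality=quality)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write the pose stream back to delimited text (round-trip safe)."""
    buf = io.StringIO()
    traj.data.to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue())


def write_session_meta(meta: SessionMeta, path) -> None:
    Path(path).write_text(json.dumps(asdict(meta), indent=1))


def read_session_meta(path) -> SessionMeta:
    return SessionMeta(**json.loads(Path(path).read_text()))


def _unwrap_deg(a: np.ndarray) -> np.ndarray:
    return np.degrees(np.unwrap(np.radians(a)))


def resample(traj: Trajectory, rate: float = DEFAULT_RATE_HZ) -> Trajectory:
    """Resample onto a uniform grid at ``rate`` Hz from first to last timestamp.

    Positions are linearly interpolated; orientation angles are unwrapped
    per component before interpolation so crossings of +-180 deg do not
    produce spurious swings.  Gaps longer than 1 s between input samples are
    flagged in the quality report but interpolated across nonetheless.
    """
    if len(traj) < 2:
        raise InsufficientDataError("resampling needs at least 2 samples")
    t = traj.t
    dt = 1.0 / rate
    n = int(np.floor((t[-1] - t[0]) / dt + 1e-9)) + 1
    grid = t[0] + dt * np.arange(n)
    out = {"t": grid}
    for c in ["x", "y", "z"]:
        out[c] = np.interp(grid, t, traj.data[c].to_numpy())
    for c in ["rx", "ry", "rz"]:
        out[c] = np.interp(grid, t, _unwrap_deg(traj.data[c].to_numpy()))
    quality = QualityReport(
        n_rows_read=traj.quality.n_rows_read,
        n_dropped_nonfinite=traj.quality.n_dropped_nonfinite,
        notes=list(traj.quality.notes),
    )
    gap_idx = np.flatnonzero(np.diff(t) > 1.0)
    for i in gap_idx:
        quality.gaps_over_1s.append((float(t[i]), float(t[i + 1])))
    if gap_idx.size:
        quality.notes.append(f"{gap_idx.size} gaps > 1 s interpolated across")
    return Trajectory(pd.DataFrame(out), traj.session, sample_rate=rate, quality=quality)
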