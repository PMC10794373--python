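"""Occupancy heatmaps over the maze floor.

Per-session maps accumulate dwell seconds into a square grid of 10 cm
patches spanning the full maze; cohort maps are per-participant means; the
difference map (second minus first exposure) localises where occupancy
shifted between testings.  Rows index the closed-arm axis (x), columns the
open-arm axis (z).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import IncompatibleMapsError, UsageError
from .geometry import MazeGeometry
from .trajectory import Trajectory


@dataclass
class OccupancyMap:
    grid: np.ndarray  # n_bins x n_bins dwell seconds (or mean s/participant)
    bin_size: float
    normalized: bool
    n_participants: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("grid must be square")

    @property
    def n_bins(self) -> int:
        return self.grid.shape[0]

    def total(self) -> float:
        return float(self.grid.sum())


def bin_index(coord, geom: MazeGeometry) -> np.ndarray | int:
    """Half-open 10 cm binning over [-extent_half, extent_half), clamped.

    index = floor((coord + extent_half) / bin_size); boundary and
    tracking-noise points outside the maze fall into the edge bins.
    """
    idx = np.floor((np.asarray(coord, dtype=float) + geom.extent_half) / geom.bin_size)
    idx = np.clip(idx, 0, geom.n_bins - 1).astype(int)
    return idx if idx.ndim else int(idx)


def accumulate(traj: Trajectory, geom: MazeGeometry) -> OccupancyMap:
    """Per-session map: each task sample adds one sample period dt to its cell."""
    seg = traj.task_segment()
    dt = traj.dt
    rows = bin_index(seg["x"].to_numpy(), geom)
    cols = bin_index(seg["z"].to_numpy(), geom)
    grid = np.zeros((geom.n_bins, geom.n_bins))
    np.add.at(grid, (rows, cols), dt)
    return OccupancyMap(grid, geom.bin_size, normalized=False, n_participants=1)


def cohort_mean(maps: list[OccupancyMap]) -> OccupancyMap:
    """Element-wise mean over per-participant maps (the cohort normalisation)."""
    if not maps:
        raise UsageError("cohort_mean needs at least one map")
    first = maps[0]
    for m in maps:
        if m.n_bins != first.n_bins or m.bin_size != first.bin_size:
            raise IncompatibleMapsError("maps have mixed geometry")
        if m.normalized:
            raise IncompatibleMapsError("cohort_mean expects unnormalized per-session maps")
    grid = np.mean([m.grid for m in maps], axis=0)
    return OccupancyMap(grid, first.bin_size, normalized=True, n_participants=len(maps))


def difference_map(second: OccupancyMap, first: OccupancyMap) -> OccupancyMap:
    """second - first on normalized cohort maps; entries may be negative."""
    if not (second.normalized and first.normalized):
        raise UsageError("difference_map expects normalized cohort maps")
    if second.n_bins != first.n_bins or second.bin_size != first.bin_size:
        raise IncompatibleMapsError("maps have mixed geometry")
    return OccupancyMap(
        second.grid - first.grid,
        second.bin_size,
        normalized=True,
        n_participants=min(second.n_participants, first.n_participants),
    )


def dwell_mask(occupancy: OccupancyMap, min_stay: float = 0.5) -> np.ndarray:
    """Cells with mean length of stay of at least ``min_stay`` seconds.

    Rendering aid only; inclusive threshold.
    """
    if min_stay < 0:
        raise ValueError("min_stay must be >= 0")
    if min_stay == 0:
        return occupancy.grid > 0
    return occupancy.grid >= min_stay


def write_map(occupancy: OccupancyMap, path) -> None:
    """Matrix as delimited text plus a JSON sidecar with binning metadata."""
    path = Path(path)
    np.savetxt(path, occupancy.grid, delimiter=",", fmt="%.10g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "bin_size_cm": occupancy.bin_size,
                "normalized": occupancy.normalized,
                "n_participants": occupancy.n_participants,
                "rows": "x (closed-arm axis)",
                "cols": "z (open-arm axis)",
            },
            indent=1,
        )
    )


def read_map(path) -> OccupancyMap:
    path = Path(path)
    grid = np.loadtxt(path, delimiter=",")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return OccupancyMap(grid, meta["bin_size_cm"], meta["normalized"], meta["n_participants"])


def plot_map(occupancy: OccupancyMap, ax=None, min_stay: float | None = None, **imshow_kw):
    """Render a map with matplotlib; difference maps get a diverging colormap."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = occupancy.grid.copy()
    if min_stay is not None:
        grid = np.where(dwell_mask(occupancy, min_stay), grid, np.nan)
    half = occupancy.bin_size * occupancy.n_bins / 2
    diverging = (occupancy.grid < 0).any()
    imshow_kw.setdefault("cmap", "RdBu" if diverging else "Greys")
    if diverging:
        vmax = float(np.nanmax(np.abs(grid))) or 1.0
        imshow_kw.setdefault("vmin", -vmax)
        imshow_kw.setdefault("vmax", vmax)
    im = ax.imshow(grid.T, origin="lower", extent=(-half, half, -half, half), **imshow_kw)
    ax.set_xlabel("x (closed arms) [cm]")
    ax.set_ylabel("z (open arms) [cm]")
    return im
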