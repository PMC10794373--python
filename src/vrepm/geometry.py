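"""Maze coordinate frame, physical dimensions and zone classification.

The plus-maze lives in a right-handed frame with its origin at the maze
center, the x-axis aligned with the two closed arms and the z-axis aligned
with the two open arms; y is vertical and plays no role in zone membership.
All lengths are centimetres.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, DataError


class ZoneKind(enum.Enum):
    CENTER = "center"
    OPEN = "open"
    CLOSED = "closed"


@dataclass(frozen=True)
class Zone:
    """Zone membership of a single maze-frame point.

    ``arm_sign`` distinguishes the two arms of a type (+1 along the positive
    axis, -1 along the negative axis) and is ``None`` exactly for the center.
    """

    kind: ZoneKind
    arm_sign: int | None = None

    def __post_init__(self) -> None:
        if (self.arm_sign is None) != (self.kind is ZoneKind.CENTER):
            raise ValueError("arm_sign must be None iff kind is CENTER")


@dataclass(frozen=True)
class MazeGeometry:
    """Physical maze dimensions, zone thresholds and heatmap binning.

    Parameters
    ----------
    arm_length : float
        Distance from maze center to an arm tip along its axis, cm.
    arm_width : float
        Arm width, cm.
    zone_threshold : float
        A point belongs to an arm when the absolute coordinate on that arm's
        axis exceeds this value, cm.  Default is half the arm width, i.e. the
        edge of the central square where the arms begin.
    end_threshold : float
        Axial distance beyond which a point counts as the distal end of an
        open arm, cm.
    bin_size : float
        Heatmap patch edge, cm.
    """

    arm_length: float = 175.0
    arm_width: float = 30.0
    zone_threshold: float = 15.0
    end_threshold: float = 160.0
    bin_size: float = 10.0

    def __post_init__(self) -> None:
        if self.arm_length <= 0 or self.arm_width <= 0:
            raise ValueError("arm dimensions must be positive")
        if not (0 < self.zone_threshold < self.end_threshold <= self.arm_length):
            raise ValueError(
                "need 0 < zone_threshold < end_threshold <= arm_length, got "
                f"{self.zone_threshold}, {self.end_threshold}, {self.arm_length}"
            )
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if (2 * self.extent_half) % self.bin_size != 0:
            raise ValueError("maze extent must be an integer number of bins")

    @property
    def extent_half(self) -> float:
        """Half side of the square bounding box; the maze spans [-h, h]^2."""
        return self.arm_length

    @property
    def n_bins(self) -> int:
        """Bins per heatmap axis; n_bins * bin_size spans the full maze."""
        return int(round(2 * self.extent_half / self.bin_size))


def make_default_geometry(**overrides) -> MazeGeometry:
    """Geometry of the physical maze: 175 cm arms, 30 cm wide, covering
    350 x 350 cm, binned into 35 x 35 patches of 10 cm."""
    return MazeGeometry(**overrides)


@dataclass(frozen=True)
class CalibrationTransform:
    """Rigid transform from the raw tracking frame into the maze frame.

    ``rotation`` must be orthonormal with determinant +1; ``translation``
    carries the maze center to the origin.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise CalibrationError("rotation must be 3x3 and translation length 3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8) or not math.isclose(
            float(np.linalg.det(r)), 1.0, abs_tol=1e-8
        ):
            raise CalibrationError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def inverse(self) -> "CalibrationTransform":
        rinv = self.rotation.T
        return CalibrationTransform(rinv, -rinv @ self.translation)

    @classmethod
    def from_yaw(cls, yaw_deg: float, translation=(0.0, 0.0, 0.0)) -> "CalibrationTransform":
        """Rotation about the vertical (y) axis by ``yaw_deg`` degrees."""
        a = math.radians(yaw_deg)
        c, s = math.cos(a), math.sin(a)
        rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
        return cls(rot, np.asarray(translation, dtype=float))


def to_maze_frame(raw_position, transform: CalibrationTransform) -> np.ndarray:
    """Map raw tracking coordinates (cm) into the maze frame.

    Accepts a single 3-vector or an (n, 3) array.
    """
    p = np.asarray(raw_position, dtype=float)
    return p @ transform.rotation.T + transform.translation


def classify_zone(position, geometry: MazeGeometry) -> Zone:
    """Classify a maze-frame point into CENTER / OPEN / CLOSED.

    Open arms run along z, closed arms along x; the vertical coordinate is
    ignored.  A tracking-noise point exceeding the threshold on both axes is
    resolved by the larger absolute coordinate, ties going to OPEN.
    """
    p = np.asarray(position, dtype=float)
    x, z = float(p[0]), float(p[-1])
    if not (math.isfinite(x) and math.isfinite(z)):
        raise DataError(f"non-finite coordinates ({x}, {z})")
    thr = geometry.zone_threshold
    on_open = abs(z) > thr
    on_closed = abs(x) > thr
    if on_open and on_closed:
        if abs(z) >= abs(x):
            return Zone(ZoneKind.OPEN, int(math.copysign(1, z)))
        return Zone(ZoneKind.CLOSED, int(math.copysign(1, x)))
    if on_open:
        return Zone(ZoneKind.OPEN, int(math.copysign(1, z)))
    if on_closed:
        return Zone(ZoneKind.CLOSED, int(math.copysign(1, x)))
    return Zone(ZoneKind.CENTER)


def classify_zones(x, z, geometry: MazeGeometry):
    """Vectorised zone classification for coordinate arrays.

    Returns an integer code array: 0 = CENTER, 1 = OPEN, 2 = CLOSED,
    matching :func:`classify_zone` point-wise (same both-axes tie-break).
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(z).all()):
        raise DataError("non-finite coordinates in trajectory")
    thr = geometry.zone_threshold
    ax, az = np.abs(x), np.abs(z)
    on_open = az > thr
    on_closed = ax > thr
    code = np.zeros(np.broadcast(x, z).shape, dtype=np.int8)
    code[on_open & ~on_closed] = 1
    code[on_closed & ~on_open] = 2
    both = on_open & on_closed
    code[both] = np.where(az[both] >= ax[both], 1, 2)
    return code
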