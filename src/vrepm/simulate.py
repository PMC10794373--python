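"""Synthetic cohorts with known ground truth.

The behavioral generator is a discrete-time arm-visit walker, not a model
of human gait: from the maze center the agent repeatedly chooses an arm —
open arms carry a choice weight 1/(1 + anxiety), closed arms weight 1 — or
re-enters the previously visited arm with probability ``dwell_persistence``,
walks out to a random depth at noisy speed, dwells, and returns.  The
generator only needs to span the behavioral metric space (zone occupancy,
threshold crossings, latencies, path length) so every downstream stage can
be validated against known latent traits.

Cohorts draw per-participant latent anxiety from a bivariate normal across
the two exposures with a configurable retest correlation, mirroring a
two-visit design (first testing on the Sea maze; second testing randomly
assigned Desert or VideoGame, 18/21 at n = 39).

The physiological generator emits baseline + task segments with an additive
task-onset response, optional anticipatory baseline elevation and
multiplicative sensitization at the second exposure, plus white noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import MazeGeometry, make_default_geometry
from .physio import PhysioSeries
from .trajectory import SessionMeta, Trajectory


@dataclass(frozen=True)
class AgentParams:
    """Latent behavioral parameters of one simulated participant."""

    anxiety: float = 1.0  # open-arm avoidance strength, >= 0
    step_speed_mean: float = 20.0  # cm/s, slow walking on a narrow beam
    step_speed_sd: float = 6.0
    dwell_persistence: float = 0.2  # P(repeat the previous arm at a choice)
    end_dwell_mean: float = 25.0  # s paused at an arm turning point
    center_dwell_mean: float = 6.0  # s paused at the center between visits

    def __post_init__(self) -> None:
        if self.anxiety < 0:
            raise ValueError("anxiety must be >= 0")
        if self.step_speed_mean <= 0:
            raise ValueError("step_speed_mean must be positive")
        if not 0 <= self.dwell_persistence < 1:
            raise ValueError("dwell_persistence must lie in [0, 1)")

    @property
    def open_weight(self) -> float:
        """Relative choice weight of each open arm (closed arms weigh 1)."""
        return 1.0 / (1.0 + self.anxiety)


@dataclass(frozen=True)
class CohortParams:
    """Two-exposure cohort design with a correlated latent anxiety trait.

    Latent anxiety is exp(trait) with trait bivariate normal across
    exposures; ``exposure2_shift`` adds a sensitization offset to the
    second-exposure trait.
    """

    n_participants: int = 39
    trait_mean: float = 0.0
    trait_sd: float = 2.0
    retest_correlation: float = 0.8
    exposure2_shift: float = 0.0
    speed_log_sd: float = 0.3  # between-participant locomotor trait (stable)
    dwell_log_sd: float = 0.4  # between-participant pausing trait (stable)
    version_split: tuple = (("Desert", 18), ("VideoGame", 21))

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not -1 <= self.retest_correlation <= 1:
            raise ValueError("retest_correlation must lie in [-1, 1]")


@dataclass(frozen=True)
class PhysioGenParams:
    """Generative parameters for one physiological channel."""

    channel: str = "SCL"
    baseline_level: float = 8.0  # channel units (e.g. microsiemens for SCL)
    onset_response: float = 2.0  # additive change at task onset
    anticipation: float = 0.0  # additive baseline elevation at exposure 2
    sensitization: float = 1.0  # multiplicative task-response factor at exposure 2
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def _walk_segment(p0, p1, speed_mean, speed_sd, dt, rng):
    """Positions along p0 -> p1 at per-step noisy speed (excludes p0)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = float(np.linalg.norm(p1 - p0))
    if length == 0:
        return np.empty((0, 2))
    direction = (p1 - p0) / length
    pts = []
    s = 0.0
    while s < length:
        step = max(rng.normal(speed_mean, speed_sd), 1.0) * dt
        s = min(s + step, length)
        pts.append(p0 + s * direction)
    return np.asarray(pts)


def simulate_trajectory(
    params: AgentParams,
    geom: MazeGeometry | None = None,
    duration: float = 300.0,
    rate: float = 5.0,
    seed: int | np.random.Generator = 0,
    session: SessionMeta | None = None,
) -> Trajectory:
    """Simulate one session as a sequence of arm visits.

    All positions lie on the plus-shaped walkable region; arm choice is
    weighted 1 per closed arm and 1/(1 + anxiety) per open arm, with
    probability ``dwell_persistence`` of revisiting the previous arm.
    Deterministic given the seed.
    """
    geom = geom or make_default_geometry()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1.0 / rate
    n_total = int(round(duration * rate))
    half_w = geom.arm_width / 2

    # arm axes: unit vectors in (x, z); open arms along z, closed along x
    arms = [
        ("open", np.array([0.0, 1.0])),
        ("open", np.array([0.0, -1.0])),
        ("closed", np.array([1.0, 0.0])),
        ("closed", np.array([-1.0, 0.0])),
    ]
    w_open = params.open_weight
    base_weights = np.array([w_open, w_open, 1.0, 1.0])

    pts: list[np.ndarray] = [np.zeros(2)]
    prev_arm: int | None = None
    while len(pts) < n_total + 1:
        if prev_arm is not None and rng.random() < params.dwell_persistence:
            arm = prev_arm
        else:
            arm = int(rng.choice(4, p=base_weights / base_weights.sum()))
        prev_arm = arm
        kind, axis = arms[arm]
        # avoidance shapes open-arm visits continuously: anxious agents
        # venture less far onto open arms and retreat sooner
        if kind == "open":
            if rng.random() < 0.5 * w_open:
                # full exploration out to the arm tip
                frac = rng.uniform(0.92, 1.0)
            else:
                frac = 0.9 * rng.random() ** (1.0 / max(w_open, 1e-6))
            dwell_mean = params.end_dwell_mean * (0.2 + 0.8 * w_open)
        else:
            frac = rng.random()
            dwell_mean = params.end_dwell_mean
        depth = geom.arm_width + (geom.arm_length - geom.arm_width) * frac
        lateral = rng.uniform(-half_w * 0.8, half_w * 0.8)
        perp = np.array([-axis[1], axis[0]])
        target = axis * depth + perp * lateral
        here = pts[-1]
        out = _walk_segment(here, target, params.step_speed_mean, params.step_speed_sd, dt, rng)
        pts.extend(out)
        n_dwell = rng.poisson(dwell_mean / dt)
        pts.extend([target] * n_dwell)
        back = _walk_segment(target, np.zeros(2), params.step_speed_mean,
                             params.step_speed_sd, dt, rng)
        pts.extend(back)
        n_cdwell = rng.poisson(params.center_dwell_mean / dt)
        pts.extend([np.zeros(2)] * n_cdwell)

    xz = np.asarray(pts[:n_total])
    t = dt * np.arange(n_total)
    head_height = 165.0 + rng.normal(0, 1.5, n_total)  # cm, posture sway
    yaw = np.degrees(np.arctan2(np.gradient(xz[:, 1]), np.gradient(xz[:, 0])))
    data = pd.DataFrame(
        {
            "t": t,
            "x": xz[:, 0],
            "y": head_height,
            "z": xz[:, 1],
            "rx": yaw,
            "ry": rng.normal(0, 3.0, n_total),
            "rz": rng.normal(0, 2.0, n_total),
        }
    )
    meta = session or SessionMeta(participant_id="sim", task_duration=duration)
    return Trajectory(data, meta, sample_rate=rate)


def _latent_traits(params: CohortParams, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) latent anxiety traits with the configured retest correlation."""
    r = params.retest_correlation
    cov = params.trait_sd**2 * np.array([[1.0, r], [r, 1.0]])
    traits = rng.multivariate_normal([params.trait_mean] * 2, cov, size=params.n_participants)
    traits[:, 1] += params.exposure2_shift
    return traits


def simulate_cohort(
    params: CohortParams,
    agent_defaults: AgentParams | None = None,
    geom: MazeGeometry | None = None,
    duration: float = 300.0,
    rate: float = 5.0,
    seed: int = 0,
):
    """Simulate a two-exposure cohort.

    Returns ``(trajectories, ground_truth)`` where ``trajectories`` maps
    (participant_id, exposure) to a :class:`Trajectory` and ``ground_truth``
    is a DataFrame of latent traits (anxiety = exp(trait)) and version
    assignments.
    """
    geom = geom or make_default_geometry()
    agent_defaults = agent_defaults or AgentParams()
    rng = np.random.default_rng(seed)
    traits = _latent_traits(params, rng)

    versions = []
    for name, count in params.version_split:
        versions.extend([name] * count)
    if len(versions) < params.n_participants:  # pad proportionally if n differs
        reps = math.ceil(params.n_participants / max(len(versions), 1))
        versions = (versions * reps)
    versions = np.array(versions[: params.n_participants])
    rng.shuffle(versions)

    # stable locomotor traits: each participant keeps their walking speed and
    # pausing tendency across both exposures
    speed_factor = np.exp(rng.normal(0.0, params.speed_log_sd, params.n_participants))
    dwell_factor = np.exp(rng.normal(0.0, params.dwell_log_sd, params.n_participants))

    trajectories = {}
    truth_rows = []
    for i in range(params.n_participants):
        pid = f"P{i + 1:03d}"
        for exposure in (1, 2):
            anxiety = float(np.exp(traits[i, exposure - 1]))
            agent = AgentParams(
                anxiety=anxiety,
                step_speed_mean=agent_defaults.step_speed_mean * speed_factor[i],
                step_speed_sd=agent_defaults.step_speed_sd,
                dwell_persistence=agent_defaults.dwell_persistence,
                end_dwell_mean=agent_defaults.end_dwell_mean * dwell_factor[i],
                center_dwell_mean=agent_defaults.center_dwell_mean * dwell_factor[i],
            )
            version = "Sea" if exposure == 1 else str(versions[i])
            meta = SessionMeta(pid, exposure=exposure, epm_version=version,
                               task_duration=duration)
            trajectories[(pid, exposure)] = simulate_trajectory(
                agent, geom, duration, rate, seed=rng, session=meta
            )
        truth_rows.append(
            {
                "participant_id": pid,
                "trait_exposure1": traits[i, 0],
                "trait_exposure2": traits[i, 1],
                "anxiety_exposure1": float(np.exp(traits[i, 0])),
                "anxiety_exposure2": float(np.exp(traits[i, 1])),
                "speed_factor": float(speed_factor[i]),
                "dwell_factor": float(dwell_factor[i]),
                "epm_version_second": str(versions[i]),
            }
        )
    return trajectories, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# physiology generation
# ---------------------------------------------------------------------------

def simulate_physio(
    params: PhysioGenParams,
    exposure: int = 1,
    duration: float = 300.0,
    baseline_duration: float = 30.0,
    rate: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> PhysioSeries:
    """Simulate one channel: baseline level (plus anticipation at exposure 2),
    then baseline + onset response (times the sensitization factor at
    exposure 2), with additive white noise.  Deterministic given the seed."""
    if exposure not in (1, 2):
        raise ValueError("exposure must be 1 or 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1.0 / rate
    t = np.arange(-baseline_duration, duration, dt)
    base = params.baseline_level + (params.anticipation if exposure == 2 else 0.0)
    response = params.onset_response * (params.sensitization if exposure == 2 else 1.0)
    level = np.where(t < 0, base, base + response)
    noise = rng.normal(0.0, params.noise_sd, t.size) if params.noise_sd > 0 else 0.0
    return PhysioSeries(params.channel, t, level + noise)
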