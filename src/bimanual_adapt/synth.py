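"""Synthetic bimanual curl-field experiments.

This module generates complete synthetic datasets for the paradigm in
which a velocity-dependent curl force field acts on the left hand but is
driven by the *right* hand's velocity:

    [Fx, Fy]_left = [[0, -B], [B, 0]] @ [vx, vy]_right

with curl gain ``B`` = 13 N·s/m.  For a forward reach (vy > 0) the field
pushes the left hand leftward (Fx < 0); perfect compensation is therefore
``+B * vy_right``.  On error-clamp (channel) trials a stiff virtual wall
(stiffness K, damping D) suppresses lateral motion so the lateral force
the simulated participant presses into the wall can be recorded.

Reaches are minimum-jerk trajectories along +y.  The duration of each
reach is rescaled so that the noise-free peak speed equals the class's
desired peak speed (peak speed, not duration, is the experimentally
controlled quantity: all three classes share distance/peak-speed ratios,
so the rescaled duration is identical across classes).

The simulated participant is a single-rate state-space learner: a
compensation gain ``alpha`` is updated on every force-field trial as

    alpha <- a * alpha + b * (1 - alpha)

(retention ``a``, learning rate ``b``, asymptote ``b / (1 - a + b)``) and
held on clamp and null-field trials, where the movement error is (near)
zero.  The learner's predictive lateral force follows a weighted encoding
of the two hands' forward velocities,

    F_cmd = alpha * B * (omega * v_right + (1 - omega) * v_left),

with ground-truth weight ``omega`` fixed per participant (1 = pure
right-hand encoding, 0 = pure left-hand encoding, 0.5 = average).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .design import (CONDITIONS, SPEED_CLASSES, Condition, GroupDesign,
                     ScheduleEntry, SpeedClass, build_schedule)

DT = 0.001  # s, 1 kHz sampling


@dataclass(frozen=True)
class FieldParams:
    """Robot force-field and channel parameters (SI units)."""

    curl_gain: float = 13.0           # B, N·s/m
    channel_stiffness: float = 6000.0  # K, N/m
    channel_damping: float = 20.0      # D, N·s/m

    def __post_init__(self) -> None:
        if self.curl_gain <= 0 or self.channel_stiffness <= 0 or self.channel_damping < 0:
            raise ValueError("require B > 0, K > 0, D >= 0")


@dataclass(frozen=True)
class KinematicsConfig:
    """Reach-generation parameters.

    peak_speed_cv
        Coefficient of variation of the multiplicative peak-speed noise.
        The default 0.05 keeps ~95% of draws inside the ±10% compliance
        band.
    right_hand_lead_ms
        The right hand starts moving this many ms before the left in
        bimanual trials (matched-speed reaches in humans show a small
        dominant-hand lead; no published magnitude, 20 ms chosen as a
        plausible default).
    pre_ms / post_ms
        Stationary recording before movement onset (needed by the force
        drift-correction window) and after movement end.
    """

    peak_speed_cv: float = 0.05
    right_hand_lead_ms: float = 20.0
    pre_ms: float = 300.0
    post_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.peak_speed_cv < 0:
            raise ValueError("peak_speed_cv must be >= 0")
        if self.right_hand_lead_ms < 0 or self.pre_ms < 0 or self.post_ms < 0:
            raise ValueError("timing parameters must be >= 0")


@dataclass(frozen=True)
class LearnerConfig:
    """Parameters of the single-rate adaptive learner."""

    retention: float = 0.99        # a
    learning_rate: float = 0.04    # b; asymptote b/(1-a+b) = 0.8 at defaults
    omega: float = 0.5             # ground-truth encoding weight
    alpha0: float = 0.0
    execution_noise_sd: float = 0.3   # N, white noise on commanded force
    force_drift_sd: float = 0.1       # N, constant per-trial force offset
    clamp_update: bool = False        # if True, alpha also updates on clamp trials

    def __post_init__(self) -> None:
        if not (0 < self.retention <= 1):
            raise ValueError("retention must lie in (0, 1]")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.execution_noise_sd < 0 or self.force_drift_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def asymptote(self) -> float:
        """Fixed point of the update rule, b / (1 - a + b)."""
        denom = 1 - self.retention + self.learning_rate
        return 0.0 if denom == 0 else self.learning_rate / denom


@dataclass
class LearnerState:
    """Current compensation gain of a simulated participant."""

    alpha: float
    config: LearnerConfig

    def updated(self) -> "LearnerState":
        c = self.config
        return LearnerState(c.retention * self.alpha
                            + c.learning_rate * (1 - self.alpha), c)


@dataclass(frozen=True)
class PlantConfig:
    """Optional lateral point-mass plant for kinematic-error simulation.

    When enabled, the left hand's lateral (x) position on null and
    force-field trials follows ``m x'' = F_field + F_cmd - c x'`` — a
    deliberately crude stand-in for limb impedance that produces leftward
    path errors early in exposure which shrink as the learner adapts.
    """

    mass: float = 1.5      # kg
    damping: float = 60.0  # N·s/m


@dataclass
class TrialRecord:
    """One trial: labels plus 1 kHz time-series for both hands.

    Arrays share a single time grid (``t_ms``).  ``force`` holds the
    measured left-hand force: the commanded (pressed-into-the-wall) force
    on clamp trials, the robot-applied field force on force-field trials
    and zero on null trials.  Right-hand velocity is identically zero in
    unimanual trials.
    """

    participant: int
    group: str
    trial: int
    phase: str
    block: int
    condition: str
    field_type: str
    t_ms: np.ndarray       # (n,)
    left_pos: np.ndarray   # (n, 2) m
    left_vel: np.ndarray   # (n, 2) m/s
    right_pos: np.ndarray  # (n, 2)
    right_vel: np.ndarray  # (n, 2)
    force: np.ndarray      # (n, 2) N, measured on the left handle

    @property
    def n_samples(self) -> int:
        return self.t_ms.shape[0]

    @property
    def bimanual(self) -> bool:
        return self.condition.startswith("b")


def minimum_jerk_speed(tau: np.ndarray, distance: float, duration: float) -> np.ndarray:
    """Minimum-jerk speed profile on normalised time ``tau`` in [0, 1].

    v(tau) = (d / T) * (30 tau^2 - 60 tau^3 + 30 tau^4); the peak,
    1.875 d/T, occurs at tau = 0.5 and the time integral equals d.
    """
    return (distance / duration) * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)


def generate_velocity_profile(
    speed_class: SpeedClass | str,
    noise_cv: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    dt: float = DT,
) -> np.ndarray:
    """Forward-speed series (m/s) for one reach of the given class.

    The profile is minimum-jerk with the duration rescaled so the
    noise-free peak speed equals ``desired_peak`` (a fixed 700 ms
    minimum-jerk reach would peak at only 1.875·d/0.7 ≈ 67 cm/s for the
    long reach, outside the compliance band).  With noise, the peak speed
    is multiplied by a normal draw centred on 1 with sd ``noise_cv``
    (duration shrinks/stretches accordingly, so the distance travelled is
    preserved).
    """
    if isinstance(speed_class, str):
        speed_class = SPEED_CLASSES[speed_class]
    d, vp = speed_class.distance, speed_class.desired_peak
    if d <= 0 or vp <= 0:
        raise ValueError("distance and peak speed must be positive")
    if noise_cv > 0:
        if rng is None:
            raise ValueError("rng required when noise_cv > 0")
        scale = rng.normal(1.0, noise_cv)
        scale = max(scale, 0.2)  # guard against absurd draws
        vp = vp * scale
    duration = 1.875 * d / vp
    n = int(round(duration / dt)) + 1
    tau = np.linspace(0.0, 1.0, n)
    return minimum_jerk_speed(tau, d, duration)


def apply_force_field(right_velocity: np.ndarray, B: float = 13.0) -> np.ndarray:
    """Curl-field force on the left hand from the right hand's velocity.

    ``right_velocity`` is an (n, 2) array of (vx, vy) in m/s; returns the
    (n, 2) force [[0, -B], [B, 0]] @ v applied sample-wise, in N.
    """
    v = np.asarray(right_velocity, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("right_velocity must have shape (n, 2)")
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity series must be finite")
    return np.column_stack([-B * v[:, 1], B * v[:, 0]])


def commanded_force(
    state: LearnerState,
    left_speed: np.ndarray,
    right_speed: np.ndarray,
    B: float,
) -> np.ndarray:
    """Noise-free predictive lateral force of the learner (N)."""
    c = state.config
    return state.alpha * B * (c.omega * right_speed + (1 - c.omega) * left_speed)


def simulate_learner_trial(
    state: LearnerState,
    left_speed: np.ndarray,
    right_speed: np.ndarray,
    field_type: str,
    field: FieldParams = FieldParams(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, LearnerState, np.ndarray]:
    """Simulate one trial of the learner.

    Returns ``(predictive lateral force, updated state, measured force)``
    where the measured force is the (n, 2) left-handle force recorded by
    the robot: on clamp trials the channel renders the reaction to the
    commanded force, on force-field trials the robot-applied field is
    recorded, on null trials zero.
    """
    left_speed = np.asarray(left_speed, dtype=float)
    right_speed = np.asarray(right_speed, dtype=float)
    if left_speed.shape != right_speed.shape:
        raise ValueError("hand speed series must share one grid")
    n = left_speed.shape[0]
    cfg = state.config
    cmd = commanded_force(state, left_speed, right_speed, field.curl_gain)
    if rng is not None and cfg.execution_noise_sd > 0:
        cmd = cmd + rng.normal(0.0, cfg.execution_noise_sd, n)

    measured = np.zeros((n, 2))
    if field_type == "clamp":
        drift = 0.0
        if rng is not None and cfg.force_drift_sd > 0:
            drift = rng.normal(0.0, cfg.force_drift_sd)
        measured[:, 0] = cmd + drift
        new_state = state.updated() if cfg.clamp_update else state
    elif field_type == "force_field":
        right_vel = np.column_stack([np.zeros(n), right_speed])
        measured = apply_force_field(right_vel, field.curl_gain)
        new_state = state.updated()
    elif field_type == "null":
        new_state = state
    else:
        raise ValueError(f"unknown field_type {field_type!r}")
    return cmd, new_state, measured


def _lateral_plant(net_force: np.ndarray, plant: PlantConfig, dt: float = DT
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the lateral point-mass plant; returns (x, vx)."""
    n = net_force.shape[0]
    x = np.zeros(n)
    vx = np.zeros(n)
    for i in range(1, n):
        ax = (net_force[i - 1] - plant.damping * vx[i - 1]) / plant.mass
        vx[i] = vx[i - 1] + ax * dt
        x[i] = x[i - 1] + vx[i - 1] * dt
    return x, vx


def _embed(move: np.ndarray, start: int, total: int) -> np.ndarray:
    """Place a movement-speed segment into a zero-padded trial grid."""
    out = np.zeros(total)
    out[start:start + move.shape[0]] = move
    return out


def simulate_trial(
    entry: ScheduleEntry,
    state: LearnerState,
    kin: KinematicsConfig,
    field: FieldParams,
    rng: np.random.Generator,
    participant: int,
    group: str,
    plant: Optional[PlantConfig] = None,
) -> tuple[TrialRecord, LearnerState]:
    """Simulate one schedule entry into a TrialRecord."""
    cond: Condition = CONDITIONS[entry.condition]
    noise_cv = kin.peak_speed_cv
    left_move = generate_velocity_profile(cond.left, noise_cv, rng)
    right_move = (generate_velocity_profile(cond.right, noise_cv, rng)
                  if cond.bimanual else None)

    n_pre = int(round(kin.pre_ms / 1000.0 / DT))
    n_post = int(round(kin.post_ms / 1000.0 / DT))
    lead = int(round(kin.right_hand_lead_ms / 1000.0 / DT)) if cond.bimanual else 0
    left_start = n_pre + lead
    right_start = n_pre
    n_move = max(left_start + left_move.shape[0],
                 right_start + (right_move.shape[0] if right_move is not None else 0))
    n = n_move + n_post

    left_speed = _embed(left_move, left_start, n)
    right_speed = (_embed(right_move, right_start, n)
                   if right_move is not None else np.zeros(n))

    cmd, new_state, measured = simulate_learner_trial(
        state, left_speed, right_speed, entry.field_type, field, rng)

    left_vel = np.column_stack([np.zeros(n), left_speed])
    right_vel = np.column_stack([np.zeros(n), right_speed])
    if plant is not None and entry.field_type != "clamp":
        # net lateral load = robot-applied field (measured) + muscle command
        net = measured[:, 0] + cmd
        x, vx = _lateral_plant(net, plant)
        left_vel[:, 0] = vx
        left_x = x
    else:
        left_x = np.zeros(n)

    left_pos = np.column_stack([left_x, np.cumsum(left_speed) * DT])
    right_pos = np.column_stack([np.zeros(n), np.cumsum(right_speed) * DT])
    t_ms = np.arange(n, dtype=float)

    rec = TrialRecord(
        participant=participant, group=group, trial=entry.trial,
        phase=entry.phase, block=entry.block, condition=entry.condition,
        field_type=entry.field_type, t_ms=t_ms,
        left_pos=left_pos, left_vel=left_vel,
        right_pos=right_pos, right_vel=right_vel, force=measured,
    )
    return rec, new_state


def simulate_participant(
    group_design: GroupDesign | str,
    participant: int,
    seed: int,
    learner: LearnerConfig = LearnerConfig(),
    kin: KinematicsConfig = KinematicsConfig(),
    field: FieldParams = FieldParams(),
    plant: Optional[PlantConfig] = None,
) -> list[TrialRecord]:
    """Simulate one participant's full 2208-trial experiment."""
    if isinstance(group_design, str):
        group_design = GroupDesign(group_design)
    ss = np.random.SeedSequence(seed)
    sched_seed_ss, noise_ss = ss.spawn(2)
    sched_seed = int(sched_seed_ss.generate_state(1)[0] % (2**31))
    schedule = build_schedule(group_design, sched_seed)
    rng = np.random.default_rng(noise_ss)
    state = LearnerState(learner.alpha0, learner)
    records: list[TrialRecord] = []
    for entry in schedule:
        rec, state = simulate_trial(entry, state, kin, field, rng,
                                    participant, group_design.group, plant)
        records.append(rec)
    return records


def iter_participants(
    group_design: GroupDesign | str,
    n_participants: int,
    seed: int,
    learner: LearnerConfig = LearnerConfig(),
    kin: KinematicsConfig = KinematicsConfig(),
    field: FieldParams = FieldParams(),
    plant: Optional[PlantConfig] = None,
    first_participant: int = 1,
) -> Iterator[list[TrialRecord]]:
    """Yield one participant's trial list at a time (memory-friendly)."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if isinstance(group_design, str):
        group_design = GroupDesign(group_design)
    children = np.random.SeedSequence(seed).spawn(n_participants)
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        yield simulate_participant(group_design, first_participant + i,
                                   sub_seed, learner, kin, field, plant)


def simulate_experiment(
    group_design: GroupDesign | str,
    n_participants: int = 1,
    seed: int = 0,
    learner: LearnerConfig = LearnerConfig(),
    kin: KinematicsConfig = KinematicsConfig(),
    field: FieldParams = FieldParams(),
    plant: Optional[PlantConfig] = None,
) -> list[TrialRecord]:
    """Simulate a cohort; returns the flattened list of TrialRecords.

    Each participant gets an independent sub-seed split from ``seed``;
    identical arguments reproduce identical datasets.  For large cohorts
    prefer :func:`iter_participants` and process one participant at a
    time.
    """
    out: list[TrialRecord] = []
    for records in iter_participants(group_design, n_participants, seed,
                                     learner, kin, field, plant):
        out.extend(records)
    return out


def default_learner_for_group(group: str, **overrides) -> LearnerConfig:
    """Learner defaults calibrated to each training regime.

    The evident group converges to strong right-hand encoding
    (omega ≈ 0.9); the ambiguous group to mixed encoding with a left-hand
    tendency (omega ≈ 0.4).
    """
    omega = {"evident": 0.9, "ambiguous": 0.4}.get(group)
    if omega is None:
        raise ValueError(f"unknown group {group!r}")
    params = dict(omega=omega)
    params.update(overrides)
    return LearnerConfig(**params)
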