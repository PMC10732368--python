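"""Signal conditioning and force-profile extraction.

Measured forces (and optionally kinematics) are low-pass filtered with a
zero-phase 5th-order Butterworth at 40 Hz.  Clamp-trial forces are
corrected for slow transducer/posture drift by subtracting the mean
lateral force over the window 200–150 ms before movement onset.  Clamp
trials are then reduced to an :class:`AlignedForceProfile`: the left-hand
lateral force resampled onto a fixed ±400 ms window centred on the
reference hand's peak speed (right hand in bimanual trials, left hand in
unimanual trials), together with the two hands' forward-speed series on
the same grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import signal

from .synth import DT, TrialRecord

FS_HZ = 1.0 / DT
HALF_WINDOW_MS = 400  # alignment window half-width
WINDOW_SAMPLES = 2 * HALF_WINDOW_MS + 1  # 801 at 1 kHz


@dataclass
class AlignedForceProfile:
    """Left-hand lateral force on a fixed grid around peak speed.

    ``lag_ms`` runs from -400 to +400 ms (801 samples at 1 kHz) around
    the reference hand's peak-speed sample.  Samples outside the recorded
    trial are padded with the trial's first/last (rest) value and flagged
    in ``padded`` so downstream fits can exclude them.
    """

    force: np.ndarray        # (801,) N, lateral (x) force
    left_speed: np.ndarray   # (801,) m/s forward speed, same grid
    right_speed: np.ndarray  # (801,)
    padded: np.ndarray       # (801,) bool
    reference_hand: str      # "right" or "left"
    center_ms: float         # peak-speed time in trial coordinates
    participant: int = 0
    trial: int = 0
    phase: str = ""
    block: int = 0
    condition: str = ""

    @property
    def lag_ms(self) -> np.ndarray:
        return np.arange(-HALF_WINDOW_MS, HALF_WINDOW_MS + 1, dtype=float)


def lowpass_filter(series: np.ndarray, order: int = 5, cutoff_hz: float = 40.0,
                   fs_hz: float = FS_HZ) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    DC gain is 1 and the phase response is zero, so peaks are not
    shifted in time.  Raises if the series is too short for stable
    forward-backward filtering (length must exceed 3x the filter order).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    padlen = 3 * (order + 1)
    if x.shape[0] <= max(3 * order, padlen):
        raise ValueError(f"series too short to filter (need > {padlen} samples)")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    return signal.sosfiltfilt(sos, x)


def hand_speed(trial: TrialRecord, hand: str) -> np.ndarray:
    vel = trial.left_vel if hand == "left" else trial.right_vel
    return np.hypot(vel[:, 0], vel[:, 1])


def detect_movement_onset(trial: TrialRecord, hand: str = "left",
                          threshold_frac: float = 0.05) -> float:
    """Movement onset (ms): first sample whose speed exceeds a fraction
    of that trial's peak speed (default 5%), searching forward from the
    trial start."""
    if not (0 < threshold_frac < 1):
        raise ValueError("threshold_frac must lie in (0, 1)")
    speed = hand_speed(trial, hand)
    peak = speed.max()
    if peak <= 0:
        raise ValueError("cannot detect onset: hand never moves")
    idx = int(np.argmax(speed > threshold_frac * peak))
    return float(trial.t_ms[idx])


def remove_force_drift(trial: TrialRecord, onset_ms: Optional[float] = None
                       ) -> TrialRecord:
    """Subtract pre-movement lateral force bias from a clamp trial.

    The mean lateral force over [onset - 200 ms, onset - 150 ms] is
    subtracted from the whole lateral-force series; repeating the
    operation is a no-op.  Requires at least 200 ms of pre-onset
    recording.
    """
    if trial.field_type != "clamp":
        raise ValueError("drift correction applies to clamp trials")
    if onset_ms is None:
        onset_ms = detect_movement_onset(trial)
    i0 = int(round((onset_ms - 200.0) / 1000.0 * FS_HZ))
    i1 = int(round((onset_ms - 150.0) / 1000.0 * FS_HZ))
    if i0 < 0:
        raise ValueError("insufficient pre-onset samples for drift window")
    bias = float(trial.force[i0:i1 + 1, 0].mean())
    force = trial.force.copy()
    force[:, 0] = force[:, 0] - bias
    return dataclasses.replace(trial, force=force)


def reference_hand_for(trial: TrialRecord) -> str:
    """Right hand for bimanual trials, left hand for unimanual trials."""
    return "right" if trial.bimanual else "left"


def align_to_peak_velocity(trial: TrialRecord,
                           reference_hand: Optional[str] = None
                           ) -> AlignedForceProfile:
    """Clip the lateral force to ±400 ms around the reference hand's
    peak speed.

    Ties in peak speed are broken by the earliest sample.  Window samples
    that fall outside the recording are filled with the first/last
    recorded value and marked in ``padded``.
    """
    if reference_hand is None:
        reference_hand = reference_hand_for(trial)
    if reference_hand == "right" and not trial.bimanual:
        raise ValueError("unimanual trial has no right-hand movement to align to")
    speed = hand_speed(trial, reference_hand)
    if speed.max() <= 0:
        raise ValueError(f"{reference_hand} hand never moves in this trial")
    center = int(np.argmax(speed))  # argmax returns the first maximum

    n = trial.n_samples
    idx = np.arange(center - HALF_WINDOW_MS, center + HALF_WINDOW_MS + 1)
    padded = (idx < 0) | (idx >= n)
    clipped = np.clip(idx, 0, n - 1)

    left = hand_speed(trial, "left")
    right = hand_speed(trial, "right")
    return AlignedForceProfile(
        force=trial.force[clipped, 0],
        left_speed=left[clipped],
        right_speed=right[clipped],
        padded=padded,
        reference_hand=reference_hand,
        center_ms=float(trial.t_ms[center]),
        participant=trial.participant, trial=trial.trial, phase=trial.phase,
        block=trial.block, condition=trial.condition,
    )


def peak_force(profile: AlignedForceProfile, half_window_ms: int = 10) -> float:
    """Mean lateral force over a 20 ms window centred on peak speed.

    "Around peak velocity" is read as a total width of 20 ms (±10 ms);
    pass ``half_window_ms=20`` for the wider reading.
    """
    c = HALF_WINDOW_MS
    return float(profile.force[c - half_window_ms:c + half_window_ms + 1].mean())


def preprocess_clamp_trial(trial: TrialRecord, filter_force: bool = True,
                           drift_correct: bool = True) -> AlignedForceProfile:
    """Filter, drift-correct and align one clamp trial."""
    if filter_force:
        force = trial.force.copy()
        force[:, 0] = lowpass_filter(force[:, 0])
        trial = dataclasses.replace(trial, force=force)
    if drift_correct:
        trial = remove_force_drift(trial)
    return align_to_peak_velocity(trial)


def extract_clamp_profiles(trials: Iterable[TrialRecord],
                           filter_force: bool = True,
                           drift_correct: bool = True
                           ) -> list[AlignedForceProfile]:
    """Aligned force profiles for every clamp trial in a dataset."""
    return [preprocess_clamp_trial(t, filter_force, drift_correct)
            for t in trials if t.field_type == "clamp"]
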