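"""Trial-level adaptation measures.

Two measures index adaptation to the curl field:

* **Maximum perpendicular error (MPE)** — the signed largest deviation of
  the left-hand path from the straight line joining the start and target
  centres, on null and force-field trials.  Positive values are leftward
  of the line for a forward reach, the direction the field pushes.
* **Force compensation (FC)** — on clamp trials, the slope (in %) of a
  through-origin linear regression of the measured lateral force on the
  perfect-compensation profile ``+B * v_right``.  100% means the
  participant fully opposes the field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .design import CONDITIONS
from .preprocess import AlignedForceProfile
from .synth import TrialRecord


@dataclass(frozen=True)
class MPEResult:
    trial: int
    mpe_cm: float  # signed; positive = leftward of the start->target line


@dataclass(frozen=True)
class FCResult:
    trial: int
    fc_percent: float


def max_perpendicular_error(
    trial: TrialRecord,
    start: Optional[Sequence[float]] = None,
    target: Optional[Sequence[float]] = None,
) -> MPEResult:
    """Signed maximum perpendicular error of the left-hand path, in cm.

    The deviation is measured from the straight line connecting the
    start and target centres; the returned value is the sample of
    largest absolute deviation, signed so that leftward deviations (for
    a forward reach) are positive.  By default the start is the first
    recorded left-hand position and the target lies one reach length
    further along +y (the simulator's geometry); pass explicit points
    for recorded data.
    """
    if trial.field_type == "clamp":
        raise ValueError("MPE is defined on null and force-field trials")
    path = trial.left_pos
    if start is None:
        start = path[0]
    start = np.asarray(start, dtype=float)
    if target is None:
        distance = CONDITIONS[trial.condition].left.distance
        target = start + np.array([0.0, distance])
    target = np.asarray(target, dtype=float)
    line = target - start
    norm = float(np.hypot(*line))
    if norm == 0:
        raise ValueError("degenerate start->target line")
    u = line / norm
    d = path - start
    # z-component of u x d: positive to the left of the line direction
    perp = u[0] * d[:, 1] - u[1] * d[:, 0]
    i = int(np.argmax(np.abs(perp)))
    return MPEResult(trial.trial, float(perp[i]) * 100.0)


def perfect_compensation_profile(profile: AlignedForceProfile,
                                 B: float = 13.0) -> np.ndarray:
    """Force profile that would exactly oppose the field: ``+B * v_right``.

    Undefined for unimanual trials (the right hand is stationary and no
    field is ever applied), which raise.
    """
    v = profile.right_speed
    if not np.any(v):
        raise ValueError("perfect compensation undefined: right hand stationary")
    return B * v


def force_compensation(measured: np.ndarray, perfect: np.ndarray,
                       exclude: Optional[np.ndarray] = None,
                       intercept: bool = False) -> float:
    """Force compensation in %, via linear regression of measured on
    perfect force.

    The default regression is through the origin (slope = sum(m*p) /
    sum(p^2)); drift correction has already removed constant offsets, so
    an intercept would only absorb noise.  Set ``intercept=True`` for an
    ordinary regression whose slope is reported instead.  ``exclude``
    masks samples (e.g. window padding) out of the fit.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(perfect, dtype=float)
    if m.shape != p.shape:
        raise ValueError("profiles must have equal length")
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        m, p = m[keep], p[keep]
    denom = float(p @ p)
    if denom == 0:
        raise ValueError("force compensation undefined: perfect profile is zero")
    if intercept:
        slope = np.polyfit(p, m, 1)[0]
    else:
        slope = float(m @ p) / denom
    return 100.0 * float(slope)


def force_compensation_for(profile: AlignedForceProfile, B: float = 13.0,
                           intercept: bool = False) -> FCResult:
    """FC of one aligned clamp-trial profile, excluding padded samples."""
    perfect = perfect_compensation_profile(profile, B)
    fc = force_compensation(profile.force, perfect, exclude=profile.padded,
                            intercept=intercept)
    return FCResult(profile.trial, fc)


def bin_series(values: Sequence[float], bin_size: int = 12
               ) -> tuple[np.ndarray, np.ndarray]:
    """Means over consecutive non-overlapping bins of trials.

    Returns ``(means, partial)`` where ``partial`` flags a trailing bin
    with fewer than ``bin_size`` values (still averaged).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    v = np.asarray(values, dtype=float)
    n_bins = int(np.ceil(v.shape[0] / bin_size))
    means = np.empty(n_bins)
    partial = np.zeros(n_bins, dtype=bool)
    for i in range(n_bins):
        chunk = v[i * bin_size:(i + 1) * bin_size]
        means[i] = chunk.mean()
        partial[i] = chunk.shape[0] < bin_size
    return means, partial
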