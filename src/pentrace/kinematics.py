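"""Per-sample kinematic signals and their statistical summaries.

From the raw x/y trajectory we derive, per movement type (on-surface or
in-air), twelve vector signals: speed ("velocity"), its vertical and
horizontal components, acceleration, vertical/horizontal acceleration, jerk,
vertical/horizontal jerk, and — on-surface only — the raw pressure, altitude
and azimuth channels.  Derivatives are first-order forward differences on
the actual timestamps (robust to uneven sampling) and are computed strictly
within a segment: no difference ever straddles a pen lift, so a k-th
derivative contributes ``max(n_i - k, 0)`` samples per segment of length
``n_i``.

Conventions, fixed for reproducibility:

* velocity = Euclidean norm of the component derivatives; acceleration is
  the derivative of that scalar speed, jerk the derivative of acceleration;
* vertical/horizontal *velocity* is summarized as a magnitude (overall
  change of per-axis position), while component accelerations and jerks are
  successive derivatives of the *signed* component velocities
  (``signed_component_velocity=True`` switches the velocity summaries to
  signed values as well);
* vector summaries report mean, median, population standard deviation,
  maximum, minimum and the 5th/95th percentiles (linear interpolation
  between order statistics) — the tail percentiles are kept because the raw
  extrema are outlier-sensitive;
* timestamps are milliseconds, so derived units are device units per second
  (per s², per s³).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, EmptyMovementError, ValidationError
from .io import IN_AIR, ON_SURFACE, TaskRecording
from .segmentation import Segment, split_segments

#: Derived (differentiated) signals, canonical order.
DERIVED_SIGNALS = (
    "velocity", "vertical_velocity", "horizontal_velocity",
    "acceleration", "vertical_acceleration", "horizontal_acceleration",
    "jerk", "vertical_jerk", "horizontal_jerk",
)
#: Raw device channels, defined for on-surface movement only.
CHANNEL_SIGNALS = ("pressure", "altitude", "azimuth")
#: All twelve vector signals of an on-surface bundle.
ALL_SIGNALS = DERIVED_SIGNALS + CHANNEL_SIGNALS


@dataclass
class SignalVector:
    """A named vector signal concatenated across segments.

    ``segment_boundaries`` holds the start index of each segment's run
    within ``values`` (derivative continuity is broken there).
    """

    name: str
    values: np.ndarray
    segment_boundaries: tuple[int, ...]


@dataclass
class KinematicBundle:
    """The vector signals of one recording restricted to one movement type.

    In-air bundles omit pressure/altitude/azimuth: the device does not
    record them while the pen hovers.
    """

    movement: str
    signals: dict[str, SignalVector]

    def __getitem__(self, name: str) -> SignalVector:
        return self.signals[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.signals)


def finite_difference(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """First-order forward difference Δvalue/Δtime with time in integer or
    float milliseconds; the result is per second.  Returns length n-1."""
    values = np.asarray(values, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if len(values) != len(times):
        raise ValidationError(
            f"values ({len(values)}) and times ({len(times)}) differ in length"
        )
    if len(values) < 2:
        raise DegenerateInputError("need at least 2 samples to differentiate")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValidationError("timestamps must be strictly increasing")
    return np.diff(values) / (dt / 1000.0)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + len(values)]
    return out


def _segment_derivatives(seg: Segment, signed: bool, smoothing_window: int
                         ) -> dict[str, np.ndarray]:
    """Derived signals within one segment (no cross-gap differences)."""
    out = {name: np.empty(0) for name in DERIVED_SIGNALS}
    if seg.n_samples < 2:
        return out
    x = _smooth(seg.x, smoothing_window)
    y = _smooth(seg.y, smoothing_window)
    t = seg.t
    vx = finite_difference(x, t)
    vy = finite_difference(y, t)
    speed = np.hypot(vx, vy)
    out["velocity"] = speed
    out["vertical_velocity"] = vy if signed else np.abs(vy)
    out["horizontal_velocity"] = vx if signed else np.abs(vx)
    if seg.n_samples >= 3:
        tv = t[:-1]  # forward-difference samples sit at the interval starts
        out["acceleration"] = finite_difference(speed, tv)
        out["vertical_acceleration"] = finite_difference(vy, tv)
        out["horizontal_acceleration"] = finite_difference(vx, tv)
    if seg.n_samples >= 4:
        ta = t[:-2]
        out["jerk"] = finite_difference(out["acceleration"], ta)
        out["vertical_jerk"] = finite_difference(out["vertical_acceleration"], ta)
        out["horizontal_jerk"] = finite_difference(out["horizontal_acceleration"], ta)
    return out


def compute_kinematics(
    rec: TaskRecording,
    movement: str = ON_SURFACE,
    *,
    smoothing_window: int = 0,
    signed_component_velocity: bool = False,
) -> KinematicBundle:
    """Derive the kinematic bundle of ``rec`` for one movement type.

    Raises :class:`EmptyMovementError` when the recording has no segment of
    the requested movement.  Segments too short for a given derivative order
    simply contribute no samples to that signal, so a signal's vector may be
    empty even when segments exist.
    """
    on, air = split_segments(rec)
    segments = on if movement == ON_SURFACE else air
    if movement not in (ON_SURFACE, IN_AIR):
        raise ValidationError(f"unknown movement {movement!r}")
    if not segments:
        raise EmptyMovementError(
            f"recording {rec.task_id!r} has no {movement} segment"
        )
    pieces: dict[str, list[np.ndarray]] = {name: [] for name in DERIVED_SIGNALS}
    boundaries: dict[str, list[int]] = {name: [] for name in ALL_SIGNALS}
    for seg in segments:
        per_seg = _segment_derivatives(seg, signed_component_velocity, smoothing_window)
        for name in DERIVED_SIGNALS:
            boundaries[name].append(sum(len(p) for p in pieces[name]))
            pieces[name].append(per_seg[name])
    signals = {
        name: SignalVector(
            name=name,
            values=np.concatenate(pieces[name]) if pieces[name] else np.empty(0),
            segment_boundaries=tuple(boundaries[name]),
        )
        for name in DERIVED_SIGNALS
    }
    if movement == ON_SURFACE:
        offset = 0
        bounds = []
        chans = {name: [] for name in CHANNEL_SIGNALS}
        for seg in segments:
            bounds.append(offset)
            offset += seg.n_samples
            chans["pressure"].append(seg.pressure)
            chans["altitude"].append(seg.altitude)
            chans["azimuth"].append(seg.azimuth)
        for name in CHANNEL_SIGNALS:
            signals[name] = SignalVector(
                name=name,
                values=np.concatenate(chans[name]),
                segment_boundaries=tuple(bounds),
            )
    return KinematicBundle(movement=movement, signals=signals)


#: Vector-summary statistics, canonical order.
SUMMARY_STATS = ("mean", "median", "std", "max", "min", "p05", "p95")


@dataclass(frozen=True)
class VectorSummary:
    """The seven summary statistics of a vector signal."""

    mean: float
    median: float
    std: float
    max: float
    min: float
    p05: float
    p95: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, s) for s in SUMMARY_STATS)


def summarize_vector(v: np.ndarray) -> VectorSummary:
    """Mean, median, population std, max, min and the 5th/95th percentiles
    (linear interpolation) of a non-empty finite vector."""
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise DegenerateInputError("cannot summarize an empty vector")
    if not np.all(np.isfinite(v)):
        raise ValidationError("vector contains non-finite values")
    p05, p95 = np.percentile(v, [5.0, 95.0])
    return VectorSummary(
        mean=float(np.mean(v)),
        median=float(np.median(v)),
        std=float(np.std(v)),  # population form
        max=float(np.max(v)),
        min=float(np.min(v)),
        p05=float(p05),
        p95=float(p95),
    )


def count_local_extrema(v: np.ndarray) -> int:
    """Number of strict local extrema after collapsing equal-value plateaus:
    a flat stretch bounded by opposite-sign slopes counts as one extremum."""
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise DegenerateInputError("cannot count extrema of an empty vector")
    if v.size < 3:
        return 0
    keep = np.concatenate(([True], np.diff(v) != 0))
    w = v[keep]
    if w.size < 3:
        return 0
    d = np.diff(w)
    return int(np.sum(d[:-1] * d[1:] < 0))


__all__ = [
    "DERIVED_SIGNALS", "CHANNEL_SIGNALS", "ALL_SIGNALS",
    "SignalVector", "KinematicBundle",
    "finite_difference", "compute_kinematics",
    "SUMMARY_STATS", "VectorSummary", "summarize_vector",
    "count_local_extrema",
]
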