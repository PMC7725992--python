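"""On-surface / in-air segmentation and segment-level geometry.

A *segment* is a maximal run of consecutive samples sharing one contact
state — the continuous movement between a pen-down and the next pen-up (or
vice versa).  This is deliberately distinct from the ballistic *stroke* of
the handwriting literature.  A *pen lift* is an on-surface → in-air
transition of the contact flag.

Besides per-segment geometry (duration, path length and its vertical and
horizontal components, bounding-box width and height) this module computes
the row-drift ("inclination") scalars: signed differences between
per-segment y-position statistics of the first vs last and second vs
penultimate segments, and the variance of those statistics across all
segments.  Children who fail to keep their writing on the row produce large
values here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .io import IN_AIR, ON_SURFACE, TaskRecording


@dataclass
class Segment:
    """A maximal same-contact-state run of samples.

    Arrays are views into the parent recording; ``index`` is the ordinal
    position among segments of the same movement type, ``start`` the 0-based
    offset of the first sample in the recording.
    """

    movement: str  # ON_SURFACE | IN_AIR
    index: int
    start: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray
    azimuth: np.ndarray
    altitude: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.t)


def split_segments(rec: TaskRecording) -> tuple[list[Segment], list[Segment]]:
    """Partition a recording into maximal constant-contact runs.

    Returns ``(on_surface_segments, in_air_segments)``.  Concatenating all
    segments in start order reproduces the recording exactly; the counts of
    the two types differ by at most one.
    """
    flags = rec.on_surface
    n = len(flags)
    if n == 0:
        return [], []
    boundaries = np.flatnonzero(np.diff(flags) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [n]))
    on: list[Segment] = []
    air: list[Segment] = []
    for a, b in zip(starts, stops):
        movement = ON_SURFACE if flags[a] == 1 else IN_AIR
        bucket = on if movement == ON_SURFACE else air
        bucket.append(
            Segment(
                movement=movement,
                index=len(bucket),
                start=int(a),
                t=rec.t[a:b],
                x=rec.x[a:b],
                y=rec.y[a:b],
                pressure=rec.pressure[a:b],
                azimuth=rec.azimuth[a:b],
                altitude=rec.altitude[a:b],
            )
        )
    return on, air


def count_pen_lifts(rec: TaskRecording) -> int:
    """Number of on-surface → in-air transitions of the contact flag."""
    f = rec.on_surface
    return int(np.sum((f[:-1] == 1) & (f[1:] == 0)))


def count_pen_returns(rec: TaskRecording) -> int:
    """Number of in-air → on-surface transitions (the in-air mirror of a
    pen lift)."""
    f = rec.on_surface
    return int(np.sum((f[:-1] == 0) & (f[1:] == 1)))


#: Segment-geometry measures in canonical order.
GEOMETRY_MEASURES = ("duration", "length", "vertical_length", "horizontal_length",
                     "width", "height")


@dataclass(frozen=True)
class SegmentGeometry:
    """Size measures of one segment.

    duration is seconds; the four lengths are device units — ``length`` sums
    Euclidean steps, ``vertical_length``/``horizontal_length`` sum absolute
    per-axis steps (path-length components), while ``width``/``height`` are
    bounding-box extents.  A single-sample segment has all measures zero.
    """

    duration: float
    length: float
    vertical_length: float
    horizontal_length: float
    width: float
    height: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, m) for m in GEOMETRY_MEASURES)


def segment_geometry(seg: Segment) -> SegmentGeometry:
    if seg.n_samples == 0:
        raise DegenerateInputError("segment has no samples")
    if seg.n_samples == 1:
        return SegmentGeometry(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    dx = np.diff(seg.x)
    dy = np.diff(seg.y)
    return SegmentGeometry(
        duration=float(seg.t[-1] - seg.t[0]) / 1000.0,
        length=float(np.sum(np.hypot(dx, dy))),
        vertical_length=float(np.sum(np.abs(dy))),
        horizontal_length=float(np.sum(np.abs(dx))),
        width=float(np.max(seg.x) - np.min(seg.x)),
        height=float(np.max(seg.y) - np.min(seg.y)),
    )


#: Statistics applied to each geometry measure across segments.
SEGMENT_STATS = ("mean", "median", "std", "max", "min")


def summarize_segments(geoms: list[SegmentGeometry]) -> dict[str, dict[str, float]]:
    """Across-segment mean / median / population std / max / min of each of
    the six geometry measures (30 values for a task)."""
    if not geoms:
        raise DegenerateInputError("no segment geometries to summarize")
    grid = np.array([g.as_tuple() for g in geoms], dtype=np.float64)
    out: dict[str, dict[str, float]] = {}
    for j, measure in enumerate(GEOMETRY_MEASURES):
        col = grid[:, j]
        out[measure] = {
            "mean": float(np.mean(col)),
            "median": float(np.median(col)),
            "std": float(np.std(col)),  # population form
            "max": float(np.max(col)),
            "min": float(np.min(col)),
        }
    return out


#: y-position statistics entering the inclination features, canonical order.
Y_STATS = ("min", "median", "mean", "max")


@dataclass(frozen=True)
class InclinationFeatures:
    """Row-drift scalars: for each per-segment y statistic (min, median,
    mean, max), the signed first-minus-last segment difference, the signed
    second-minus-penultimate difference, and the population variance across
    all segments.

    Fallbacks keep downstream feature matrices finite: with fewer than two
    segments every value is 0; with fewer than four segments the
    second-vs-penultimate differences are 0.
    """

    diff_end: dict[str, float]
    diff_preend: dict[str, float]
    var_y: dict[str, float]


def _y_stats(seg: Segment) -> dict[str, float]:
    y = seg.y
    return {
        "min": float(np.min(y)),
        "median": float(np.median(y)),
        "mean": float(np.mean(y)),
        "max": float(np.max(y)),
    }


def inclination_features(segments: list[Segment]) -> InclinationFeatures:
    if not segments:
        raise DegenerateInputError("no segments for inclination features")
    stats = [_y_stats(s) for s in segments]
    n = len(stats)
    zero = {k: 0.0 for k in Y_STATS}
    if n < 2:
        return InclinationFeatures(dict(zero), dict(zero), dict(zero))
    diff_end = {k: stats[0][k] - stats[-1][k] for k in Y_STATS}
    if n < 4:
        diff_preend = dict(zero)
    else:
        diff_preend = {k: stats[1][k] - stats[-2][k] for k in Y_STATS}
    var_y = {
        k: float(np.var([s[k] for s in stats]))  # population variance
        for k in Y_STATS
    }
    return InclinationFeatures(diff_end, diff_preend, var_y)


__all__ = [
    "Segment", "split_segments", "count_pen_lifts", "count_pen_returns",
    "GEOMETRY_MEASURES", "SegmentGeometry", "segment_geometry",
    "SEGMENT_STATS", "summarize_segments",
    "Y_STATS", "InclinationFeatures", "inclination_features",
]
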