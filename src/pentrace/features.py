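"""Canonical per-task feature vectors, session merging and standardization.

One handwriting task yields 133 on-surface features:

* 12 vector signals x 7 statistics = 84 (speed, vertical/horizontal speed,
  acceleration and its components, jerk and its components, pressure,
  altitude, azimuth; mean/median/std/max/min/p05/p95);
* 6 segment-geometry measures x 5 statistics = 30 (duration, length,
  vertical/horizontal length, width, height; mean/median/std/max/min);
* 19 scalars: pen lifts, counts of local speed and acceleration extrema,
  total duration, total length, total vertical and horizontal length, and
  the twelve row-drift scalars (4 first-vs-last y differences, 4
  second-vs-penultimate y differences, 4 across-segment y variances).

The in-air vector drops the three device channels that are only recorded
while the pen touches the surface (pressure, altitude, azimuth: 3 x 7 = 21),
leaving 112 features; every other feature is computed over the in-air
segments, with "pen lifts" read as in-air -> on-surface returns.  A complete
eight-task session merges, task-major in template order, into
8 x 133 + 112 = 1176 features (the in-air block is extracted for the
sentence task only — for the shorter tasks in-air movement carries no
predictive benefit).

Degenerate inputs never produce NaNs: a feature whose defining vector is
empty (e.g. jerk when every segment is too short) falls back to 0 and is
listed in the vector's degeneracy flags, so downstream classifiers always
see finite matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import segmentation as seg
from .errors import DegenerateInputError, SchemaError, ValidationError
from .io import IN_AIR, ON_SURFACE, TASK_IDS, Session, TaskRecording

#: Tasks whose in-air movement is extracted in the merged session vector.
IN_AIR_TASKS = ("sentence",)

_SCALAR_NAMES = (
    ("pen_lifts", "n_velocity_extrema", "n_acceleration_extrema",
     "total_duration", "total_length", "total_vertical_length",
     "total_horizontal_length")
    + tuple(f"diff_end__{s}" for s in seg.Y_STATS)
    + tuple(f"diff_preend__{s}" for s in seg.Y_STATS)
    + tuple(f"var_y__{s}" for s in seg.Y_STATS)
)


def feature_registry(movement: str = ON_SURFACE) -> tuple[str, ...]:
    """The canonical ordered feature names for one movement type: 133
    on-surface, 112 in-air.  Stable across runs and versions — merged-matrix
    column indices depend on it."""
    if movement not in (ON_SURFACE, IN_AIR):
        raise ValidationError(f"unknown movement {movement!r}")
    signals = kin.ALL_SIGNALS if movement == ON_SURFACE else kin.DERIVED_SIGNALS
    names = [f"{s}__{stat}" for s in signals for stat in kin.SUMMARY_STATS]
    names += [
        f"seg_{measure}__{stat}"
        for measure in seg.GEOMETRY_MEASURES
        for stat in seg.SEGMENT_STATS
    ]
    names += list(_SCALAR_NAMES)
    return tuple(names)


@dataclass
class FeatureVector:
    """Named, ordered feature values for one task (or one merged session).

    ``degenerate`` lists the names whose value came from a fallback rule
    rather than a real computation (empty signal, too few segments, ...).
    """

    names: tuple[str, ...]
    values: np.ndarray
    degenerate: frozenset[str] = frozenset()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != len(self.values):
            raise ValidationError("names and values differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def extract_task_features(
    rec: TaskRecording,
    movement: str = ON_SURFACE,
    *,
    smoothing_window: int = 0,
    signed_component_velocity: bool = False,
) -> FeatureVector:
    """Compute the full per-task feature vector for one movement type.

    A recording with no segment of the requested movement yields an all-zero
    vector with every name flagged degenerate, keeping session matrices
    rectangular and finite.
    """
    registry = feature_registry(movement)
    values: dict[str, float] = {}
    flagged: set[str] = set()

    on, air = seg.split_segments(rec)
    segments = on if movement == ON_SURFACE else air
    if not segments:
        return FeatureVector(registry, np.zeros(len(registry)),
                             frozenset(registry))

    bundle = kin.compute_kinematics(
        rec, movement,
        smoothing_window=smoothing_window,
        signed_component_velocity=signed_component_velocity,
    )
    for name in bundle.names:
        vec = bundle[name].values
        if vec.size == 0:
            for stat in kin.SUMMARY_STATS:
                values[f"{name}__{stat}"] = 0.0
                flagged.add(f"{name}__{stat}")
        else:
            summary = kin.summarize_vector(vec)
            for stat, val in zip(kin.SUMMARY_STATS, summary.as_tuple()):
                values[f"{name}__{stat}"] = val

    geoms = [seg.segment_geometry(s) for s in segments]
    for measure, stats in seg.summarize_segments(geoms).items():
        for stat, val in stats.items():
            values[f"seg_{measure}__{stat}"] = val

    if movement == ON_SURFACE:
        values["pen_lifts"] = float(seg.count_pen_lifts(rec))
    else:
        values["pen_lifts"] = float(seg.count_pen_returns(rec))
    for scalar, signal in (("n_velocity_extrema", "velocity"),
                           ("n_acceleration_extrema", "acceleration")):
        vec = bundle[signal].values
        if vec.size == 0:
            values[scalar] = 0.0
            flagged.add(scalar)
        else:
            values[scalar] = float(kin.count_local_extrema(vec))
    values["total_duration"] = float(sum(g.duration for g in geoms))
    values["total_length"] = float(sum(g.length for g in geoms))
    values["total_vertical_length"] = float(sum(g.vertical_length for g in geoms))
    values["total_horizontal_length"] = float(sum(g.horizontal_length for g in geoms))

    incl = seg.inclination_features(segments)
    if len(segments) < 2:
        flagged.update(f"diff_end__{s}" for s in seg.Y_STATS)
        flagged.update(f"var_y__{s}" for s in seg.Y_STATS)
    if len(segments) < 4:
        flagged.update(f"diff_preend__{s}" for s in seg.Y_STATS)
    for s in seg.Y_STATS:
        values[f"diff_end__{s}"] = incl.diff_end[s]
        values[f"diff_preend__{s}"] = incl.diff_preend[s]
        values[f"var_y__{s}"] = incl.var_y[s]

    vec = np.array([values[name] for name in registry])
    expected = 133 if movement == ON_SURFACE else 112
    assert len(registry) == expected, "feature registry arithmetic broken"
    return FeatureVector(registry, vec, frozenset(flagged))


def merge_session_features(
    session: Session,
    *,
    smoothing_window: int = 0,
    signed_component_velocity: bool = False,
) -> FeatureVector:
    """Concatenate the eight on-surface task vectors plus the sentence
    in-air vector into the 1176-feature session vector, task-major in
    template order, names prefixed ``task.movement.feature``."""
    session.require_tasks(TASK_IDS)
    names: list[str] = []
    values: list[np.ndarray] = []
    flagged: set[str] = set()
    blocks = [(task, ON_SURFACE) for task in TASK_IDS]
    blocks += [(task, IN_AIR) for task in IN_AIR_TASKS]
    for task, movement in blocks:
        fv = extract_task_features(
            session.recordings[task], movement,
            smoothing_window=smoothing_window,
            signed_component_velocity=signed_component_velocity,
        )
        prefix = f"{task}.{movement}."
        names.extend(prefix + n for n in fv.names)
        values.append(fv.values)
        flagged.update(prefix + n for n in fv.degenerate)
    return FeatureVector(tuple(names), np.concatenate(values), frozenset(flagged))


# ---------------------------------------------------------------------------
# Feature matrices and standardization
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Rectangular subjects x features grid with optional binary labels
    (positive class = "dysgraphia")."""

    subject_ids: tuple[str, ...]
    columns: tuple[str, ...]
    values: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.subject_ids), len(self.columns)):
            raise ValidationError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.columns)} columns"
            )
        if len(set(self.columns)) != len(self.columns):
            raise ValidationError("column names are not unique")
        if self.labels is not None:
            if len(self.labels) != len(self.subject_ids):
                raise ValidationError("labels and subjects differ in length")
            bad = set(self.labels) - {"dysgraphia", "control"}
            if bad:
                raise ValidationError(f"labels must be binary, got extra {bad}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def y(self) -> np.ndarray:
        """0/1 label vector (1 = dysgraphia)."""
        if self.labels is None:
            raise ValidationError("feature matrix carries no labels")
        return np.array([1 if lab == "dysgraphia" else 0 for lab in self.labels])

    @classmethod
    def from_vectors(cls, subject_ids: Sequence[str],
                     vectors: Sequence[FeatureVector],
                     labels: Sequence[str] | None = None) -> "FeatureMatrix":
        if not vectors:
            raise DegenerateInputError("no feature vectors")
        columns = vectors[0].names
        for v in vectors[1:]:
            if v.names != columns:
                raise SchemaError("feature vectors have differing schemas")
        return cls(
            subject_ids=tuple(subject_ids),
            columns=columns,
            values=np.vstack([v.values for v in vectors]),
            labels=tuple(labels) if labels is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.columns))
        df.insert(0, "subject_id", list(self.subject_ids))
        if self.labels is not None:
            df.insert(1, "label", list(self.labels))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        if "subject_id" not in df.columns:
            raise SchemaError("frame lacks a subject_id column")
        labels = tuple(df["label"]) if "label" in df.columns else None
        feature_cols = [c for c in df.columns if c not in ("subject_id", "label")]
        return cls(
            subject_ids=tuple(str(s) for s in df["subject_id"]),
            columns=tuple(feature_cols),
            values=df[feature_cols].to_numpy(dtype=np.float64),
            labels=labels,
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class StandardizationStats:
    """Per-column mean and population std fitted on a training matrix;
    zero-variance columns are flagged and mapped to 0 on application."""

    columns: tuple[str, ...]
    mean: np.ndarray
    std: np.ndarray
    zero_variance: np.ndarray  # boolean mask

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        self.zero_variance = np.asarray(self.zero_variance, dtype=bool)
        k = len(self.columns)
        if not (len(self.mean) == len(self.std) == len(self.zero_variance) == k):
            raise ValidationError("standardization stats lengths differ from columns")
        if np.any(self.std < 0):
            raise ValidationError("negative standard deviation")


def fit_standardizer(m: FeatureMatrix) -> StandardizationStats:
    """Column means and population stds for z-scoring; needs >= 2 rows."""
    if m.n_subjects < 2:
        raise DegenerateInputError("need at least 2 rows to fit a standardizer")
    mean = np.mean(m.values, axis=0)
    std = np.std(m.values, axis=0)  # population form
    return StandardizationStats(
        columns=m.columns, mean=mean, std=std, zero_variance=(std == 0.0)
    )


def apply_standardizer(m: FeatureMatrix, s: StandardizationStats) -> FeatureMatrix:
    """Z-score ``m`` with statistics fitted elsewhere (never refit here:
    applying train-fold statistics to test folds is the caller's contract).
    Zero-variance columns map to 0."""
    if m.columns != s.columns:
        raise SchemaError("matrix columns do not match standardizer columns")
    safe_std = np.where(s.zero_variance, 1.0, s.std)
    z = (m.values - s.mean) / safe_std
    z[:, s.zero_variance] = 0.0
    return FeatureMatrix(
        subject_ids=m.subject_ids, columns=m.columns, values=z, labels=m.labels
    )


def feature_weight_report(
    weights: Mapping[str, float],
    *,
    aggregate_tasks: bool = True,
) -> pd.DataFrame:
    """Turn an externally computed feature-weight vector (e.g. from a
    feature-selection algorithm) keyed by registry names into a ranked
    report.

    With ``aggregate_tasks=True``, weights of the same base feature coming
    from different tasks are summed (prefix ``task.movement.`` stripped), the
    way stacked per-task relevance profiles are usually read.
    """
    rows = []
    for name, w in weights.items():
        base = name.split(".", 2)[-1] if "." in name else name
        rows.append({"feature": name, "base_feature": base, "weight": float(w)})
    df = pd.DataFrame(rows)
    if df.empty:
        raise DegenerateInputError("no weights supplied")
    if aggregate_tasks:
        df = (df.groupby("base_feature", as_index=False)["weight"].sum()
                .rename(columns={"base_feature": "feature"}))
    df = df.sort_values("weight", ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


__all__ = [
    "IN_AIR_TASKS", "feature_registry", "FeatureVector",
    "extract_task_features", "merge_session_features",
    "FeatureMatrix", "StandardizationStats",
    "fit_standardizer", "apply_standardizer", "feature_weight_report",
]
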