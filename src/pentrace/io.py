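"""Reading, writing and validating raw digitizer pen recordings.

A recording is the time-ordered stream of samples a graphics tablet emits
while a subject writes one task: x/y pen position, timestamp, a binary
surface-contact flag, the two pen-orientation angles (azimuth, altitude) and
tip pressure.  Files use a plain-text "SVC" dialect common to public
tablet-handwriting corpora: a first line holding the sample count, then one
whitespace-separated line per sample.  The column order is carried by a
:class:`SvcDialect` descriptor so other column conventions can be read
without code changes.

Sessions group the eight template tasks of one subject (the letter "l" at
normal and fast speed, the syllable "le" at normal and fast speed, the words
"leto", "lamoken", "hračkárstvo" and one full sentence) together with the
subject's demographics and diagnostic label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, NamedTuple

import numpy as np

from .errors import MissingTaskError, ParseError, ValidationError

#: Canonical template-task identifiers, in template order.
TASK_IDS: tuple[str, ...] = (
    "l",
    "l_fast",
    "le",
    "le_fast",
    "leto",
    "lamoken",
    "hrackarstvo",
    "sentence",
)

ON_SURFACE = "on_surface"
IN_AIR = "in_air"
MOVEMENTS = (ON_SURFACE, IN_AIR)

_SVC_FIELDS = ("x", "y", "t", "on_surface", "azimuth", "altitude", "pressure")


@dataclass(frozen=True)
class SvcDialect:
    """Column layout of an SVC-dialect text file.

    Parameters
    ----------
    columns
        Field name of each whitespace-separated column, in file order.
        Must be a permutation of ``x, y, t, on_surface, azimuth, altitude,
        pressure``.
    header_count
        Whether the first line holds the number of data lines.
    time_unit
        Unit of the timestamp column.  Only ``"ms"`` is interpreted by the
        kinematics layer; the field exists so files can declare themselves.
    position_unit
        Unit of the coordinate columns (metadata only; the device does not
        publish a physical calibration).
    """

    columns: tuple[str, ...] = _SVC_FIELDS
    header_count: bool = True
    time_unit: str = "ms"
    position_unit: str = "device"

    def __post_init__(self):
        if sorted(self.columns) != sorted(_SVC_FIELDS):
            raise ValidationError(
                f"dialect columns must be a permutation of {_SVC_FIELDS}, "
                f"got {self.columns}"
            )


DEFAULT_DIALECT = SvcDialect()


class PenSample(NamedTuple):
    """One digitizer sample.  Pressure/azimuth/altitude are device units and
    are treated as undefined while the pen is in the air."""

    t: float
    x: float
    y: float
    on_surface: int
    azimuth: float
    altitude: float
    pressure: float


@dataclass
class TaskRecording:
    """Time-ordered pen samples for one handwriting task.

    Samples are stored columnwise as numpy arrays; ``t`` is integer
    milliseconds, ``on_surface`` is a 0/1 flag, everything else is float64
    device units (y increases upward).  Use :meth:`from_samples` to build one
    from row records and :attr:`samples` to iterate rows.
    """

    task_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    on_surface: np.ndarray
    azimuth: np.ndarray
    altitude: np.ndarray
    pressure: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.int64)
        self.on_surface = np.asarray(self.on_surface, dtype=np.int64)
        for name in ("x", "y", "azimuth", "altitude", "pressure"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))

    @classmethod
    def from_samples(cls, task_id: str, samples: "list[PenSample]") -> "TaskRecording":
        cols = list(zip(*samples)) if samples else [[] for _ in PenSample._fields]
        data = dict(zip(PenSample._fields, cols))
        return cls(task_id=task_id, **data)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def samples(self) -> Iterator[PenSample]:
        for i in range(self.n_samples):
            yield PenSample(
                t=int(self.t[i]),
                x=float(self.x[i]),
                y=float(self.y[i]),
                on_surface=int(self.on_surface[i]),
                azimuth=float(self.azimuth[i]),
                altitude=float(self.altitude[i]),
                pressure=float(self.pressure[i]),
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, TaskRecording):
            return NotImplemented
        return self.task_id == other.task_id and all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in _SVC_FIELDS
        )


@dataclass(frozen=True)
class Violation:
    """One validation finding: the 0-based sample index (or None for
    recording-level findings) and a human-readable message."""

    index: int | None
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __iter__(self):
        return iter(self.violations)

    def __len__(self):
        return len(self.violations)


def validate_recording(rec: TaskRecording) -> ValidationReport:
    """Check a recording against the structural invariants and report every
    violation (non-monotone or duplicate timestamps, non-binary contact flag,
    negative pressure, too few samples, no on-surface sample).

    An empty report means the recording is usable downstream.
    """
    report = ValidationReport()
    if rec.task_id not in TASK_IDS:
        report.violations.append(
            Violation(None, f"unknown task_id {rec.task_id!r}; expected one of {TASK_IDS}")
        )
    n = rec.n_samples
    if n < 2:
        report.violations.append(Violation(None, f"recording has {n} samples; need >= 2"))
    dt = np.diff(rec.t)
    for i in np.flatnonzero(dt == 0):
        report.violations.append(Violation(int(i + 1), f"duplicate timestamp {rec.t[i + 1]}"))
    for i in np.flatnonzero(dt < 0):
        report.violations.append(
            Violation(int(i + 1), f"non-increasing timestamp {rec.t[i + 1]} after {rec.t[i]}")
        )
    bad_flag = np.flatnonzero((rec.on_surface != 0) & (rec.on_surface != 1))
    for i in bad_flag:
        report.violations.append(
            Violation(int(i), f"contact flag {rec.on_surface[i]} not in {{0, 1}}")
        )
    if n and not np.any(rec.on_surface == 1):
        report.violations.append(Violation(None, "no on-surface sample"))
    neg_p = np.flatnonzero(rec.pressure < 0)
    for i in neg_p:
        report.violations.append(Violation(int(i), f"negative pressure {rec.pressure[i]}"))
    for name in ("x", "y", "azimuth", "altitude", "pressure"):
        col = getattr(rec, name)
        if col.size and not np.all(np.isfinite(col)):
            j = int(np.flatnonzero(~np.isfinite(col))[0])
            report.violations.append(Violation(j, f"non-finite value in {name}"))
    return report


def check_recording(rec: TaskRecording) -> TaskRecording:
    """Validate and return ``rec``, raising :class:`ValidationError` listing
    every violation if the recording is unusable."""
    report = validate_recording(rec)
    if not report.ok:
        lines = "; ".join(
            (f"[{v.index}] " if v.index is not None else "") + v.message
            for v in report.violations
        )
        raise ValidationError(f"invalid recording {rec.task_id!r}: {lines}")
    return rec


# ---------------------------------------------------------------------------
# SVC-dialect reading and writing
# ---------------------------------------------------------------------------

def _format_number(v: float) -> str:
    # integers print without a decimal point so integer fields round-trip
    # bit-exactly; floats use repr (shortest exact form for float64)
    f = float(v)
    if f.is_integer() and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def read_recording(
    source: str | Path | IO[str],
    task_id: str,
    dialect: SvcDialect = DEFAULT_DIALECT,
    validate: bool = True,
) -> TaskRecording:
    """Parse an SVC-dialect text stream into a validated :class:`TaskRecording`.

    ``source`` may be a path or an open text stream.  Sample order is
    preserved: the i-th data line becomes the i-th sample.  Raises
    :class:`ParseError` with the offending line number on malformed input and
    :class:`ValidationError` if the parsed recording violates an invariant
    (unless ``validate=False``).
    """
    if isinstance(source, (str, Path)):
        with open(source, "r") as fh:
            return read_recording(fh, task_id, dialect, validate)

    lines = source.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError("empty recording file")
    start = 0
    declared = None
    if dialect.header_count:
        try:
            declared = int(lines[0].split()[0])
        except ValueError:
            raise ParseError(f"header is not an integer sample count: {lines[0]!r}", 1)
        start = 1
    rows: list[list[float]] = []
    ncol = len(dialect.columns)
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = line.split()
        if len(parts) != ncol:
            raise ParseError(
                f"expected {ncol} columns, got {len(parts)}", lineno
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ParseError(f"non-numeric field: {exc}", lineno)
    if declared is not None and declared != len(rows):
        raise ParseError(
            f"header declares {declared} samples but file has {len(rows)}"
        )
    if not rows:
        raise ParseError("file contains no data lines")
    grid = np.asarray(rows, dtype=np.float64)
    data = {name: grid[:, j] for j, name in enumerate(dialect.columns)}
    rec = TaskRecording(task_id=task_id, **data)
    if validate:
        check_recording(rec)
    return rec


def write_recording(
    rec: TaskRecording,
    dest: str | Path | IO[str] | None = None,
    dialect: SvcDialect = DEFAULT_DIALECT,
) -> str:
    """Serialize a recording to the SVC dialect; returns the text and, when
    ``dest`` is given, also writes it there.  The output parses back to an
    identical recording under :func:`read_recording` (integer fields
    bit-exact)."""
    check_recording(rec)
    out = []
    if dialect.header_count:
        out.append(str(rec.n_samples))
    cols = [getattr(rec, name) for name in dialect.columns]
    for i in range(rec.n_samples):
        out.append(" ".join(_format_number(col[i]) for col in cols))
    text = "\n".join(out) + "\n"
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)
    return text


# ---------------------------------------------------------------------------
# Sessions: the eight tasks of one subject
# ---------------------------------------------------------------------------

@dataclass
class Session:
    """All recordings of one subject plus demographics and diagnostic label
    (``"dysgraphia"``, ``"control"`` or None when unknown)."""

    subject_id: str
    age: int
    sex: str  # "M" | "F"
    handedness: str  # "L" | "R"
    label: str | None
    recordings: dict[str, TaskRecording] = field(default_factory=dict)

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.handedness not in ("L", "R"):
            raise ValidationError(f"handedness must be 'L' or 'R', got {self.handedness!r}")
        if self.label not in ("dysgraphia", "control", None):
            raise ValidationError(f"unknown label {self.label!r}")
        for task_id, rec in self.recordings.items():
            if task_id != rec.task_id:
                raise ValidationError(
                    f"recording keyed {task_id!r} carries task_id {rec.task_id!r}"
                )

    @property
    def is_complete(self) -> bool:
        return all(t in self.recordings for t in TASK_IDS)

    def require_tasks(self, tasks: tuple[str, ...] = TASK_IDS) -> None:
        missing = [t for t in tasks if t not in self.recordings]
        if missing:
            raise MissingTaskError(
                f"session {self.subject_id!r} is missing task(s): {', '.join(missing)}"
            )


_META_FIELDS = ("subject_id", "age", "sex", "handedness", "label")


def write_session(session: Session, directory: str | Path,
                  dialect: SvcDialect = DEFAULT_DIALECT) -> Path:
    """Persist a session as one SVC file per task plus a tab-separated
    manifest (task_id, file name) and a meta file with demographics."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_lines = []
    for task_id in TASK_IDS:
        if task_id not in session.recordings:
            continue
        fname = f"{task_id}.svc"
        write_recording(session.recordings[task_id], directory / fname, dialect)
        manifest_lines.append(f"{task_id}\t{fname}")
    (directory / "manifest.tsv").write_text("\n".join(manifest_lines) + "\n")
    meta = {
        "subject_id": session.subject_id,
        "age": session.age,
        "sex": session.sex,
        "handedness": session.handedness,
        "label": session.label if session.label is not None else "unknown",
    }
    (directory / "meta.tsv").write_text(
        "\n".join(f"{k}\t{v}" for k, v in meta.items()) + "\n"
    )
    return directory


def read_session(directory: str | Path,
                 dialect: SvcDialect = DEFAULT_DIALECT) -> Session:
    """Load a session written by :func:`write_session`."""
    directory = Path(directory)
    meta: dict[str, str] = {}
    for line in (directory / "meta.tsv").read_text().splitlines():
        if line.strip():
            k, _, v = line.partition("\t")
            meta[k] = v
    label = None if meta.get("label") in (None, "unknown") else meta["label"]
    recordings = {}
    for line in (directory / "manifest.tsv").read_text().splitlines():
        if not line.strip():
            continue
        task_id, _, fname = line.partition("\t")
        recordings[task_id] = read_recording(directory / fname, task_id, dialect)
    return Session(
        subject_id=meta["subject_id"],
        age=int(meta["age"]),
        sex=meta["sex"],
        handedness=meta["handedness"],
        label=label,
        recordings=recordings,
    )


def write_cohort(sessions: list[Session], directory: str | Path,
                 dialect: SvcDialect = DEFAULT_DIALECT) -> Path:
    """Persist a list of sessions under one directory (one sub-directory per
    subject) plus a ``labels.tsv`` index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["subject_id\tdirectory\tlabel\tage\tsex\thandedness"]
    for s in sessions:
        write_session(s, directory / s.subject_id, dialect)
        lines.append(
            f"{s.subject_id}\t{s.subject_id}\t{s.label or 'unknown'}\t{s.age}\t{s.sex}\t{s.handedness}"
        )
    (directory / "labels.tsv").write_text("\n".join(lines) + "\n")
    return directory


def read_cohort(directory: str | Path,
                dialect: SvcDialect = DEFAULT_DIALECT) -> list[Session]:
    """Load every session listed in a cohort directory's ``labels.tsv``."""
    directory = Path(directory)
    sessions = []
    lines = (directory / "labels.tsv").read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        subject_id, subdir, *_ = line.split("\t")
        sessions.append(read_session(directory / subdir, dialect))
    return sessions


__all__ = [
    "TASK_IDS", "ON_SURFACE", "IN_AIR", "MOVEMENTS",
    "SvcDialect", "DEFAULT_DIALECT", "PenSample", "TaskRecording",
    "Violation", "ValidationReport", "validate_recording", "check_recording",
    "read_recording", "write_recording",
    "Session", "read_session", "write_session", "read_cohort", "write_cohort",
]
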