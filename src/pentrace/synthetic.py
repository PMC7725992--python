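"""Synthetic handwriting cohorts with plantable group effects.

The generator emulates what a digitizer tablet records while a child works
through the eight-task template: multi-segment pen traces (strokes joined by
in-air transits), smooth bell-shaped speed profiles (minimum-jerk position
law along each stroke), hand tremor as additive band-limited positional
noise, and pressure/azimuth/altitude channels with per-subject baselines.
It exists so the whole pipeline — parsing, segmentation, kinematics, feature
assembly, cross-validated classification — is exercisable end to end
without any recorded data.

Group differences are planted through an :class:`EffectProfile` targeting
the feature families that matter for dysgraphia screening: extra pen lifts,
baseline y-drift across segments (row-keeping failure), a tremor gain that
raises the density of local speed extrema, an additive pressure offset and a
stroke-speed multiplier.  The null profile leaves both groups exchangeable,
so downstream cross-validated accuracy calibrates to chance; graded
profiles let planted-effect recovery be checked monotonically.

The cohort preset mirrors the study population this pipeline is designed
for: 120 schoolchildren aged 8-15, 57 with dysgraphia and 63 controls,
two-thirds boys, 16 left-handed, sampled at 100 Hz (a typical tablet rate;
the template itself fixes no rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import Session, TaskRecording, TASK_IDS

# ---------------------------------------------------------------------------
# Effect profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectProfile:
    """Per-channel group-difference magnitudes planted into one subject's
    handwriting.

    pen_lift_rate_delta
        Expected extra pen lifts per task (Poisson; >= 0).
    baseline_drift_sd
        Std of the per-stroke random walk of the writing baseline, device
        units.  Comparable to the letter height (~16 units) it destroys
        row-keeping entirely.
    tremor_gain
        Multiplier (>= 1) on the band-limited positional tremor, hence on
        the density of local speed extrema.
    pressure_shift
        Additive offset on the subject's pressure baseline, device units.
    speed_scale
        Multiplier on stroke velocity (< 1 slows the writing down).
    """

    pen_lift_rate_delta: float = 0.0
    baseline_drift_sd: float = 0.0
    tremor_gain: float = 1.0
    pressure_shift: float = 0.0
    speed_scale: float = 1.0

    def __post_init__(self):
        if self.pen_lift_rate_delta < 0:
            raise ValidationError("pen_lift_rate_delta must be >= 0")
        if self.tremor_gain < 1.0:
            raise ValidationError("tremor_gain must be >= 1")
        if self.speed_scale <= 0:
            raise ValidationError("speed_scale must be > 0")


NULL_EFFECT = EffectProfile()


def graded_effect(strength: float) -> EffectProfile:
    """Interpolate between the null profile (``strength=0``) and the strong
    dysgraphia profile (``strength=1``): +3 pen lifts per task, baseline
    drift of 6 device units (about a third of the letter height), doubled
    tremor, a -15-unit pressure offset and 15% slower strokes."""
    if not 0.0 <= strength <= 1.0:
        raise ValidationError("strength must lie in [0, 1]")
    return EffectProfile(
        pen_lift_rate_delta=3.0 * strength,
        baseline_drift_sd=6.0 * strength,
        tremor_gain=1.0 + 1.0 * strength,
        pressure_shift=-15.0 * strength,
        speed_scale=1.0 - 0.15 * strength,
    )


WEAK_EFFECT = graded_effect(0.15)
MEDIUM_EFFECT = graded_effect(0.4)
STRONG_EFFECT = graded_effect(1.0)

# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------

#: (min strokes, max strokes, speed multiplier) per template task; the fast
#: variants are the same material written quicker, the sentence is longest.
TASK_PROFILES: dict[str, tuple[int, int, float]] = {
    "l": (4, 6, 1.0),
    "l_fast": (4, 6, 1.6),
    "le": (6, 9, 1.0),
    "le_fast": (6, 9, 1.6),
    "leto": (8, 12, 1.0),
    "lamoken": (12, 16, 1.0),
    "hrackarstvo": (14, 20, 1.0),
    "sentence": (26, 34, 1.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level knobs.  The defaults are the cohort preset described in
    the module docstring; ``effect`` applies to the dysgraphia group only,
    controls always get the null profile."""

    n_subjects: int = 120
    n_dysgraphia: int = 57
    age_range: tuple[int, int] = (8, 15)
    male_fraction: float = 80 / 120
    left_handed_fraction: float = 16 / 120
    sampling_rate: float = 100.0
    task_profiles: dict[str, tuple[int, int, float]] = field(
        default_factory=lambda: dict(TASK_PROFILES)
    )
    effect: EffectProfile = STRONG_EFFECT
    #: Base amplitude of the positional tremor noise, device units.
    tremor_base: float = 0.06
    #: Letter arch height, device units (letters are ~2x this tall).
    letter_height: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.n_dysgraphia <= self.n_subjects:
            raise ValidationError("need 0 <= n_dysgraphia <= n_subjects")
        if self.sampling_rate <= 0 or self.sampling_rate > 1000:
            raise ValidationError("sampling_rate must be in (0, 1000] Hz")
        if self.age_range[0] > self.age_range[1]:
            raise ValidationError("age_range must be (low, high)")
        missing = [t for t in TASK_IDS if t not in self.task_profiles]
        if missing:
            raise ValidationError(f"task_profiles missing tasks: {missing}")


def table1_config(seed: int = 0, effect: EffectProfile = STRONG_EFFECT) -> GeneratorConfig:
    """The default 120-subject preset (57 dysgraphia / 63 control)."""
    return GeneratorConfig(seed=seed, effect=effect)


def null_config(seed: int = 0) -> GeneratorConfig:
    """Same cohort but with no planted group difference: both groups draw
    from the identical distribution, so classifiers should sit at chance."""
    return GeneratorConfig(seed=seed, effect=NULL_EFFECT)


# ---------------------------------------------------------------------------
# Stroke- and task-level generation
# ---------------------------------------------------------------------------

def _band_limited_noise(n: int, rng: np.random.Generator, window: int = 3) -> np.ndarray:
    """Moving-average-smoothed white noise, unit marginal scale."""
    if n == 0:
        return np.empty(0)
    raw = rng.normal(0.0, 1.0, n + window - 1)
    kernel = np.ones(window) / window
    return np.convolve(raw, kernel, mode="valid") * np.sqrt(window)


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position law: 0 -> 1 with bell-shaped speed."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def generate_stroke(
    start: tuple[float, float],
    target: tuple[float, float],
    duration: float,
    profile: EffectProfile,
    rng: np.random.Generator,
    *,
    sampling_rate: float = 100.0,
    tremor_base: float = 0.06,
    arch_height: float = 8.0,
    pressure_base: float = 60.0,
    azimuth_base: float = 1800.0,
    altitude_base: float = 600.0,
) -> dict[str, np.ndarray]:
    """One on-surface stroke from ``start`` to ``target``.

    The pen follows the straight line under a minimum-jerk (bell-shaped
    speed) law, arched perpendicular to it by ``arch_height * sin(pi tau)``
    so strokes look like letter bodies; band-limited tremor noise of
    amplitude ``tremor_base * profile.tremor_gain`` rides on both
    coordinates.  With ``tremor_base=0`` the trajectory is deterministic and
    ends exactly on ``target``.  Returns arrays x, y, pressure, azimuth,
    altitude (no timestamps: the caller owns the sample clock).
    """
    if duration <= 0:
        raise ValidationError("stroke duration must be > 0")
    n = max(4, int(round(duration * sampling_rate)))
    tau = np.linspace(0.0, 1.0, n)
    s = _min_jerk(tau)
    sx, sy = start
    txp, typ = target
    dx, dy = txp - sx, typ - sy
    norm = float(np.hypot(dx, dy)) or 1.0
    # unit normal to the stroke direction carries the arch
    nx, ny = -dy / norm, dx / norm
    arch = arch_height * np.sin(np.pi * tau)
    amp = tremor_base * profile.tremor_gain
    x = sx + dx * s + nx * arch + amp * _band_limited_noise(n, rng)
    y = sy + dy * s + ny * arch + amp * _band_limited_noise(n, rng)
    bell = np.sin(np.pi * tau)
    pressure = (pressure_base + profile.pressure_shift) * (0.85 + 0.3 * bell)
    if tremor_base > 0:
        pressure = pressure + rng.normal(0.0, 2.0, n)
    pressure = np.clip(pressure, 1.0, None)
    azimuth = np.clip(azimuth_base + 30.0 * _band_limited_noise(n, rng, window=7), 0, 3600)
    altitude = np.clip(altitude_base + 10.0 * _band_limited_noise(n, rng, window=7), 100, 900)
    return {"x": x, "y": y, "pressure": pressure,
            "azimuth": azimuth, "altitude": altitude}


def _transit(start, target, duration, profile, rng, *, sampling_rate, tremor_base,
             azimuth_base, altitude_base):
    """In-air hop between strokes: straight minimum-jerk, zero pressure."""
    n = max(2, int(round(duration * sampling_rate)))
    tau = np.linspace(0.0, 1.0, n)
    s = _min_jerk(tau)
    amp = tremor_base * profile.tremor_gain
    x = start[0] + (target[0] - start[0]) * s + amp * _band_limited_noise(n, rng)
    y = start[1] + (target[1] - start[1]) * s + amp * _band_limited_noise(n, rng)
    azimuth = np.clip(azimuth_base + 30.0 * _band_limited_noise(n, rng, window=7), 0, 3600)
    altitude = np.clip(altitude_base + 10.0 * _band_limited_noise(n, rng, window=7), 100, 900)
    return {"x": x, "y": y, "pressure": np.zeros(n),
            "azimuth": azimuth, "altitude": altitude}


@dataclass
class _SubjectTraits:
    """Per-subject baselines drawn once and shared across the eight tasks."""

    pressure_base: float
    azimuth_base: float
    altitude_base: float
    stroke_duration: float  # seconds, before speed scaling
    stroke_advance: float  # x progress per stroke, device units


def _draw_traits(rng: np.random.Generator) -> _SubjectTraits:
    return _SubjectTraits(
        pressure_base=float(rng.normal(60.0, 5.0)),
        azimuth_base=float(rng.uniform(1500.0, 2100.0)),
        altitude_base=float(rng.uniform(500.0, 700.0)),
        stroke_duration=float(rng.uniform(0.30, 0.40)),
        stroke_advance=float(rng.uniform(3.5, 5.0)),
    )


def generate_task(
    task_id: str,
    profile: EffectProfile,
    rng: np.random.Generator,
    config: GeneratorConfig = GeneratorConfig(),
    traits: _SubjectTraits | None = None,
) -> TaskRecording:
    """One task recording: strokes joined by in-air transits, with the
    profile's extra pen lifts, baseline drift, tremor, pressure offset and
    speed change planted.  Parses and validates cleanly through the I/O
    layer."""
    if task_id not in config.task_profiles:
        raise ValidationError(f"unknown task {task_id!r}")
    lo, hi, task_speed = config.task_profiles[task_id]
    traits = traits or _draw_traits(rng)
    n_strokes = int(rng.integers(lo, hi + 1))
    pieces = n_strokes + int(rng.poisson(profile.pen_lift_rate_delta))
    speed = task_speed * profile.speed_scale

    baseline = 100.0
    x_cursor = 0.0
    drift = 0.0
    chunks: list[tuple[int, dict[str, np.ndarray]]] = []  # (on_surface, arrays)
    prev_end: tuple[float, float] | None = None
    for i in range(pieces):
        drift += float(rng.normal(0.0, profile.baseline_drift_sd))
        jitter = float(rng.normal(0.0, 0.6))
        y0 = baseline + drift + jitter
        start = (x_cursor, y0)
        advance = traits.stroke_advance * float(rng.uniform(0.8, 1.2))
        target = (x_cursor + advance, y0 + float(rng.normal(0.0, 1.0)))
        duration = traits.stroke_duration * float(rng.uniform(0.85, 1.15)) / speed
        if prev_end is not None:
            hop = _transit(
                prev_end, start,
                duration=float(rng.uniform(0.08, 0.18)) / speed,
                profile=profile, rng=rng,
                sampling_rate=config.sampling_rate,
                tremor_base=config.tremor_base,
                azimuth_base=traits.azimuth_base,
                altitude_base=traits.altitude_base,
            )
            chunks.append((0, hop))
        stroke = generate_stroke(
            start, target, duration, profile, rng,
            sampling_rate=config.sampling_rate,
            tremor_base=config.tremor_base,
            arch_height=config.letter_height,
            pressure_base=traits.pressure_base,
            azimuth_base=traits.azimuth_base,
            altitude_base=traits.altitude_base,
        )
        chunks.append((1, stroke))
        prev_end = (float(stroke["x"][-1]), float(stroke["y"][-1]))
        x_cursor += advance

    cols = {k: [] for k in ("x", "y", "pressure", "azimuth", "altitude")}
    flags: list[np.ndarray] = []
    for flag, arrays in chunks:
        n = len(arrays["x"])
        flags.append(np.full(n, flag, dtype=np.int64))
        for k in cols:
            cols[k].append(arrays[k])
    flag_vec = np.concatenate(flags)
    total = len(flag_vec)
    t = np.round(np.arange(total) * 1000.0 / config.sampling_rate).astype(np.int64)
    return TaskRecording(
        task_id=task_id,
        t=t,
        x=np.concatenate(cols["x"]),
        y=np.concatenate(cols["y"]),
        on_surface=flag_vec,
        azimuth=np.concatenate(cols["azimuth"]),
        altitude=np.concatenate(cols["altitude"]),
        pressure=np.concatenate(cols["pressure"]),
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_session(
    subject_id: str,
    label: str,
    age: int,
    sex: str,
    handedness: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> Session:
    """A complete eight-task session for one subject; the effect profile is
    applied iff the label is ``"dysgraphia"``."""
    profile = config.effect if label == "dysgraphia" else NULL_EFFECT
    traits = _draw_traits(rng)
    recordings = {
        task_id: generate_task(task_id, profile, rng, config, traits)
        for task_id in TASK_IDS
    }
    return Session(
        subject_id=subject_id, age=age, sex=sex, handedness=handedness,
        label=label, recordings=recordings,
    )


def generate_cohort(config: GeneratorConfig = GeneratorConfig()) -> list[Session]:
    """A labeled cohort of ``config.n_subjects`` sessions, fully
    deterministic in ``config.seed``: labels are assigned to a seeded random
    permutation of subjects, demographics drawn per the configured ratios,
    and each subject consumes an independent child RNG stream (so changing
    one subject never perturbs another)."""
    root = np.random.SeedSequence(config.seed)
    cohort_ss, *subject_ss = root.spawn(config.n_subjects + 1)
    rng = np.random.default_rng(cohort_ss)
    labels = np.array(
        ["dysgraphia"] * config.n_dysgraphia
        + ["control"] * (config.n_subjects - config.n_dysgraphia)
    )
    rng.shuffle(labels)
    lo_age, hi_age = config.age_range
    sessions = []
    for i in range(config.n_subjects):
        sessions.append(generate_session(
            subject_id=f"S{i:03d}",
            label=str(labels[i]),
            age=int(rng.integers(lo_age, hi_age + 1)),
            sex="M" if rng.random() < config.male_fraction else "F",
            handedness="L" if rng.random() < config.left_handed_fraction else "R",
            config=config,
            rng=np.random.default_rng(subject_ss[i]),
        ))
    return sessions


__all__ = [
    "EffectProfile", "NULL_EFFECT", "WEAK_EFFECT", "MEDIUM_EFFECT",
    "STRONG_EFFECT", "graded_effect",
    "TASK_PROFILES", "GeneratorConfig", "table1_config", "null_config",
    "generate_stroke", "generate_task", "generate_session", "generate_cohort",
]
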