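"""Feature registry, per-task extraction, session merging, standardization."""

import numpy as np
import pytest

from pentrace.errors import MissingTaskError, SchemaError, DegenerateInputError
from pentrace.features import (
    FeatureMatrix,
    apply_standardizer,
    extract_task_features,
    feature_registry,
    feature_weight_report,
    fit_standardizer,
    merge_session_features,
)
from pentrace.io import IN_AIR, ON_SURFACE, Session

from conftest import make_recording


# --- registry --------------------------------------------------------------

def test_registry_counts():
    on = feature_registry(ON_SURFACE)
    air = feature_registry(IN_AIR)
    assert len(on) == 133
    assert len(air) == 112


def test_in_air_registry_drops_exactly_the_device_channels():
    on = set(feature_registry(ON_SURFACE))
    air = set(feature_registry(IN_AIR))
    dropped = on - air
    assert len(dropped) == 21
    assert all(
        name.split("__")[0] in ("pressure", "altitude", "azimuth")
        for name in dropped
    )
    assert air <= on


def test_registry_names_unique_and_stable():
    on = feature_registry(ON_SURFACE)
    assert len(set(on)) == len(on)
    assert on == feature_registry(ON_SURFACE)
    # one name per (signal, statistic) pair
    assert on.count("velocity__mean") == 1
    assert "seg_duration__std" in on
    assert "var_y__median" in on


# --- extraction ------------------------------------------------------------

def test_extraction_counts_on_generated_task(small_session):
    fv = extract_task_features(small_session.recordings["leto"], ON_SURFACE)
    assert len(fv) == 133
    assert np.all(np.isfinite(fv.values))
    air = extract_task_features(small_session.recordings["sentence"], IN_AIR)
    assert len(air) == 112


def test_stationary_pen_features():
    n = 12
    rec = make_recording([1] * n, x=np.zeros(n), y=np.zeros(n),
                         pressure=np.full(n, 50.0))
    fv = extract_task_features(rec, ON_SURFACE)
    assert fv["velocity__mean"] == 0.0
    assert fv["jerk__max"] == 0.0
    for stat in ("mean", "median", "max", "min", "p05", "p95"):
        assert fv[f"pressure__{stat}"] == 50.0
    assert fv["pressure__std"] == 0.0


def test_no_movement_segments_give_flagged_zero_vector():
    rec = make_recording([1, 1, 1, 1])  # no in-air movement at all
    fv = extract_task_features(rec, IN_AIR)
    assert len(fv) == 112
    assert np.all(fv.values == 0.0)
    assert fv.degenerate == frozenset(fv.names)


def test_extraction_is_deterministic(small_session):
    rec = small_session.recordings["hrackarstvo"]
    a = extract_task_features(rec, ON_SURFACE)
    b = extract_task_features(rec, ON_SURFACE)
    assert a.names == b.names
    assert np.array_equal(a.values, b.values)


def test_scalar_features_cross_check(small_session):
    from pentrace.segmentation import count_pen_lifts, split_segments, segment_geometry

    rec = small_session.recordings["le"]
    fv = extract_task_features(rec, ON_SURFACE)
    assert fv["pen_lifts"] == count_pen_lifts(rec)
    on, _ = split_segments(rec)
    total = sum(segment_geometry(s).duration for s in on)
    assert fv["total_duration"] == pytest.approx(total)


# --- session merging -------------------------------------------------------

def test_merged_session_vector_has_1176_features(small_session):
    fv = merge_session_features(small_session)
    assert len(fv) == 1176
    assert fv.names[0].startswith("l.on_surface.")
    assert fv.names[-1].startswith("sentence.in_air.")


def test_missing_task_error_names_the_task(small_session):
    incomplete = Session(
        subject_id="X", age=9, sex="F", handedness="R", label=None,
        recordings={k: v for k, v in small_session.recordings.items() if k != "leto"},
    )
    with pytest.raises(MissingTaskError, match="leto"):
        merge_session_features(incomplete)


# --- standardization -------------------------------------------------------

def _matrix(values, columns=None, labels=None):
    values = np.asarray(values, dtype=float)
    columns = columns or tuple(f"f{i}" for i in range(values.shape[1]))
    ids = tuple(f"s{i}" for i in range(values.shape[0]))
    return FeatureMatrix(subject_ids=ids, columns=tuple(columns), values=values,
                         labels=labels)


def test_population_standardization_example():
    stats = fit_standardizer(_matrix([[0.0], [2.0]]))
    assert stats.mean[0] == 1.0
    assert stats.std[0] == 1.0  # population form


def test_constant_column_flagged_and_mapped_to_zero():
    m = _matrix([[3.0, 1.0], [3.0, 2.0], [3.0, 3.0]])
    stats = fit_standardizer(m)
    assert stats.zero_variance.tolist() == [True, False]
    z = apply_standardizer(m, stats)
    assert np.all(z.values[:, 0] == 0.0)


def test_standardized_columns_have_zero_mean_unit_variance():
    rng = np.random.default_rng(13)
    m = _matrix(rng.normal(3, 7, (40, 6)))
    z = apply_standardizer(m, fit_standardizer(m))
    assert np.allclose(z.values.mean(axis=0), 0.0, atol=1e-10)
    assert np.allclose(z.values.var(axis=0), 1.0, atol=1e-10)


def test_standardization_is_idempotent():
    rng = np.random.default_rng(14)
    m = _matrix(rng.normal(0, 2, (20, 4)))
    z1 = apply_standardizer(m, fit_standardizer(m))
    z2 = apply_standardizer(z1, fit_standardizer(z1))
    assert np.allclose(z1.values, z2.values, atol=1e-10)


def test_test_matrix_uses_train_statistics_only():
    train = _matrix([[0.0], [2.0]])
    test = _matrix([[10.0], [20.0]])
    stats = fit_standardizer(train)
    z = apply_standardizer(test, stats)
    # (10-1)/1 and (20-1)/1: no refit on the test matrix
    assert z.values[:, 0].tolist() == [9.0, 19.0]


def test_schema_mismatch_raises():
    stats = fit_standardizer(_matrix([[0.0], [2.0]], columns=("a",)))
    with pytest.raises(SchemaError):
        apply_standardizer(_matrix([[1.0], [2.0]], columns=("b",)), stats)


def test_standardizer_needs_two_rows():
    with pytest.raises(DegenerateInputError):
        fit_standardizer(_matrix([[1.0, 2.0]]))


# --- matrix I/O and weight report ------------------------------------------

def test_feature_matrix_csv_round_trip(tmp_path):
    rng = np.random.default_rng(15)
    m = _matrix(rng.normal(0, 1, (5, 3)), labels=("dysgraphia", "control") * 2 + ("control",))
    path = tmp_path / "m.csv"
    m.write_csv(path)
    back = FeatureMatrix.read_csv(path)
    assert back.columns == m.columns
    assert back.labels == m.labels
    assert np.allclose(back.values, m.values)
    assert back.y.tolist() == [1, 0, 1, 0, 0]


def test_weight_report_aggregates_across_tasks():
    weights = {
        "l.on_surface.pen_lifts": 1.0,
        "leto.on_surface.pen_lifts": 2.5,
        "leto.on_surface.velocity__mean": 3.0,
    }
    report = feature_weight_report(weights, aggregate_tasks=True)
    assert report.loc[0, "feature"] == "pen_lifts"
    assert report.loc[0, "weight"] == pytest.approx(3.5)
    assert report.loc[0, "rank"] == 1
    flat = feature_weight_report(weights, aggregate_tasks=False)
    assert len(flat) == 3
    assert flat.loc[0, "weight"] == 3.0
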