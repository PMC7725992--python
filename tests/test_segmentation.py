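"""Contact-state segmentation, geometry and row-drift features."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pentrace.errors import DegenerateInputError
from pentrace.segmentation import (
    count_pen_lifts,
    count_pen_returns,
    inclination_features,
    segment_geometry,
    split_segments,
    summarize_segments,
)

from conftest import make_recording


def brute_runs(flags):
    """Independent run-length encoder: list of (state, length)."""
    return [(state, len(list(group))) for state, group in itertools.groupby(flags)]


# --- splitting -------------------------------------------------------------

def test_all_on_surface_single_segment():
    on, air = split_segments(make_recording([1, 1, 1]))
    assert len(on) == 1 and len(air) == 0
    assert on[0].n_samples == 3


def test_transition_enumeration():
    on, air = split_segments(make_recording([1, 1, 0, 0, 1]))
    assert len(on) == 2 and len(air) == 1
    assert [s.n_samples for s in on] == [2, 1]
    assert air[0].n_samples == 2


@given(st.lists(st.integers(0, 1), min_size=1, max_size=40))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_split_matches_run_length_encoder(flags):
    if not any(flags):
        flags = flags + [1]
    rec = make_recording(flags)
    on, air = split_segments(rec)
    merged = sorted(on + air, key=lambda s: s.start)
    # partition: sample counts add up and segment order reconstructs the flags
    assert sum(s.n_samples for s in merged) == len(flags)
    reconstructed = [
        1 if s.movement == "on_surface" else 0
        for s in merged
        for _ in range(s.n_samples)
    ]
    assert reconstructed == list(flags)
    # maximality: run lengths match the independent encoder
    assert [(1 if s.movement == "on_surface" else 0, s.n_samples) for s in merged] \
        == brute_runs(flags)
    assert abs(len(on) - len(air)) <= 1


# --- pen lifts -------------------------------------------------------------

def test_no_lift_without_in_air():
    assert count_pen_lifts(make_recording([1, 1, 1])) == 0


def test_lift_counting():
    assert count_pen_lifts(make_recording([1, 0, 1, 0])) == 2
    assert count_pen_returns(make_recording([1, 0, 1, 0])) == 1


@given(st.lists(st.integers(0, 1), min_size=2, max_size=40))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_lifts_equal_segment_count_identity(flags):
    flags = [1] + flags + [1]  # starts and ends on-surface
    rec = make_recording(flags)
    on, _ = split_segments(rec)
    assert count_pen_lifts(rec) == len(on) - 1


def test_lifts_ignore_in_air_trajectory_content():
    flags = [1, 1, 0, 0, 1]
    a = make_recording(flags)
    b = make_recording(flags, x=[0, 1, 99, -99, 2], y=[0, 0, 50, -50, 0])
    assert count_pen_lifts(a) == count_pen_lifts(b)


# --- geometry --------------------------------------------------------------

def test_single_sample_segment_has_zero_geometry():
    on, _ = split_segments(make_recording([0, 1, 0]))
    g = segment_geometry(on[0])
    assert g.as_tuple() == (0, 0, 0, 0, 0, 0)


def test_square_path_geometry():
    rec = make_recording([1] * 4, x=[0, 1, 1, 0], y=[0, 0, 1, 1])
    on, _ = split_segments(rec)
    g = segment_geometry(on[0])
    assert g.duration == pytest.approx(0.03)
    assert g.length == pytest.approx(3.0)
    assert g.horizontal_length == pytest.approx(2.0)
    assert g.vertical_length == pytest.approx(1.0)
    assert g.width == 1.0 and g.height == 1.0


@given(
    st.lists(st.floats(-100, 100), min_size=2, max_size=20),
    st.lists(st.floats(-100, 100), min_size=2, max_size=20),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_extent_never_exceeds_path_length(xs, ys):
    n = min(len(xs), len(ys))
    rec = make_recording([1] * n, x=xs[:n], y=ys[:n])
    on, _ = split_segments(rec)
    g = segment_geometry(on[0])
    assert g.width <= g.horizontal_length + 1e-9
    assert g.height <= g.vertical_length + 1e-9


# --- segment summaries -----------------------------------------------------

def test_single_segment_summary_collapses():
    on, _ = split_segments(make_recording([1] * 5))
    stats = summarize_segments([segment_geometry(on[0])])
    for measure, s in stats.items():
        assert s["mean"] == s["median"] == s["max"] == s["min"]
        assert s["std"] == 0.0


def test_two_segment_duration_statistics():
    # durations 0.1 s and 0.3 s
    flags = [1] * 11 + [0] * 2 + [1] * 31
    rec = make_recording(flags)
    on, _ = split_segments(rec)
    stats = summarize_segments([segment_geometry(s) for s in on])
    assert stats["duration"]["mean"] == pytest.approx(0.2)
    assert stats["duration"]["std"] == pytest.approx(0.1)  # population form


def test_segment_summary_matches_brute_force():
    rng = np.random.default_rng(8)
    flags = (rng.random(200) < 0.7).astype(int)
    flags[0] = 1
    rec = make_recording(flags, x=rng.normal(0, 5, 200), y=rng.normal(0, 5, 200))
    on, _ = split_segments(rec)
    geoms = [segment_geometry(s) for s in on]
    stats = summarize_segments(geoms)
    durations = [g.duration for g in geoms]
    assert stats["duration"]["mean"] == pytest.approx(np.mean(durations), abs=1e-12)
    assert stats["duration"]["std"] == pytest.approx(np.std(durations), abs=1e-12)
    assert stats["width"]["max"] == max(g.width for g in geoms)


def test_summarize_requires_segments():
    with pytest.raises(DegenerateInputError):
        summarize_segments([])


# --- inclination -----------------------------------------------------------

def test_single_segment_inclination_is_all_zero():
    on, _ = split_segments(make_recording([1, 1, 1]))
    incl = inclination_features(on)
    assert all(v == 0.0 for v in incl.diff_end.values())
    assert all(v == 0.0 for v in incl.diff_preend.values())
    assert all(v == 0.0 for v in incl.var_y.values())


def test_two_segment_hand_arithmetic():
    # segment 1 y = {0, 2}; segment 2 y = {1, 3}
    rec = make_recording([1, 1, 0, 1, 1], y=[0, 2, 9, 1, 3])
    on, _ = split_segments(rec)
    incl = inclination_features(on)
    assert incl.diff_end["max"] == pytest.approx(2 - 3)
    assert incl.diff_end["min"] == pytest.approx(0 - 1)
    assert incl.diff_end["mean"] == pytest.approx(1 - 2)
    assert incl.var_y["max"] == pytest.approx(np.var([2, 3]))  # 0.25
    # fewer than four segments: second-vs-penultimate differences fall back to 0
    assert all(v == 0.0 for v in incl.diff_preend.values())


def test_identical_rows_have_zero_drift():
    y = [0, 5, 9, 0, 5, 9, 0, 5]
    flags = [1, 1, 0, 1, 1, 0, 1, 1]
    on, _ = split_segments(make_recording(flags, y=y))
    incl = inclination_features(on)
    assert all(v == 0.0 for v in incl.diff_end.values())
    assert all(v == 0.0 for v in incl.var_y.values())


def test_y_translation_leaves_inclination_unchanged():
    rng = np.random.default_rng(9)
    flags = [1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 1]
    y = rng.normal(0, 10, len(flags))
    a, _ = split_segments(make_recording(flags, y=y))
    b, _ = split_segments(make_recording(flags, y=y + 1234.5))
    ia, ib = inclination_features(a), inclination_features(b)
    for k in ia.diff_end:
        assert ia.diff_end[k] == pytest.approx(ib.diff_end[k], abs=1e-9)
        assert ia.diff_preend[k] == pytest.approx(ib.diff_preend[k], abs=1e-9)
        assert ia.var_y[k] == pytest.approx(ib.var_y[k], abs=1e-6)
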