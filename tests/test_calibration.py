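"""Personalized calibration and the frame-state classifier."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drowsemeter.calibration import (CalibrationProfile, binarize_stream, calibrate,
                                     classify_frame, top_fraction_mean)
from drowsemeter.errors import (CalibrationError, InsufficientDataError,
                                MissingCalibrationError)
from drowsemeter.stream import FrameRecord, StateStream


def continuous_stream(n, fps=30.0, left=6.0, right=6.0, mar=0.4, rng=None):
    t = np.arange(n) / fps
    jitter = (lambda base: base + rng.normal(0, 0.05 * base, n)) if rng else (lambda b: np.full(n, b))
    return StateStream.from_arrays(t, nominal_fps=fps, left_gap=jitter(left),
                                   right_gap=jitter(right), mar=jitter(mar))


def test_one_minute_at_30fps_collects_1800_values_per_signal(rng):
    s = continuous_stream(1800, rng=rng)
    p = calibrate(s, duration_s=60.0)
    assert p.n_samples["n_left"] == 1800
    assert p.n_samples["n_right"] == 1800
    assert p.n_samples["n_mar"] == 1800
    # top 5% of 1800 values -> 90 averaged per signal
    assert p.n_samples["k_left"] == 90 == math.ceil(0.05 * 1800)


def test_constant_gap_reference_is_exact():
    s = continuous_stream(1800, left=4.2, right=3.3, mar=0.5)
    p = calibrate(s)
    assert p.open_gap_ref_left == pytest.approx(4.2)
    assert p.open_gap_ref_right == pytest.approx(3.3)
    assert p.open_mar_ref == pytest.approx(0.5)


def test_top_fraction_mean_matches_sort_oracle(rng):
    for n in (7, 90, 1800, 1801):
        vals = rng.uniform(0, 10, n)
        got, k = top_fraction_mean(vals, 0.05)
        expect_k = math.ceil(0.05 * n)
        expect = float(np.sort(vals)[::-1][:expect_k].mean())  # brute-force oracle
        assert k == expect_k
        assert got == pytest.approx(expect, rel=1e-12)


def test_calibrate_is_permutation_invariant(rng):
    vals = rng.uniform(1, 9, 600)
    a, _ = top_fraction_mean(vals, 0.05)
    b, _ = top_fraction_mean(rng.permutation(vals), 0.05)
    assert a == pytest.approx(b, rel=1e-12)


def test_calibration_skips_faceless_frames(rng):
    gaps = rng.uniform(3, 6, 1800)
    gaps[:100] = np.nan
    t = np.arange(1800) / 30.0
    with pytest.warns(UserWarning):
        s = StateStream.from_arrays(t, left_gap=gaps, right_gap=gaps.copy(),
                                    mar=np.full(1800, np.nan))
    p = calibrate(s)
    assert p.n_samples["n_left"] == 1700
    assert p.open_mar_ref is None


def test_too_short_stream_raises():
    with pytest.raises(InsufficientDataError):
        calibrate(continuous_stream(300), duration_s=60.0)


def test_binary_only_stream_cannot_calibrate():
    t = np.arange(1800) / 30.0
    s = StateStream.from_arrays(t, left_closed=[False] * 1800,
                                right_closed=[False] * 1800, mouth_open=[False] * 1800)
    with pytest.raises(CalibrationError):
        calibrate(s)


# -- classification rules ---------------------------------------------

PROFILE = CalibrationProfile(open_gap_ref_left=10.0, open_gap_ref_right=10.0,
                             open_mar_ref=1.0)


def test_both_eyes_below_20pct_counts_closed():
    rec = FrameRecord(t=0, left_gap=1.9, right_gap=1.5, mar=0.1)
    assert classify_frame(rec, PROFILE) == (True, False)


def test_one_open_eye_keeps_eyes_open_under_all_combine():
    rec = FrameRecord(t=0, left_gap=1.9, right_gap=5.0, mar=0.1)
    assert classify_frame(rec, PROFILE)[0] is False


@pytest.mark.parametrize("left,right", [(True, True), (True, False),
                                        (False, True), (False, False)])
def test_eye_combination_matches_boolean_oracle(left, right):
    # brute force over the four per-eye flag combinations
    rec = FrameRecord(t=0, left_gap=1.0 if left else 9.0,
                      right_gap=1.0 if right else 9.0)
    prof_all = CalibrationProfile(10, 10, eye_combine="all")
    prof_any = CalibrationProfile(10, 10, eye_combine="any")
    assert classify_frame(rec, prof_all)[0] == (left and right)
    assert classify_frame(rec, prof_any)[0] == (left or right)


def test_mar_threshold_is_strictly_greater():
    assert classify_frame(FrameRecord(t=0, left_gap=9, right_gap=9, mar=0.71), PROFILE)[1] is True
    assert classify_frame(FrameRecord(t=0, left_gap=9, right_gap=9, mar=0.70), PROFILE)[1] is False


def test_exactly_20pct_is_not_closed():
    rec = FrameRecord(t=0, left_gap=2.0, right_gap=2.0)  # gap == 0.2 * ref
    assert classify_frame(rec, PROFILE)[0] is False


def test_prebinarized_record_passes_through():
    rec = FrameRecord(t=0, left_closed=True, right_closed=True, mouth_open=True)
    assert classify_frame(rec, profile=None) == (True, True)


def test_continuous_record_without_profile_raises():
    with pytest.raises(MissingCalibrationError):
        classify_frame(FrameRecord(t=0, left_gap=1.0, right_gap=1.0))


def test_binarize_matches_per_frame_loop(rng):
    n = 400
    t = np.arange(n) / 30.0
    s = StateStream.from_arrays(t, left_gap=rng.uniform(0, 12, n),
                                right_gap=rng.uniform(0, 12, n),
                                mar=rng.uniform(0, 1.5, n))
    b = binarize_stream(s, PROFILE)
    assert b.is_binarized
    left = b.binary_column("left_closed")
    right = b.binary_column("right_closed")
    mouth = b.binary_column("mouth_open")
    for i, rec in enumerate(s.records()):  # per-frame oracle
        eyes, mo = classify_frame(rec, PROFILE)
        assert (left[i] and right[i]) == eyes
        assert mouth[i] == mo


def test_binarize_is_idempotent(rng):
    closed = rng.random(100) < 0.3
    t = np.arange(100) / 30.0
    s = StateStream.from_arrays(t, left_closed=closed, right_closed=closed.copy(),
                                mouth_open=np.zeros(100, bool))
    b = binarize_stream(s)
    assert b.df.equals(s.df)


@given(scale=st.floats(min_value=0.1, max_value=50.0, allow_nan=False))
@settings(max_examples=25, deadline=None)
def test_scaling_gaps_scales_references_and_preserves_classification(scale):
    rng = np.random.default_rng(7)
    n = 360
    gaps = rng.uniform(0.5, 10, n)
    t = np.arange(n) / 30.0

    def stream(factor):
        return StateStream.from_arrays(t, left_gap=gaps * factor,
                                       right_gap=gaps * factor,
                                       mar=np.full(n, 0.2))

    p1 = calibrate(stream(1.0), duration_s=12.0)
    p2 = calibrate(stream(scale), duration_s=12.0)
    assert p2.open_gap_ref_left == pytest.approx(scale * p1.open_gap_ref_left, rel=1e-9)
    b1 = binarize_stream(stream(1.0), p1).binary_column("left_closed")
    b2 = binarize_stream(stream(scale), p2).binary_column("left_closed")
    assert (b1 == b2).all()
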