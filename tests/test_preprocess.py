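"""Tests of pupillometry preprocessing: scaling, interpolation, artifact
flagging, baselines, exclusion and binning."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from pupilddm.preprocess import (PupilSamples, baseline_per_trial,
                                 bin_by_pupil, exclude_trials, flag_artifacts,
                                 interpolate_blinks, px_to_mm)


def _stream(diam, valid=None, gaze=None, fs=250.0):
    n = len(diam)
    t = np.arange(n) / fs
    g = np.zeros(n) if gaze is None else np.asarray(gaze, float)
    v = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, bool)
    return PupilSamples(time=t, diameter=np.asarray(diam, float),
                        gaze_x=g, gaze_y=np.zeros(n), valid=v, units="mm")


class TestPxToMm:
    def test_linear_scaling(self):
        s = _stream([400.0, 410.0])
        s = replace(s, units="px")
        out = px_to_mm(s, 0.01)
        np.testing.assert_allclose(out.diameter, [4.0, 4.1])
        assert out.units == "mm"

    def test_idempotent_once_in_mm(self, flat_stream):
        out = px_to_mm(px_to_mm(replace(flat_stream, units="px"), 2.0), 2.0)
        np.testing.assert_allclose(out.diameter, flat_stream.diameter * 2.0)

    def test_roundtrip(self):
        s = replace(_stream(np.linspace(300, 500, 50)), units="px")
        mm = px_to_mm(s, 0.0123)
        back = mm.diameter / 0.0123
        np.testing.assert_allclose(back, s.diameter, rtol=1e-15)

    def test_nonpositive_scale_rejected(self, flat_stream):
        with pytest.raises(ValueError):
            px_to_mm(flat_stream, 0.0)


class TestInterpolateBlinks:
    def test_short_gap_linear_ramp(self):
        # 0.4 s gap (100 samples at 250 Hz) between 3.0 and 3.2 mm
        diam = np.concatenate([np.full(100, 3.0), np.zeros(100), np.full(100, 3.2)])
        valid = np.concatenate([np.ones(100), np.zeros(100), np.ones(100)]).astype(bool)
        out = interpolate_blinks(_stream(diam, valid))
        assert out.valid.all()
        mid = out.diameter[149:151].mean()
        assert mid == pytest.approx(3.1, abs=0.005)
        diffs = np.diff(out.diameter[99:201])
        assert np.all(diffs >= 0)  # monotone ramp

    def test_long_gap_left_invalid(self):
        n_gap = 300  # 1.2 s at 250 Hz
        diam = np.concatenate([np.full(100, 3.0), np.zeros(n_gap), np.full(100, 3.0)])
        valid = np.concatenate([np.ones(100), np.zeros(n_gap), np.ones(100)]).astype(bool)
        out = interpolate_blinks(_stream(diam, valid))
        assert not out.valid[100:100 + n_gap].any()

    def test_boundary_gap_never_interpolated(self):
        diam = np.concatenate([np.zeros(50), np.full(200, 3.0)])
        valid = np.concatenate([np.zeros(50), np.ones(200)]).astype(bool)
        out = interpolate_blinks(_stream(diam, valid))
        assert not out.valid[:50].any()

    def test_clean_stream_unchanged(self, flat_stream):
        out = interpolate_blinks(flat_stream)
        np.testing.assert_array_equal(out.diameter, flat_stream.diameter)
        assert out.valid.all()

    @given(st.integers(1, 240))
    @settings(max_examples=20, deadline=None)
    def test_valid_samples_never_changed(self, gap_len):
        rng = np.random.default_rng(gap_len)
        diam = rng.uniform(2, 5, 600)
        valid = np.ones(600, dtype=bool)
        valid[200:200 + gap_len] = False
        out = interpolate_blinks(_stream(diam, valid))
        np.testing.assert_array_equal(out.diameter[valid], diam[valid])


class TestFlagArtifacts:
    def test_amplitude_threshold(self):
        mask = flag_artifacts(_stream([3.0, 0.95, 3.0]))
        assert mask.tolist() == [False, True, True]  # jump back also > grad

    def test_gradient_threshold(self):
        mask = flag_artifacts(_stream([3.00, 3.03, 3.04]))
        assert mask.tolist() == [False, True, False]
        mask2 = flag_artifacts(_stream([3.00, 3.019, 3.038]))
        assert not mask2.any()

    def test_gaze_threshold(self):
        s = _stream([3.0, 3.0, 3.0], gaze=[0.0, 6.0, 4.9])
        mask = flag_artifacts(s)
        assert mask.tolist() == [False, True, False]

    def test_monotone_in_gradient_threshold(self, rng):
        s = _stream(rng.uniform(2, 5, 500))
        loose = flag_artifacts(s, grad_max=0.5)
        tight = flag_artifacts(s, grad_max=0.01)
        assert not (loose & ~tight).any()  # raising grad_max never adds flags


class TestBaseline:
    def test_constant_trace(self, flat_stream):
        out = baseline_per_trial(flat_stream, [5.0, 10.0])
        np.testing.assert_allclose(out["baseline_pupil"], 3.0)
        assert not out["artifact_flag"].any()

    def test_linear_ramp_mean(self):
        n = 500
        s = _stream(2.0 + np.arange(n) / 250.0 / 2.0 * 2.0)  # 2->3 over 1 s window
        out = baseline_per_trial(s, [1.0])
        assert out["baseline_pupil"][0] == pytest.approx(2.5, abs=0.01)

    def test_artifact_in_window_flags_trial(self, flat_stream):
        mask = np.zeros(len(flat_stream.time), dtype=bool)
        mask[int(4.5 * 250)] = True
        out = baseline_per_trial(flat_stream, [5.0, 10.0], artifact_mask=mask)
        assert out["artifact_flag"].tolist() == [True, False]
        assert np.isnan(out["baseline_pupil"][0])

    def test_onset_outside_stream_errors(self, flat_stream):
        with pytest.raises(ValueError, match="trial 0"):
            baseline_per_trial(flat_stream, [0.5])


class TestExclude:
    def test_per_reason_tally(self):
        rt = np.full(100, 0.7)
        rt[0] = 0.09
        art = np.zeros(100, dtype=bool)
        art[1:3] = True
        t = pd.DataFrame({"subject": 0, "rt": rt, "artifact_flag": art,
                          "accuracy": 1, "baseline_pupil": 4.0})
        out = exclude_trials(t)
        assert len(out) == 97
        assert out.attrs["exclusions"] == {"fast": 1, "slow": 0,
                                           "artifact": 2, "retained": 97}

    def test_fast_and_retained_boundaries(self):
        t = pd.DataFrame({"subject": 0, "rt": [0.09, 0.723], "accuracy": [1, 1],
                          "artifact_flag": [False, False]})
        out = exclude_trials(t)
        assert out["rt"].tolist() == [0.723]

    def test_empty_result_errors(self):
        t = pd.DataFrame({"subject": 0, "rt": [0.05], "accuracy": [1],
                          "artifact_flag": [False]})
        with pytest.raises(ValueError):
            exclude_trials(t)


class TestBinning:
    def test_two_fifths_split(self):
        t = pd.DataFrame({"subject": 0, "trial": range(10),
                          "baseline_pupil": np.arange(10.0), "rt": 0.7,
                          "accuracy": 1})
        out = bin_by_pupil(t)
        assert (out["pupil_bin"] == "low").sum() == 4
        assert (out["pupil_bin"] == "high").sum() == 4
        assert (out["pupil_bin"] == "middle").sum() == 2
        assert set(out[out["pupil_bin"] == "low"]["baseline_pupil"]) == {0, 1, 2, 3}

    def test_490_trials_gives_196_per_bin(self):
        t = pd.DataFrame({"subject": 0, "trial": range(490),
                          "baseline_pupil": np.random.default_rng(0).normal(4, 1, 490),
                          "rt": 0.7, "accuracy": 1})
        out = bin_by_pupil(t)
        assert (out["pupil_bin"] == "low").sum() == 196
        assert (out["pupil_bin"] == "high").sum() == 196

    def test_ties_deterministic_by_trial_order(self):
        t = pd.DataFrame({"subject": 0, "trial": range(10),
                          "baseline_pupil": 4.0, "rt": 0.7, "accuracy": 1})
        out1 = bin_by_pupil(t)
        out2 = bin_by_pupil(t)
        assert (out1["pupil_bin"] == out2["pupil_bin"]).all()
        assert (out1.loc[:3, "pupil_bin"] == "low").all()

    def test_monotone_transform_invariance(self, rng):
        base = rng.normal(4, 0.5, 50)
        t1 = pd.DataFrame({"subject": 0, "trial": range(50),
                           "baseline_pupil": base, "rt": 0.7, "accuracy": 1})
        t2 = t1.copy()
        t2["baseline_pupil"] = np.exp(base)  # order-preserving transform
        assert (bin_by_pupil(t1)["pupil_bin"] == bin_by_pupil(t2)["pupil_bin"]).all()

    def test_too_few_trials_errors(self):
        t = pd.DataFrame({"subject": 0, "trial": range(4),
                          "baseline_pupil": [1., 2., 3., 4.], "rt": 0.7,
                          "accuracy": 1})
        with pytest.raises(ValueError):
            bin_by_pupil(t)
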