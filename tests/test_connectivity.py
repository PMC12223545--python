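"""Time-course cleaning, FNC estimation, QC and Δ-matrix construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

import deltafuse as df
from deltafuse.connectivity import QC_THRESHOLDS, QCReport, bandpass_sos, individual_mask


def make_tcs(tc, tr=0.8, motion=None, subject="sub-a", timepoint="baseline"):
    return df.TimecourseSet(subject, timepoint, tc, tr, motion)


class TestPostprocess:
    T = 400

    def test_cubic_trend_removed_to_numerical_zero(self, rng):
        t = np.linspace(-1, 1, self.T)
        tc = np.column_stack([1 + 2 * t - t**2 + 0.5 * t**3, 3 * t**3 - t])
        out = df.postprocess_timecourses(make_tcs(tc))
        assert np.max(np.abs(out.tc)) < 1e-8

    def test_motion_combination_removed_to_numerical_zero(self, rng):
        motion = rng.standard_normal((self.T, 6)).cumsum(axis=0) * 0.01
        tc = motion @ rng.standard_normal((6, 3))
        # despiking disabled: the property under test is the step-3 projection
        out = df.postprocess_timecourses(make_tcs(tc, motion=motion), z_thresh=np.inf)
        assert np.max(np.abs(out.tc)) < 1e-6

    def test_stopband_frequency_attenuated_20db(self):
        # 0.2 Hz lies above the 0.15 Hz band edge at TR 0.8 s
        tr = 0.8
        t = np.arange(self.T) * tr
        tc = np.sin(2 * np.pi * 0.2 * t)[:, None]
        out = df.postprocess_timecourses(make_tcs(tc, tr=tr))
        mid = slice(self.T // 4, 3 * self.T // 4)  # avoid filter edges
        # steady-state amplitude at 0.2 Hz by least-squares quadrature fit
        basis = np.column_stack(
            [np.sin(2 * np.pi * 0.2 * t[mid]), np.cos(2 * np.pi * 0.2 * t[mid])]
        )
        coef, *_ = np.linalg.lstsq(basis, out.tc[mid, 0], rcond=None)
        atten_db = 20 * np.log10(1.0 / max(np.hypot(*coef), 1e-300))
        assert atten_db >= 20

    def test_filter_response_oracle_confirms_attenuation(self):
        # independent frequency-response check of the same Butterworth band
        sos = bandpass_sos(0.8)
        w, h = signal.sosfreqz(sos, worN=[0.2], fs=1 / 0.8)
        assert 2 * 20 * np.log10(1 / abs(h[0])) >= 20  # forward-backward doubles dB

    def test_passband_frequency_preserved(self):
        tr = 0.8
        t = np.arange(self.T) * tr
        tc = np.sin(2 * np.pi * 0.05 * t)[:, None]
        out = df.postprocess_timecourses(make_tcs(tc, tr=tr))
        mid = slice(self.T // 4, 3 * self.T // 4)
        assert np.abs(out.tc[mid]).max() > 0.8

    def test_too_short_series_raises_named_minimum(self):
        with pytest.raises(ValueError, match="T >"):
            df.postprocess_timecourses(make_tcs(np.zeros((10, 2))))

    def test_outlier_spike_suppressed(self, rng):
        tc = rng.standard_normal((self.T, 1)) * 0.5
        tc[100, 0] = 50.0
        out = df.postprocess_timecourses(make_tcs(tc))
        assert np.abs(out.tc[100, 0]) < 5.0


class TestComputeFnc:
    def test_duplicated_column_perfectly_correlated(self, rng):
        x = rng.standard_normal(200)
        fnc = df.compute_fnc(make_tcs(np.column_stack([x, x, rng.standard_normal(200)])))
        assert fnc.values[0, 1] == pytest.approx(1.0)

    def test_quadrature_sinusoids_uncorrelated(self):
        t = np.linspace(0, 4 * 2 * np.pi, 400, endpoint=False)
        fnc = df.compute_fnc(make_tcs(np.column_stack([np.sin(t), np.cos(t)])))
        assert fnc.values[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_target_covariance_recovered(self, rng):
        target = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, -0.3], [0.2, -0.3, 1.0]])
        chol = np.linalg.cholesky(target)
        tc = rng.standard_normal((20000, 3)) @ chol.T
        fnc = df.compute_fnc(make_tcs(tc))
        assert np.allclose(fnc.values, target, atol=0.03)

    def test_zero_variance_column_flagged_undefined(self):
        tc = np.column_stack([np.ones(100), np.arange(100.0)])
        fnc = df.compute_fnc(make_tcs(tc))
        assert fnc.undefined[0] and not fnc.undefined[1]
        assert np.isnan(fnc.values[0, 1])
        assert fnc.values[0, 0] == 1.0

    def test_symmetric_unit_diagonal(self, rng):
        fnc = df.compute_fnc(make_tcs(rng.standard_normal((150, 8))))
        assert np.allclose(fnc.values, fnc.values.T)
        assert np.allclose(np.diag(fnc.values), 1.0)
        assert np.nanmax(np.abs(fnc.values)) <= 1.0


class TestVectorize:
    def test_53_networks_give_1378_cells(self):
        m = np.eye(53)
        assert df.vectorize_fnc(m).shape == (1378,)

    def test_row_major_upper_triangle_order(self):
        m = np.array([[1, 0.5, 0.2], [0.5, 1, -0.3], [0.2, -0.3, 1]])
        assert np.allclose(df.vectorize_fnc(m), [0.5, 0.2, -0.3])

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="n\\(n-1\\)/2"):
            df.devectorize_fnc(np.zeros(10), 53)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=2, max_value=20), st.integers(min_value=0, max_value=2**31 - 1))
    def test_round_trip_identity(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((n, n))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 1.0)
        back = df.devectorize_fnc(df.vectorize_fnc(m), n)
        assert np.array_equal(back.values, (m + m.T) / 2)


class TestQC:
    @staticmethod
    def masks(rng, n=12, shape=(8, 8, 24)):
        base = rng.random(shape) > 0.35
        out = {}
        for i in range(n):
            m = base.copy()
            flip = rng.random(shape) < 0.02
            out[f"scan{i:02d}"] = m ^ flip
        return out

    def test_identical_mask_scores_unity_and_passes(self, rng):
        masks = self.masks(rng)
        group = np.stack(list(masks.values())).mean(axis=0) > 0.9
        masks["perfect"] = group.copy()
        report = {r.scan_id: r for r in df.qc_filter(masks)}
        r = report["perfect"]
        assert (r.r_top10, r.r_bottom10, r.r_whole) == (1.0, 1.0, 1.0)
        assert r.passed

    def test_pass_fail_thresholds(self):
        # the documented decision boundaries: 0.75 / 0.55 / 0.8
        assert QCReport("a", 0.8, 0.6, 0.85).passed
        assert not QCReport("b", 0.74, 0.6, 0.85).passed
        assert not QCReport("c", 0.8, 0.54, 0.85).passed
        assert not QCReport("d", 0.8, 0.6, 0.79).passed
        assert QC_THRESHOLDS == (0.75, 0.55, 0.8)

    def test_pass_set_invariant_to_scan_order(self, rng):
        masks = self.masks(rng)
        fwd = {r.scan_id: r.passed for r in df.qc_filter(masks)}
        rev = {r.scan_id: r.passed for r in df.qc_filter(dict(reversed(masks.items())))}
        assert fwd == rev

    def test_too_few_slices_rejected(self, rng):
        with pytest.raises(ValueError, match="axial slices"):
            df.qc_filter({"a": np.ones((8, 8, 10), bool)})

    def test_individual_mask_threshold(self):
        vol = np.zeros((4, 4, 4))
        vol[:2] = 10.0  # mean = 2.5, threshold 2.25
        assert individual_mask(vol).sum() == 32


class TestBuildDelta:
    def test_identical_timepoints_give_zero(self, rng):
        feats = {f"s{i}": rng.standard_normal(6) for i in range(4)}
        d = df.build_delta(feats, {k: v.copy() for k, v in feats.items()}, "fnc_cells")
        assert np.allclose(d.data, 0)

    def test_baseline_minus_followup_sign(self):
        d = df.build_delta({"s": np.array([0.5])}, {"s": np.array([0.3])}, "fnc_cells")
        assert d.data[0, 0] == pytest.approx(0.2)

    def test_antisymmetric_under_timepoint_swap(self, rng):
        a = {f"s{i}": rng.standard_normal(5) for i in range(6)}
        b = {f"s{i}": rng.standard_normal(5) for i in range(6)}
        fwd = df.build_delta(a, b, "gmv_voxels")
        rev = df.build_delta(b, a, "gmv_voxels")
        assert np.allclose(fwd.data, -rev.data)

    def test_missing_subjects_excluded_and_logged(self, rng):
        a = {"s1": np.zeros(3), "s2": np.ones(3)}
        b = {"s1": np.zeros(3), "s3": np.ones(3)}
        with pytest.warns(UserWarning, match="excluding 2"):
            d = df.build_delta(a, b, "fnc_cells")
        assert d.subject_ids == ["s1"]
        assert set(d.excluded_subjects) == {"s2", "s3"}

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError, match="both timepoints"):
            df.build_delta({"a": np.zeros(2)}, {"b": np.zeros(2)}, "fnc_cells")

    def test_localized_gmv_change_stays_localized(self, rng):
        base = rng.standard_normal(100)
        follow = base.copy()
        follow[10:20] += 1.0
        d = df.build_delta({"s": base}, {"s": follow}, "gmv_voxels")
        assert np.all(d.data[0, 10:20] != 0)
        assert np.allclose(np.delete(d.data[0], np.s_[10:20]), 0)
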