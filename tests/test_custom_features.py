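import numpy as np
import pytest
from hypothesis import given, strategies as st

from pupilscreen.custom_features import (
    CUSTOM_FEATURE_NAMES,
    ProbeTiming,
    dilation_acceleration,
    dilation_series,
    dilation_velocity,
    extract_custom_features,
    list_custom_features,
)
from pupilscreen.errors import ParameterError, WindowError
from conftest import make_reduced_trial, make_trial


class TestDilationVelocity:
    def test_secant_arithmetic(self):
        # P_0 = 2.0 at T_0 = 0, P_1 = 2.5 at T_1 = 250 -> V_1 = 0.002
        tr = make_trial([2.0, 2.5, 3.0], sample_period_ms=250)
        v = dilation_velocity(tr, 0)
        assert v[1] == pytest.approx(0.002)

    def test_constant_series_zero(self):
        v = dilation_velocity(make_trial(np.full(10, 4.2)), 0)
        np.testing.assert_array_equal(v, 0.0)

    def test_linear_series_constant_slope(self):
        m = 0.37
        t = np.arange(20.0)
        v = dilation_velocity(make_trial(m * t + 5.0), 0)
        np.testing.assert_allclose(v[1:], m, rtol=1e-12)

    def test_additive_shift_invariance(self, rng):
        p = rng.normal(size=30)
        v1 = dilation_velocity(make_trial(p), 3)
        v2 = dilation_velocity(make_trial(p + 17.0), 3)
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    def test_invalid_origin(self):
        with pytest.raises(ParameterError):
            dilation_velocity(make_trial([1.0, 2.0]), 5)


class TestDilationAcceleration:
    def test_linear_series_zero(self):
        a = dilation_acceleration(make_trial(2.0 * np.arange(10.0)), 0)
        np.testing.assert_allclose(a, 0.0, atol=1e-15)

    def test_quadratic_closed_form(self):
        # P(t) = c t^2 from origin 0: V_i = c T_i, so
        # A_i = c (T_i - T_1)/(T_i - T_0)
        c = 0.003
        t = np.arange(12.0)
        a = dilation_acceleration(make_trial(c * t**2), 0)
        expected = np.zeros_like(t)
        expected[1:] = c * (t[1:] - t[1]) / (t[1:] - t[0])
        np.testing.assert_allclose(a, expected, rtol=1e-12)

    def test_too_short(self):
        with pytest.raises(ParameterError):
            dilation_acceleration(make_trial([1.0, 2.0]), 0)


def test_accumulated_velocity_prefix_sum(rng):
    p = rng.normal(size=40)
    ds = dilation_series(make_trial(p), 2)
    np.testing.assert_allclose(np.diff(ds.av), ds.v[1:], rtol=1e-12)
    assert ds.av[0] == ds.v[0] == 0.0


class TestExtractCustomFeatures:
    def test_exactly_22_named_features(self):
        tr = make_reduced_trial(lambda t: np.sin(t / 700.0) + 3.0)
        feats = extract_custom_features(tr)
        assert tuple(feats) == CUSTOM_FEATURE_NAMES
        assert len(feats) == 22
        assert list_custom_features() == list(CUSTOM_FEATURE_NAMES)
        assert all(np.isfinite(v) for v in feats.values())

    def test_constant_trial_degenerate_values(self):
        feats = extract_custom_features(
            make_reduced_trial(lambda t: np.full(len(t), 2.5)))
        for name in ("max_size_post_probe", "max_size_pre_probe",
                     "min_size_late", "mean_size_mid_post_probe",
                     "size_median", "size_mean"):
            assert feats[name] == 2.5
        for name in CUSTOM_FEATURE_NAMES[4:]:
            if name in ("size_median", "size_mean"):
                continue
            assert feats[name] == 0.0, name

    def test_piecewise_trial_against_direct_secant(self):
        """Flat baseline, post-probe linear rise to a plateau: pre-probe
        velocity terms vanish and the post-probe mean velocity matches a
        brute-force secant evaluation."""
        def shape(t):
            return np.where(
                t < 5000, 2.0,
                np.where(t < 6000, 2.0 + (t - 5000) / 1000.0, 3.0))

        tr = make_reduced_trial(shape, period_ms=1)
        feats = extract_custom_features(tr)
        assert feats["mean_velocity_before"] == 0.0
        assert feats["max_velocity_before"] == 0.0
        assert feats["max_size_post_probe"] == 3.0
        assert feats["mean_velocity_after"] > 0
        # independent direct evaluation from the probe origin
        t = tr.t_ms
        p = tr.pupil
        o = 5000
        sec = [(p[i] - p[o]) / (t[i] - t[o]) for i in range(o + 1, len(t))]
        assert feats["mean_velocity_after"] == pytest.approx(
            np.mean(sec), rel=1e-12)
        assert feats["max_velocity_after"] == pytest.approx(
            max(sec), rel=1e-12)

    def test_scaling_behaviour(self, rng):
        base = make_reduced_trial(
            lambda t: 3 + np.sin(t / 500.0) + 0.05 * rng.normal(size=len(t)))
        k = 3.0
        scaled = base.with_pupil(k * base.pupil)
        f1 = extract_custom_features(base)
        f2 = extract_custom_features(scaled)
        for name in ("size_std", "mean_velocity_after",
                     "max_velocity_before", "max_accum_velocity_after",
                     "accum_velocity_gain", "max_accel_post_probe"):
            assert f2[name] == pytest.approx(k * f1[name], rel=1e-9), name
        for name in ("size_kurtosis", "size_skew"):
            assert f2[name] == pytest.approx(f1[name], rel=1e-9)

    def test_item16_to_19_identities(self, rng):
        tr = make_reduced_trial(
            lambda t: 3 + 0.1 * rng.normal(size=len(t)))
        f = extract_custom_features(tr)
        assert f["accum_velocity_gain"] == pytest.approx(
            f["max_accum_velocity_after"] - f["max_accum_velocity_before"])
        assert f["velocity_accum_gap"] == pytest.approx(
            f["max_velocity_after"] - f["max_accum_velocity_before"])
        assert f["mean_velocity_accum_gap"] == pytest.approx(
            f["mean_velocity_after"] - f["max_accum_velocity_before"])
        # literal reading: item 19 duplicates item 17
        assert f["velocity_accum_gap_dup"] == f["velocity_accum_gap"]
        alt = extract_custom_features(
            tr, item19_interpretation="velocity_after_minus_accum_after")
        assert alt["velocity_accum_gap_dup"] == pytest.approx(
            f["max_velocity_after"] - f["max_accum_velocity_after"])

    def test_before_after_windows_partition_trial(self):
        tr = make_reduced_trial(lambda t: np.sin(t / 300.0))
        probe_idx = int(5000 // 16)
        before = set(range(0, probe_idx))
        after = set(range(probe_idx, len(tr)))
        assert before.isdisjoint(after)
        assert before | after == set(range(len(tr)))

    def test_short_trial_rejected(self):
        tr = make_reduced_trial(lambda t: t / 1000.0, duration_ms=4000)
        with pytest.raises(WindowError):
            extract_custom_features(tr)

    def test_scaled_timing_keeps_catalogue_defined(self):
        timing = ProbeTiming(probe_ms=1250.0, trial_end_ms=2000.0)
        tr = make_reduced_trial(lambda t: 3 + np.sin(t / 200.0),
                                duration_ms=2000, period_ms=4)
        feats = extract_custom_features(tr, timing)
        assert len(feats) == 22
        assert all(np.isfinite(v) for v in feats.values())

    def test_unknown_item19_mode_rejected(self):
        tr = make_reduced_trial(lambda t: np.sin(t / 300.0))
        with pytest.raises(ParameterError):
            extract_custom_features(tr, item19_interpretation="fixup")


@given(st.floats(-5, 5), st.floats(0.1, 4))
def test_velocity_affine_equivariance(shift, scale):
    """V(a + b*x) == b*V(x): velocity is built from pupil differences."""
    rng = np.random.default_rng(7)
    p = rng.normal(size=64)
    t1 = make_trial(p)
    t2 = make_trial(shift + scale * p)
    v1 = dilation_velocity(t1, 0)
    v2 = dilation_velocity(t2, 0)
    np.testing.assert_allclose(v2, scale * v1, rtol=1e-9, atol=1e-12)
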