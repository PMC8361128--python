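import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pupilscreen as ps
from pupilscreen.errors import ParameterError, ValidationError
from pupilscreen.general_features import (
    FeatureSpec,
    absolute_energy,
    approximate_entropy,
    basic_moments,
    build_feature_matrix,
    change_quantiles_var,
    fft_real_coefficient,
    general_feature_specs,
    linear_trend_stderr,
    list_general_features,
    number_peaks,
)
from pupilscreen.trial_io import Cohort, Group, Subject
from conftest import make_reduced_trial, make_trial


# ---------------------------------------------------------------- oracles

def naive_dft_real(x, k):
    n = len(x)
    return sum(
        x[i] * math.cos(-2 * math.pi * k * i / n) for i in range(n)
    )


def brute_force_peaks(x, n):
    count = 0
    for i in range(n, len(x) - n):
        left = all(x[i] > x[i - off] for off in range(1, n + 1))
        right = all(x[i] > x[i + off] for off in range(1, n + 1))
        count += left and right
    return count


def literal_apen(x, m, r):
    """Independent transcription of the Pincus definition."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm):
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for ti in templates:
            c = sum(
                max(abs(a - b) for a, b in zip(ti, tj)) <= r
                for tj in templates
            ) / len(templates)
            total += math.log(c)
        return total / len(templates)

    return phi(m) - phi(m + 1)


def corridor_variance(x, ql, qh):
    """Literal corridor-feature oracle: absolute consecutive changes with
    both endpoints inside the [ql, qh] quantile band, population var."""
    lo = float(np.quantile(x, ql))
    hi = float(np.quantile(x, qh))
    diffs = [
        abs(x[i + 1] - x[i])
        for i in range(len(x) - 1)
        if lo <= x[i] <= hi and lo <= x[i + 1] <= hi
    ]
    if len(diffs) < 2:
        return 0.0
    mu = sum(diffs) / len(diffs)
    return sum((d - mu) ** 2 for d in diffs) / len(diffs)


# ------------------------------------------------------------------ tests

class TestAbsoluteEnergy:
    def test_examples(self):
        assert absolute_energy([1, 2, 3]) == 14
        assert absolute_energy(np.zeros(10)) == 0

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=100)
        oracle = sum(float(v) ** 2 for v in x)
        assert absolute_energy(x) == pytest.approx(oracle, rel=1e-12)

    @given(st.floats(0.1, 10))
    def test_quadratic_scaling(self, k):
        x = np.arange(1.0, 20.0)
        assert absolute_energy(k * x) == pytest.approx(
            k**2 * absolute_energy(x), rel=1e-9)


class TestFFTRealCoefficient:
    def test_hand_dft(self):
        assert fft_real_coefficient([1, 0, -1, 0], 1) == pytest.approx(2.0)

    def test_constant_spectrum(self):
        c = 3.7
        x = np.full(16, c)
        assert fft_real_coefficient(x, 0) == pytest.approx(16 * c)
        assert fft_real_coefficient(x, 5) == pytest.approx(0.0, abs=1e-9)

    def test_matches_naive_dft(self, rng):
        x = rng.normal(size=64)
        assert fft_real_coefficient(x, 2) == pytest.approx(
            naive_dft_real(x, 2), rel=1e-9)

    def test_linearity(self, rng):
        x, y = rng.normal(size=32), rng.normal(size=32)
        lhs = fft_real_coefficient(2.0 * x + y, 3)
        rhs = 2.0 * fft_real_coefficient(x, 3) + fft_real_coefficient(y, 3)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_out_of_range_k(self):
        with pytest.raises(ParameterError):
            fft_real_coefficient([1.0, 2.0], 5)


class TestChangeQuantilesVar:
    def test_constant_series(self):
        assert change_quantiles_var(np.full(50, 2.0)) == 0.0

    def test_no_qualifying_pair(self):
        # the median value 50 occurs twice, never adjacently; a narrow
        # corridor captures only those samples
        x = np.array([0, 50, 100, 0, 100, 0, 100, 50, 0, 100], float)
        assert change_quantiles_var(x, 0.49, 0.51) == 0.0

    def test_matches_corridor_oracle(self, rng):
        x = rng.normal(size=200)
        assert change_quantiles_var(x, 0.4, 0.8) == pytest.approx(
            corridor_variance(x, 0.4, 0.8), rel=1e-10)

    def test_bad_quantiles(self):
        with pytest.raises(ParameterError):
            change_quantiles_var(np.arange(10.0), 0.8, 0.4)


class TestApproximateEntropy:
    def test_constant_series(self):
        assert approximate_entropy(np.full(50, 1.0)) == 0.0

    def test_regularity_ordering(self, rng):
        alternating = np.tile([0.0, 1.0], 50)
        noise = rng.uniform(size=100)
        assert approximate_entropy(alternating) < approximate_entropy(noise)

    def test_matches_literal_pincus(self, rng):
        x = rng.normal(size=60)
        r = 0.2 * float(np.std(x))
        assert approximate_entropy(x, 2, 0.2) == pytest.approx(
            literal_apen(x, 2, r), abs=1e-9)

    def test_shift_and_scale_invariance(self, rng):
        x = rng.normal(size=80)
        a = approximate_entropy(x)
        assert approximate_entropy(x + 100.0) == pytest.approx(a, abs=1e-9)
        # r scales with std, so positive rescaling leaves ApEn unchanged
        assert approximate_entropy(5.0 * x) == pytest.approx(a, abs=1e-9)

    def test_too_short(self):
        with pytest.raises(ParameterError):
            approximate_entropy([1.0, 2.0, 3.0], m=2)


class TestNumberPeaks:
    def test_monotone_series_has_none(self):
        assert number_peaks(np.arange(40.0), 10) == 0

    def test_single_bump(self):
        x = np.r_[np.zeros(12), [1.0, 2.0, 1.0], np.zeros(12)]
        assert number_peaks(x, 10) == 1

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=300)
        assert number_peaks(x, 10) == brute_force_peaks(x, 10)

    def test_shift_invariance(self, rng):
        x = rng.normal(size=120)
        assert number_peaks(x, 5) == number_peaks(x + 42.0, 5)

    def test_short_series_returns_zero(self):
        assert number_peaks(np.arange(15.0), 10) == 0


class TestLinearTrendStderr:
    def test_perfect_line(self):
        assert linear_trend_stderr(3.0 * np.arange(20.0) + 1) == (
            pytest.approx(0.0, abs=1e-12))

    def test_closed_form_triangle(self):
        # x=[0,1,0]: slope 0, SSE=2/3, sxx=2 -> sqrt((2/3)/1/2)
        assert linear_trend_stderr([0.0, 1.0, 0.0]) == pytest.approx(
            math.sqrt((2 / 3) / 1 / 2))

    def test_constant(self):
        assert linear_trend_stderr(np.full(10, 4.0)) == 0.0

    def test_matches_scipy_linregress(self, rng):
        x = rng.normal(size=50)
        from scipy.stats import linregress

        res = linregress(np.arange(50.0), x)
        assert linear_trend_stderr(x) == pytest.approx(
            res.stderr, rel=1e-10)


class TestBasicMoments:
    def test_small_example(self):
        m = basic_moments([1, 2, 3])
        assert m["mean"] == 2 and m["median"] == 2
        assert m["variance"] == pytest.approx(2 / 3)
        assert m["std"] == pytest.approx(math.sqrt(2 / 3))

    def test_constant_conventions(self):
        m = basic_moments(np.full(8, 3.0))
        assert m["variance"] == 0 and m["skew"] == 0 and m["kurtosis"] == 0

    def test_matches_textbook_formulas(self, rng):
        x = rng.normal(size=200)
        m = basic_moments(x)
        mu = x.mean()
        c2 = ((x - mu) ** 2).mean()
        c3 = ((x - mu) ** 3).mean()
        c4 = ((x - mu) ** 4).mean()
        assert m["variance"] == pytest.approx(c2, rel=1e-12)
        assert m["skew"] == pytest.approx(c3 / c2**1.5, rel=1e-10)
        assert m["kurtosis"] == pytest.approx(c4 / c2**2 - 3, rel=1e-10)


class TestRegistryAndMatrix:
    def test_registry_names(self):
        names = list_general_features()
        assert len(names) == 12
        assert len(set(names)) == 12
        assert "absolute_energy" in names and "approx_entropy_m2" in names

    def test_every_feature_finite_on_observed_trials(self, rng):
        tr = make_trial(3 + rng.normal(size=64))
        for spec in general_feature_specs():
            assert np.isfinite(spec(tr)), spec.name

    def test_identical_trials_average_to_trial_value(self):
        tr1 = make_reduced_trial(lambda t: 3 + np.sin(t / 400.0),
                                 trial_id="t1")
        tr2 = make_reduced_trial(lambda t: 3 + np.sin(t / 400.0),
                                 trial_id="t2")
        cohort = Cohort([
            Subject("a", Group.ADHD_POSITIVE, [tr1, tr2]),
            Subject("b", Group.CONTROL, [tr1]),
        ])
        fm = build_feature_matrix(cohort)
        per_trial = ps.extract_custom_features(tr1)["size_std"]
        assert fm.column("size_std")[0] == pytest.approx(per_trial)

    def test_default_registry_is_34_columns(self):
        tr = make_reduced_trial(lambda t: 3 + np.cos(t / 300.0))
        cohort = Cohort([
            Subject("a", Group.ADHD_POSITIVE, [tr]),
            Subject("b", Group.CONTROL, [tr]),
        ])
        fm = build_feature_matrix(cohort)
        assert len(fm.feature_names) == 34
        assert fm.feature_names[:22] == list(ps.list_custom_features())

    def test_two_stage_energy_oracle(self, rng):
        trials_a = [make_trial(rng.normal(size=64), trial_id=f"t{i}")
                    for i in range(3)]
        cohort = Cohort([Subject("a", Group.CONTROL, trials_a)])
        spec = [s for s in general_feature_specs()
                if s.name == "absolute_energy"]
        fm = build_feature_matrix(cohort, spec)
        oracle = np.mean([np.sum(t.pupil**2) for t in trials_a])
        assert fm.values[0, 0] == pytest.approx(oracle, rel=1e-12)

    def test_spec_failing_everywhere_raises(self):
        tr = make_trial(np.arange(32.0))

        def broken(trial):
            raise ParameterError("nope")

        cohort = Cohort([Subject("a", Group.CONTROL, [tr])])
        with pytest.raises(ValidationError, match="broken.*a|a.*broken"):
            build_feature_matrix(cohort, [FeatureSpec("broken", broken)])

    def test_duplicate_spec_names_rejected(self):
        tr = make_trial(np.arange(32.0))
        cohort = Cohort([Subject("a", Group.CONTROL, [tr])])
        spec = general_feature_specs()[0]
        with pytest.raises(ParameterError):
            build_feature_matrix(cohort, [spec, spec])
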