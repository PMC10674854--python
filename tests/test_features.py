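import numpy as np
import pytest

from fingertap import (
    FEATURE_NAMES,
    Demographics,
    amplitude_stats,
    build_feature_vector,
    decrement_features,
    feature_label_correlations,
    fit_piecewise,
    frequency_and_count,
    halt_hesitation_count,
    velocity_series,
    velocity_stats,
)
from fingertap.errors import ValidationError

from conftest import make_peaks


class TestAmplitudeStats:
    @pytest.mark.parametrize(
        "amps, avg, var",
        [([1, 2, 3], 2.0, 2.0 / 3.0), ([5], 5.0, 0.0)],
    )
    def test_small_cases(self, amps, avg, var):
        got_avg, got_var = amplitude_stats(make_peaks(amps))
        assert got_avg == pytest.approx(avg)
        assert got_var == pytest.approx(var)

    def test_seeded_normal_sample_mean(self, rng):
        a = rng.normal(1.5, 0.2, size=100)
        avg, var = amplitude_stats(make_peaks(a))
        sem = 0.2 / np.sqrt(100)
        assert abs(avg - 1.5) < 3 * sem
        assert avg == pytest.approx(a.mean(), abs=1e-12)
        assert var == pytest.approx(a.var(), abs=1e-12)


class TestVelocity:
    def test_basic_formula(self):
        v = velocity_series(make_peaks([1.0, 1.0], dt=0.5))
        np.testing.assert_allclose(v.values, [4.0])

    def test_zero_amplitude_second_peak(self):
        v = velocity_series(make_peaks([2.0, 0.0], dt=1.0))
        np.testing.assert_allclose(v.values, [2.0])

    def test_constant_amplitude_and_spacing_gives_constant_velocity(self):
        v = velocity_series(make_peaks([1.2] * 8, dt=0.4))
        assert np.ptp(v.values) == pytest.approx(0.0)

    def test_single_peak_rejected(self):
        with pytest.raises(ValidationError):
            velocity_series(make_peaks([1.0]))

    @pytest.mark.parametrize("vals, avg, var", [([4, 4, 4], 4.0, 0.0), ([2, 4], 3.0, 1.0)])
    def test_stats_small_cases(self, vals, avg, var):
        v = velocity_series(make_peaks(np.ones(len(vals) + 1)))
        v.values = np.array(vals, dtype=float)
        got_avg, got_var = velocity_stats(v)
        assert (got_avg, got_var) == (pytest.approx(avg), pytest.approx(var))

    def test_stats_match_two_pass_oracle(self, rng):
        vals = rng.uniform(0.5, 9.0, size=50)
        v = velocity_series(make_peaks(np.ones(51)))
        v.values = vals
        avg, var = velocity_stats(v)
        # independent two-pass computation
        s = 0.0
        for x in vals:
            s += x
        mean = s / len(vals)
        ss = 0.0
        for x in vals:
            ss += (x - mean) ** 2
        assert avg == pytest.approx(mean, abs=1e-12)
        assert var == pytest.approx(ss / len(vals), abs=1e-12)


class TestPiecewiseFit:
    def test_exact_recovery_from_generated_data(self):
        x = np.arange(1, 13, dtype=float)
        bp = 6.0
        y = 2.0 - 0.05 * x - 0.20 * np.maximum(0.0, x - bp)
        fit = fit_piecewise(x, y)
        assert fit.breakpoint == bp
        assert fit.intercept == pytest.approx(2.0, rel=1e-6)
        assert fit.slope1 == pytest.approx(-0.05, rel=1e-6)
        assert fit.slope2 == pytest.approx(-0.20, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_collinear_data_degenerates_to_line(self):
        x = np.arange(1, 11, dtype=float)
        y = 3.0 + 0.5 * x
        fit = fit_piecewise(x, y)
        assert abs(fit.slope2) <= 1e-8 * abs(fit.slope1) + 1e-12
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_x_reversal_mirrors_slopes_same_rss(self, rng):
        x = np.arange(1, 15, dtype=float)
        y = 1.5 - 0.02 * x - 0.15 * np.maximum(0.0, x - 8) + rng.normal(0, 0.03, x.size)
        fwd = fit_piecewise(x, y)
        rev = fit_piecewise(x, y[::-1])
        assert rev.rss == pytest.approx(fwd.rss, rel=1e-6)
        # total slopes of the two segments swap sign under reversal
        assert rev.slope1 == pytest.approx(-(fwd.slope1 + fwd.slope2), rel=1e-6)
        assert rev.slope1 + rev.slope2 == pytest.approx(-fwd.slope1, rel=1e-6)

    def test_fewer_than_four_points_flagged_degenerate(self):
        fit = fit_piecewise(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert fit.degenerate and fit.slope2 == 0.0
        assert fit.breakpoint == pytest.approx(2.0)


class TestDecrement:
    def test_flat_then_drop_recovers_breakpoint(self):
        n = np.arange(1, 13, dtype=float)
        amps = np.where(n <= 5, 1.0, 1.0 - 0.1 * (n - 5))
        s1, s2, bp = decrement_features(amps)
        assert s1 == pytest.approx(0.0, abs=1e-10)
        assert s2 < 0
        assert bp == 5.0

    def test_constant_amplitudes_have_zero_slopes(self):
        s1, s2, _ = decrement_features(np.full(10, 1.3))
        assert s1 == pytest.approx(0.0, abs=1e-12)
        assert s2 == pytest.approx(0.0, abs=1e-12)

    def test_increasing_amplitudes_have_positive_slope(self):
        s1, _, _ = decrement_features(np.linspace(0.5, 1.5, 10))
        assert s1 > 0


class TestHaltHesitation:
    def test_half_depth_dip_is_flagged(self):
        amps = np.full(11, 1.0)
        amps[5] = 0.5
        assert halt_hesitation_count(make_peaks(amps)) == 1

    def test_shallow_dip_is_not_flagged(self):
        amps = np.full(11, 1.0)
        amps[5] = 0.9
        assert halt_hesitation_count(make_peaks(amps)) == 0

    def test_on_trend_peaks_count_zero(self):
        amps = 1.4 - 0.02 * np.arange(12)
        assert halt_hesitation_count(make_peaks(amps)) == 0

    def test_upward_outlier_never_counts(self):
        amps = np.full(11, 1.0)
        amps[5] = 1.6
        assert halt_hesitation_count(make_peaks(amps)) == 0

    def test_scale_invariance(self):
        amps = np.full(15, 1.0)
        amps[[4, 9]] = 0.45
        base = halt_hesitation_count(make_peaks(amps))
        assert base == 2
        for c in (0.01, 7.0, 500.0):
            assert halt_hesitation_count(make_peaks(amps * c)) == base

    def test_too_few_peaks_returns_zero(self, caplog):
        assert halt_hesitation_count(make_peaks([1.0, 1.0])) == 0

    def test_leave_one_out_variant_flags_clear_dip(self):
        amps = np.full(11, 1.0)
        amps[5] = 0.5
        assert halt_hesitation_count(make_peaks(amps), leave_one_out=True) == 1


class TestFrequency:
    def test_eleven_peaks_over_five_seconds(self):
        peaks = make_peaks(np.ones(11), dt=0.5)  # span 5 s
        freq, n = frequency_and_count(peaks)
        assert (freq, n) == (pytest.approx(2.0), 11)

    def test_two_peaks(self):
        freq, _ = frequency_and_count(make_peaks(np.ones(2), dt=0.4))
        assert freq == pytest.approx(2.5)

    def test_single_peak_flagged_zero(self):
        freq, n = frequency_and_count(make_peaks([1.0]))
        assert (freq, n) == (0.0, 1)


class TestFeatureVector:
    def test_canonical_order_and_length(self, demographics):
        fv = build_feature_vector(make_peaks(np.linspace(1.4, 1.0, 10)), demographics)
        assert tuple(fv.values) == FEATURE_NAMES
        assert fv.to_array().shape == (15,)

    def test_age_isolation(self):
        peaks = make_peaks(np.linspace(1.4, 1.0, 10))
        a = build_feature_vector(peaks, Demographics(50, "female")).values
        b = build_feature_vector(peaks, Demographics(80, "female")).values
        diff = {k for k in FEATURE_NAMES if a[k] != b[k]}
        assert diff == {"age"}

    def test_matches_independent_recomputation(self, rng, demographics):
        """Every entry equals a from-scratch evaluation of its formula."""
        amps = rng.uniform(0.8, 1.6, size=14)
        peaks = make_peaks(amps, dt=0.35)
        fv = build_feature_vector(peaks, demographics)

        t, a, n = peaks.times, peaks.amplitudes, peaks.n
        assert fv["age"] == demographics.age
        assert fv["sex"] == 1.0
        assert fv["amp_avg"] == pytest.approx(sum(a) / n, abs=1e-12)
        assert fv["amp_var"] == pytest.approx(
            sum((ai - sum(a) / n) ** 2 for ai in a) / n, abs=1e-12
        )
        vel = [(a[i] + a[i - 1]) / (t[i] - t[i - 1]) for i in range(1, n)]
        assert fv["vel_avg"] == pytest.approx(sum(vel) / len(vel), abs=1e-12)
        assert fv["freq"] == pytest.approx((n - 1) / (t[-1] - t[0]), abs=1e-12)
        assert fv["n_peaks"] == n
        # trend features agree with a brute-force refit
        s1, s2, bp = decrement_features(a)
        assert (fv["amp_alpha1"], fv["amp_alpha2"], fv["amp_bp"]) == (s1, s2, bp)

    def test_time_unit_consistency(self, demographics):
        """The same physical motion at twice the frame rate scores identically."""
        amps = np.linspace(1.4, 0.9, 12)
        slow = make_peaks(amps, dt=0.4, fps=30.0)
        fast = make_peaks(amps, dt=0.4, fps=60.0)
        a = build_feature_vector(slow, demographics).to_array()
        b = build_feature_vector(fast, demographics).to_array()
        np.testing.assert_allclose(a, b, rtol=1e-6)


class TestCorrelations:
    def _matrix(self, rng, n=40):
        return rng.normal(size=(n, len(FEATURE_NAMES)))

    def test_feature_equal_to_label(self, rng):
        X = self._matrix(rng)
        labels = rng.integers(0, 5, size=40).astype(float)
        X[:, 3] = labels
        X[:, 7] = -labels
        r, flags = feature_label_correlations(X, labels)
        assert r[3] == pytest.approx(1.0)
        assert r[7] == pytest.approx(-1.0)
        assert flags == []

    def test_constant_feature_flagged_zero(self, rng):
        X = self._matrix(rng)
        X[:, 0] = 5.0
        r, flags = feature_label_correlations(X, rng.integers(0, 5, size=40))
        assert r[0] == 0.0
        assert "age" in flags

    def test_null_feature_uncorrelated(self, rng):
        X = rng.normal(size=(1000, len(FEATURE_NAMES)))
        labels = rng.integers(0, 5, size=1000)
        r, _ = feature_label_correlations(X, labels)
        assert np.abs(r).max() < 0.1
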