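import itertools

import numpy as np
import pytest
from scipy import stats

from circaheart.detectors import (DETECTORS, TimeSeries, arser_test,
                                  concordance_null_pmf, f24_statistic,
                                  f24_test, harmonic_regression_test,
                                  jtk_cycle_test, kendall_tau,
                                  lomb_scargle_power, lomb_scargle_test,
                                  mack_wolfe_statistic, rain_test,
                                  _reference_blocks)


def cosinor(t, mesor=10.0, amp=3.0, phase=9.0, period=24.0):
    return mesor + amp * np.cos(2 * np.pi * (t - phase) / period)


@pytest.fixture
def noisy_ts(zt_times):
    rng = np.random.default_rng(99)
    y = cosinor(zt_times) * np.exp(rng.normal(0, 0.15, zt_times.size))
    return TimeSeries(zt_times, y)


class TestTimeSeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            TimeSeries(np.array([1.0, 2.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="distinct"):
            TimeSeries(np.array([1.0, 1.0, 2.0, 2.0]), np.ones(4))
        with pytest.raises(ValueError, match="period"):
            TimeSeries(np.arange(4.0), np.ones(4), period=0)


class TestDetectorInvariances:
    """p-values are invariant to adding a constant and to positive rescaling."""

    @pytest.mark.parametrize("name", list(DETECTORS))
    def test_shift_and_scale_invariance(self, name, noisy_ts):
        def run(ts):
            if name == "f24":
                return DETECTORS[name](ts, n_perm=300, rng=np.random.default_rng(1))
            return DETECTORS[name](ts)

        base = run(noisy_ts)
        shifted = run(TimeSeries(noisy_ts.times, noisy_ts.values + 100.0))
        scaled = run(TimeSeries(noisy_ts.times, noisy_ts.values * 3.5))
        assert shifted.p == pytest.approx(base.p, rel=1e-9)
        assert scaled.p == pytest.approx(base.p, rel=1e-9)

    @pytest.mark.parametrize("name", list(DETECTORS))
    def test_constant_series_p_is_one(self, name, zt_times):
        ts = TimeSeries(zt_times, np.full(18, 5.0))
        if name == "f24":
            res = DETECTORS[name](ts, n_perm=100, rng=np.random.default_rng(0))
        else:
            res = DETECTORS[name](ts)
        assert res.p == 1.0


class TestHarmonicRegression:
    def test_noise_free_cosinor_recovered(self, zt_times):
        res = harmonic_regression_test(TimeSeries(zt_times, cosinor(zt_times)))
        assert res.p < 1e-10
        assert res.phase == pytest.approx(9.0, abs=1e-9)
        assert res.amplitude == pytest.approx(3.0, abs=1e-9)
        assert res.mesor == pytest.approx(10.0, abs=1e-9)

    def test_constant_input(self, zt_times):
        res = harmonic_regression_test(TimeSeries(zt_times, np.full(18, 5.0)))
        assert res.p == 1.0 and res.amplitude == 0.0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            harmonic_regression_test(TimeSeries(np.array([0.0, 8.0, 16.0]),
                                                np.array([1.0, 2.0, 3.0])))

    @pytest.mark.parametrize("delta", [3.0, 7.5, 20.0])
    def test_phase_equivariance_under_time_shift(self, zt_times, delta):
        """Shifting the whole series by delta hours shifts the peak estimate
        by delta (mod 24)."""
        rng = np.random.default_rng(3)
        y = cosinor(zt_times, phase=5.0) + rng.normal(0, 0.3, zt_times.size)
        a = harmonic_regression_test(TimeSeries(zt_times, y))
        b = harmonic_regression_test(TimeSeries(zt_times + delta, y))
        assert b.phase == pytest.approx((a.phase + delta) % 24, abs=1e-9)

    def test_null_p_distribution_uniform(self, zt_times):
        """Gaussian iid null: the cosinor F-test p-value is exactly uniform."""
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(10_000):
            res = harmonic_regression_test(TimeSeries(zt_times, rng.normal(0, 1, 18)))
            ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestLombScargle:
    def test_matches_classical_periodogram_on_even_spacing(self):
        t = np.arange(24.0)
        rng = np.random.default_rng(8)
        y = cosinor(t, amp=1.5) + rng.normal(0, 0.5, 24)
        z = lomb_scargle_power(t, y, np.array([24.0]))[0]
        yc = y - y.mean()
        w = 2 * np.pi / 24.0
        classical = ((yc @ np.cos(w * t)) ** 2 + (yc @ np.sin(w * t)) ** 2) / len(t)
        assert z == pytest.approx(classical / yc.var(ddof=1), abs=1e-9)

    def test_grid_requires_24_points(self, noisy_ts):
        with pytest.raises(ValueError):
            lomb_scargle_test(noisy_ts, n_periods=10)

    def test_null_rejection_bounded(self, zt_times):
        rng = np.random.default_rng(12)
        sigma = np.sqrt(np.log1p(0.2 ** 2))
        rej = sum(
            lomb_scargle_test(TimeSeries(zt_times, 10 * np.exp(rng.normal(0, sigma, 18)))).p < 0.05
            for _ in range(2000)
        )
        assert rej / 2000 <= 0.07


class TestKendallTau:
    def test_perfect_agreement_and_reversal(self):
        assert kendall_tau([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
        assert kendall_tau([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 2], [1, 2, 3])

    def test_matches_pair_count_definition_with_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = 50
            x = rng.integers(0, 10, n).astype(float)
            y = rng.integers(0, 10, n).astype(float)
            s = 0.0
            tx = ty = 0.0
            for i, j in itertools.combinations(range(n), 2):
                s += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            n0 = n * (n - 1) / 2
            tx = sum(c * (c - 1) / 2 for c in np.bincount(x.astype(int)))
            ty = sum(c * (c - 1) / 2 for c in np.bincount(y.astype(int)))
            expect = s / np.sqrt((n0 - tx) * (n0 - ty))
            assert kendall_tau(x, y) == pytest.approx(expect, abs=1e-12)


class TestJTK:
    def test_reference_pattern_gets_best_lag_and_unit_tau(self, zt_times):
        """Data equal to the reference cosine: tau-b = 1 at the matching lag
        (replicates tie exactly as the reference does) and p is tiny."""
        y = cosinor(zt_times, phase=9.0)
        res = jtk_cycle_test(TimeSeries(zt_times, y))
        assert res.phase == pytest.approx(9.0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p < 1e-4

    def test_untied_reference_pattern_attains_minimal_exact_p(self, zt_times):
        rng = np.random.default_rng(19)
        y = cosinor(zt_times, phase=9.0) + rng.normal(0, 1e-6, 18)
        res = jtk_cycle_test(TimeSeries(zt_times, y))
        # all cross-block pairs concordant at the best lag -> top of the pmf
        pmf = concordance_null_pmf((3, 6, 6, 3))
        assert res.p <= 6 * pmf[-1] + 1e-15

    def test_antiphase_shifts_best_lag_12h(self, zt_times):
        rng = np.random.default_rng(21)
        noise = rng.normal(0, 0.2, 18)
        a = jtk_cycle_test(TimeSeries(zt_times, cosinor(zt_times, phase=5.0) + noise))
        b = jtk_cycle_test(TimeSeries(zt_times, -cosinor(zt_times, phase=5.0) + noise))
        assert (b.phase - a.phase) % 24 == pytest.approx(12.0)

    def test_exact_per_lag_p_matches_permutation_enumeration(self):
        """n = 6 (one replicate per ZT): DP tail equals the 720-permutation tail."""
        t = np.array([1.0, 5.0, 9.0, 13.0, 17.0, 21.0])
        rng = np.random.default_rng(23)
        y = rng.normal(0, 1, 6)
        lag = 5.0
        ref = np.cos(2 * np.pi * (t - lag) / 24.0)
        block_of_tp, sizes = _reference_blocks(ref, np.ones(6, dtype=int))
        blocks = block_of_tp  # one observation per timepoint

        def concordance(yy):
            return sum(
                1
                for i, j in itertools.combinations(range(6), 2)
                if blocks[j] > blocks[i] and yy[j] > yy[i]
                or blocks[i] > blocks[j] and yy[i] > yy[j]
            )

        t_obs = concordance(y)
        count = sum(concordance(p) >= t_obs for p in itertools.permutations(y))
        oracle = count / 720.0
        pmf = concordance_null_pmf(sizes)
        assert pmf[t_obs:].sum() == pytest.approx(oracle, abs=1e-12)


class TestArser:
    def test_noise_free_cosine_selects_24h(self, zt_times):
        res = arser_test(TimeSeries(zt_times, cosinor(zt_times)))
        assert abs(res.period - 24.0) < 0.5
        assert res.p < 1e-6

    def test_pure_linear_trend_not_rhythmic(self, zt_times):
        """A pure trend is absorbed by the nuisance covariate: no rhythm left."""
        res = arser_test(TimeSeries(zt_times, 1.0 + 0.5 * zt_times))
        assert res.p > 0.5

    def test_pinned_period_matches_independent_linear_model_f_test(self, zt_times):
        """With the period search pinned, the p-value equals the textbook
        partial F test of the cosinor pair given intercept + trend, computed
        here with an independent OLS fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        tt = np.unique(zt_times)
        profile = cosinor(tt, amp=2.0) + rng.normal(0, 0.5, 6)
        res = arser_test(TimeSeries(tt, profile), fix_period=24.0)
        w = 2 * np.pi / 24.0
        x_full = sm.add_constant(np.column_stack(
            [tt, np.cos(w * tt), np.sin(w * tt)]))
        x_red = sm.add_constant(tt)
        full = sm.OLS(profile, x_full).fit()
        red = sm.OLS(profile, x_red).fit()
        f = ((red.ssr - full.ssr) / 2) / (full.ssr / full.df_resid)
        p = stats.f.sf(f, 2, full.df_resid)
        assert res.statistic == pytest.approx(f, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)


class TestRain:
    def test_clean_umbrella_peak_recovered(self, zt_times):
        y = cosinor(zt_times, phase=9.0)
        res = rain_test(TimeSeries(zt_times, y))
        assert res.phase == pytest.approx(9.0)
        assert res.p < 0.01

    def test_monotone_data_peaks_at_last_timepoint(self, zt_times):
        rng = np.random.default_rng(5)
        y = zt_times + rng.uniform(0, 0.5, 18)  # strictly increasing in time
        res = rain_test(TimeSeries(zt_times, y))
        assert res.phase == pytest.approx(21.0)

    def test_statistic_matches_pairwise_count_oracle(self):
        t = np.repeat([1.0, 5.0, 9.0, 13.0, 17.0, 21.0], 2)
        rng = np.random.default_rng(37)
        y = rng.normal(0, 1, 12)
        ts = TimeSeries(t, y)
        groups = [y[t == u] for u in np.unique(t)]
        for peak in range(1, 7):
            expect = 0.0
            for i, j in itertools.combinations(range(6), 2):
                if j + 1 <= peak:
                    expect += sum(b > a for a in groups[i] for b in groups[j])
                elif i + 1 >= peak:
                    expect += sum(b < a for a in groups[i] for b in groups[j])
            assert mack_wolfe_statistic(ts, peak) == pytest.approx(expect, abs=1e-12)


class TestF24:
    def test_pure_fundamental_gives_unit_fraction(self):
        tt = np.array([1.0, 5.0, 9.0, 13.0, 17.0, 21.0])
        assert f24_statistic(np.cos(2 * np.pi * tt / 24.0)) == pytest.approx(1.0)

    def test_pure_second_harmonic_gives_zero_fraction(self):
        tt = np.array([1.0, 5.0, 9.0, 13.0, 17.0, 21.0])
        assert f24_statistic(np.cos(2 * np.pi * tt / 12.0)) == pytest.approx(0.0, abs=1e-12)

    def test_permutation_p_reproducible_for_fixed_seed(self, noisy_ts):
        p1 = f24_test(noisy_ts, n_perm=1000, rng=np.random.default_rng(77)).p
        p2 = f24_test(noisy_ts, n_perm=1000, rng=np.random.default_rng(77)).p
        assert p1 == p2

    def test_unbalanced_design_rejected(self):
        t = np.array([1.0, 5.0, 9.0, 13.0, 17.0, 21.0, 1.0])
        with pytest.raises(ValueError, match="balanced"):
            f24_test(TimeSeries(t, np.arange(7.0)))
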