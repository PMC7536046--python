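"""Rolling-window pipeline: detrending, bootstrap, metrics, trends."""

import numpy as np
import pytest

from specews import (
    EWSConfig,
    SpectralEWS,
    TimeSeries,
    compute_ews,
    kendall_tau,
    lag_autocorrelation,
    lowess_detrend,
    make_scenario,
    oscillation_period,
    stationary_block_bootstrap,
    variance,
)
from specews.ews import auto_block_length

from conftest import ar1_series


class TestLowessDetrend:
    def test_constant_series_zero_residuals(self):
        ts = TimeSeries(np.arange(50.0), np.full(50, 3.7))
        _, resid = lowess_detrend(ts, span=0.3)
        np.testing.assert_allclose(resid.values, 0.0, atol=1e-10)

    def test_linear_ramp_removed(self):
        ts = TimeSeries(np.arange(200.0), np.linspace(0, 10, 200))
        _, resid = lowess_detrend(ts, span=0.2)
        assert np.std(resid.values) < 0.01 * 10

    def test_trend_plus_residuals_reconstruct(self, rng):
        ts = TimeSeries(np.arange(100.0), rng.standard_normal(100))
        trend, resid = lowess_detrend(ts, span=0.5)
        np.testing.assert_allclose(trend.values + resid.values, ts.values,
                                   atol=1e-12)

    def test_absolute_time_span(self):
        # an 80-day span on a 400-day record equals a 0.2 fraction
        ts = TimeSeries(np.arange(0.0, 400.0), np.sin(np.arange(400.0) / 30))
        _, r1 = lowess_detrend(ts, span_time=80.0)
        _, r2 = lowess_detrend(ts, span=0.2)
        np.testing.assert_allclose(r1.values, r2.values, atol=1e-12)

    def test_too_small_span_rejected(self):
        ts = TimeSeries(np.arange(100.0), np.zeros(100))
        with pytest.raises(ValueError):
            lowess_detrend(ts, span=0.01)


class TestBlockBootstrap:
    def test_sample_shapes(self, rng):
        x = rng.standard_normal(80)
        samples = stationary_block_bootstrap(x, 10, 100, seed=0)
        assert samples.shape == (100, 80)

    def test_samples_draw_from_input_values(self, rng):
        x = rng.standard_normal(50)
        samples = stationary_block_bootstrap(x, 5, 20, seed=1)
        assert np.isin(samples, x).all()

    def test_huge_block_gives_circular_rotation(self, rng):
        x = rng.standard_normal(40)
        samples = stationary_block_bootstrap(x, 1e9, 10, seed=2)
        for sample in samples:
            assert any(np.allclose(np.roll(x, k), sample) for k in range(40))

    def test_near_nominal_coverage_for_weak_correlation(self):
        """Percentile CIs for lag-1 autocorrelation approach nominal coverage
        when the correlation is weak; stronger correlation degrades coverage
        (join bias), which is a documented limitation."""
        lam, n = 0.2, 200
        cover = 0
        for trial in range(50):
            x = ar1_series(lam, n, seed=trial)
            samples = stationary_block_bootstrap(x, 10, 200, seed=trial)
            acs = np.array([lag_autocorrelation(sm, 1) for sm in samples])
            lo, hi = np.quantile(acs, [0.025, 0.975])
            cover += lo <= lam <= hi
        assert cover >= 40

    def test_invalid_block_length_rejected(self):
        with pytest.raises(ValueError):
            stationary_block_bootstrap(np.zeros(10), 0.5, 1)

    def test_auto_block_length_clipped(self):
        assert 5.0 <= auto_block_length(ar1_series(0.5, 300, 0)) <= 40.0


class TestPointMetrics:
    def test_variance_denominator_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert variance(x) == pytest.approx(np.sum((x - 2.5) ** 2) / 4)

    def test_alternating_series_lag1_ac(self):
        x = np.tile([1.0, -1.0], 20)
        assert lag_autocorrelation(x, 1) == pytest.approx(-1.0, abs=1e-12)

    def test_lag_zero_is_one(self, rng):
        assert lag_autocorrelation(rng.standard_normal(30), 0) == 1.0

    def test_matches_bruteforce_lagged_correlation(self, rng):
        x = rng.standard_normal(60)
        for tau in (1, 2, 5):
            oracle = np.corrcoef(x[:-tau], x[tau:])[0, 1]
            assert lag_autocorrelation(x, tau) == pytest.approx(oracle, rel=1e-10)

    def test_close_to_autocovariance_ratio_for_long_series(self, rng):
        # the lagged-Pearson and autocovariance-ratio estimators agree to O(1/n)
        x = rng.standard_normal(5000)
        xbar = x.mean()
        ratio = np.dot(x[:-1] - xbar, x[1:] - xbar) / np.dot(x - xbar, x - xbar)
        assert lag_autocorrelation(x, 1) == pytest.approx(ratio, abs=5e-3)

    def test_constant_segment_ac_missing(self):
        assert np.isnan(lag_autocorrelation(np.ones(20), 1))

    def test_oscillation_period_worked_value(self):
        # a spectral peak at omega0 ~ 1/3 rad/day implies a ~19-day cycle
        assert round(oscillation_period(1.0 / 3.0)) == 19


class TestKendallTau:
    def test_monotone_limits(self):
        assert kendall_tau(np.arange(10.0)) == pytest.approx(1.0)
        assert kendall_tau(-np.arange(10.0)) == pytest.approx(-1.0)

    def test_all_tied_returns_zero(self):
        assert kendall_tau(np.ones(10)) == 0.0

    def test_matches_pair_counting_oracle(self, rng):
        y = rng.integers(0, 5, size=20).astype(float)  # ties likely
        t = np.arange(20.0)
        n_c = n_d = ties_y = 0
        for i in range(20):
            for j in range(i + 1, 20):
                d = (y[j] - y[i])
                if d > 0:
                    n_c += 1
                elif d < 0:
                    n_d += 1
                else:
                    ties_y += 1
        n_pairs = 20 * 19 / 2
        tau_b = (n_c - n_d) / np.sqrt((n_pairs - ties_y) * n_pairs)
        assert kendall_tau(y, t) == pytest.approx(tau_b, rel=1e-10)


@pytest.fixture(scope="module")
def fold_results():
    ts, trunc = make_scenario("fold_forced", seed=3)
    cfg = EWSConfig(n_bootstrap=25, seed=0)
    return compute_ews(ts, cfg, truncation_time=trunc)


class TestComputeEws:
    def test_expected_metrics_present(self, fold_results):
        metrics = set(fold_results.frame["metric"])
        assert {"variance", "ac_1", "ac_2", "smax", "smax_freq",
                "w_fold", "w_hopf", "w_null"} <= metrics

    def test_ci_ordering(self, fold_results):
        f = fold_results.frame.dropna()
        assert (f["ci_lo"] <= f["boot_mean"] + 1e-12).all()
        assert (f["boot_mean"] <= f["ci_hi"] + 1e-12).all()

    def test_point_estimate_inside_own_ci(self, fold_results):
        f = fold_results.frame
        f = f[f["metric"].isin(["variance", "ac_1", "smax"])].dropna()
        inside = ((f["point"] >= f["ci_lo"]) & (f["point"] <= f["ci_hi"])).mean()
        assert inside >= 0.9

    def test_window_times_within_truncation(self, fold_results):
        assert fold_results.frame["time"].max() <= 438

    def test_weights_sum_to_one_per_window(self, fold_results):
        wide = fold_results.wide
        total = wide["w_fold"] + wide["w_hopf"] + wide["w_null"]
        np.testing.assert_allclose(total.dropna(), 1.0, atol=1e-9)

    def test_summary_mentions_kendall(self, fold_results):
        text = fold_results.summary()
        assert "Kendall tau" in text and "variance" in text

    def test_csv_and_json_export(self, fold_results, tmp_path):
        fold_results.to_csv(tmp_path / "ews.csv")
        fold_results.to_json_summary(tmp_path / "ews.json")
        import json
        payload = json.loads((tmp_path / "ews.json").read_text())
        assert "kendall_tau" in payload and "variance" in payload["kendall_tau"]

    def test_too_short_series_rejected(self):
        ts = TimeSeries(np.arange(30.0), np.random.default_rng(0).standard_normal(30))
        with pytest.raises(ValueError):
            SpectralEWS(ts, EWSConfig())


@pytest.fixture(scope="module")
def flip_batch():
    cfg = EWSConfig(n_bootstrap=0, spectral_weights=False)
    out = []
    for seed in range(8):
        ts, trunc = make_scenario("flip_forced", seed=seed)
        out.append(compute_ews(ts, cfg, truncation_time=trunc))
    return out


class TestFlipSignature:
    """Before the period-doubling, the lag-1 autocorrelation falls (lag = half
    the emerging period-2 cycle) while lag-2 rises, and S_max outpaces variance."""

    def test_lag1_down_lag2_up(self, flip_batch):
        ac1 = [r.kendall_tau["ac_1"] for r in flip_batch]
        ac2 = [r.kendall_tau["ac_2"] for r in flip_batch]
        assert np.median(ac1) < 0 < np.median(ac2)

    def test_smax_outpaces_variance(self, flip_batch):
        wins = 0
        for r in flip_batch:
            wide = r.wide
            smax_ratio = wide["smax"].iloc[-1] / wide["smax"].iloc[0]
            var_ratio = wide["variance"].iloc[-1] / wide["variance"].iloc[0]
            wins += smax_ratio > var_ratio
        assert wins > len(flip_batch) / 2
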