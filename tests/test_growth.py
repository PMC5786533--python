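"""3PLM fitting, growth rates, ANOVA calibration, trait-yield regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lidarcanopy as lc
from lidarcanopy.growth import simulate_field_season

DATES = np.array([45.0, 52, 67, 74, 88, 95, 102, 109])


class TestLogisticGrowthFit:
    @pytest.mark.parametrize(
        "x0, xn, tau",
        [(0.1, 1.0, 0.12), (0.05, 0.9, 0.08), (0.3, 2.7, 0.2), (0.5, 1.2, 0.05)],
    )
    def test_noise_free_recovery_to_1e6(self, x0, xn, tau):
        y = lc.logistic3(DATES, x0, xn, tau, 45.0)
        res = lc.LogisticGrowth(DATES, y, T=45).fit()
        np.testing.assert_allclose(res.params, [x0, xn, tau], rtol=1e-6)
        assert res.converged

    def test_predict_at_reference_day_is_x0(self):
        y = lc.logistic3(DATES, 0.1, 1.0, 0.12, 45.0)
        res = lc.LogisticGrowth(DATES, y, T=45).fit()
        assert res.predict(45.0) == pytest.approx(res.x0, rel=1e-12)

    def test_predict_asymptote(self):
        y = lc.logistic3(DATES, 0.1, 1.0, 0.12, 45.0)
        res = lc.LogisticGrowth(DATES, y, T=45).fit()
        assert res.predict(1e5) == pytest.approx(res.xn, rel=1e-6)

    def test_equal_x0_xn_is_constant_curve(self):
        assert lc.logistic3(77.0, 0.4, 0.4, 0.2, 45.0) == pytest.approx(0.4)

    def test_noisy_mean_bias_within_5pct(self):
        truth = np.array([0.1, 1.0, 0.12])
        rng = np.random.default_rng(0)
        estimates = []
        for _ in range(50):
            y = lc.logistic3(DATES, *truth, 45.0) + rng.normal(0, 0.02, DATES.size)
            y = np.clip(y, 1e-6, None)
            estimates.append(lc.LogisticGrowth(DATES, y, T=45).fit().params)
        bias = np.mean(estimates, axis=0) / truth - 1
        assert np.abs(bias).max() <= 0.05

    def test_constant_series_flags_tau(self):
        res = lc.LogisticGrowth(DATES, np.full(DATES.size, 0.5), T=45).fit()
        assert res.x0 == pytest.approx(0.5, rel=1e-3)
        assert res.xn == pytest.approx(0.5, rel=1e-3)
        assert any("unidentifiable" in f for f in res.flags)

    def test_confidence_interval_covers_truth_noise_free(self):
        y = lc.logistic3(DATES, 0.1, 1.0, 0.12, 45.0)
        ci = lc.LogisticGrowth(DATES, y, T=45).fit().conf_int()
        for truth, (lo, hi) in zip([0.1, 1.0, 0.12], ci):
            assert lo <= truth <= hi

    def test_input_validation(self):
        with pytest.raises(ValueError, match="4 observations"):
            lc.LogisticGrowth([45, 52, 67], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="positive"):
            lc.LogisticGrowth(DATES, np.linspace(-0.1, 1, DATES.size))
        with pytest.raises(ValueError, match="duplicate"):
            lc.LogisticGrowth([45, 45, 52, 67], [0.1, 0.1, 0.2, 0.3])

    def test_truncate_at_max_drops_defoliation_tail(self):
        y = lc.logistic3(DATES, 0.1, 1.0, 0.12, 45.0)
        y[-2:] = [0.8, 0.7]  # late decline
        res = lc.LogisticGrowth(DATES, y, T=45).fit(truncate_at_max=True)
        assert res.nobs == DATES.size - 2
        np.testing.assert_allclose(res.params, [0.1, 1.0, 0.12], rtol=1e-4)

    def test_summary_mentions_parameters(self):
        y = lc.logistic3(DATES, 0.1, 1.0, 0.12, 45.0)
        s = lc.LogisticGrowth(DATES, y, T=45).fit().summary()
        for name in ("x0", "xn", "tau", "SSE"):
            assert name in s


class TestGrowthRate:
    def test_known_interval_rate(self):
        # canopy height 1.0 -> 1.18 m over 10 days: 0.018 m/day
        gr = lc.growth_rate([60.0, 70.0], [1.0, 1.18])
        assert gr["gr"].iloc[0] == pytest.approx(0.018)

    def test_constant_series_zero_everywhere(self):
        gr = lc.growth_rate(DATES, np.full(DATES.size, 2.0))
        np.testing.assert_allclose(gr["gr"], 0.0)

    def test_single_observation_empty(self):
        assert len(lc.growth_rate([50.0], [1.0])) == 0

    def test_linear_series_constant_slope(self):
        t = np.array([10.0, 20, 35, 50])
        gr = lc.growth_rate(t, 0.02 * t + 1)
        np.testing.assert_allclose(gr["gr"], 0.02)

    def test_duplicate_dates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            lc.growth_rate([50.0, 50.0], [1.0, 1.1])

    def test_canonical_calendar_labels(self):
        gr = lc.growth_rate([43.0, 45, 52, 67, 74, 88, 95, 102, 109], np.arange(9.0) + 1)
        assert list(gr["interval"]) == [f"P{i}" for i in range(1, 9)]
        gr2 = lc.growth_rate([45.0, 52, 67], [1.0, 2.0, 3.0])
        assert list(gr2["interval"]) == ["P2", "P3"]
        gr3 = lc.growth_rate([1.0, 2.0], [1.0, 2.0])
        assert list(gr3["interval"]) == ["I1"]


def _null_table(rng, n_dates=2, n_per_group=8, n_groups=4):
    rows = []
    for d in range(n_dates):
        for g in range(n_groups):
            for p in range(n_per_group):
                rows.append(
                    {"plot_id": f"g{g}p{p}", "cultivar": f"c{g}", "dap": 45 + 7 * d,
                     "max_ch": rng.normal(1.0, 0.1)}
                )
    return pd.DataFrame(rows)


class TestCultivarAnova:
    def test_extreme_effect_tiny_p(self):
        rng = np.random.default_rng(1)
        df = _null_table(rng, n_dates=1)
        df.loc[df.cultivar == "c0", "max_ch"] += 1.0  # 10 sd separation
        out = lc.cultivar_anova(df, "max_ch")
        assert out["p"].iloc[0] < 1e-6

    def test_two_groups_equals_t_test(self):
        rng = np.random.default_rng(2)
        df = _null_table(rng, n_dates=1, n_groups=2)
        out = lc.cultivar_anova(df, "max_ch")
        a = df[df.cultivar == "c0"]["max_ch"]
        b = df[df.cultivar == "c1"]["max_ch"]
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert out["F"].iloc[0] == pytest.approx(t**2, rel=1e-10)
        assert out["p"].iloc[0] == pytest.approx(p, rel=1e-10)

    def test_null_rejection_rate_calibrated(self):
        """Type-I error at nominal 5% over 1000 simulated null fields."""
        rng = np.random.default_rng(3)
        rej = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = [rng.normal(0.0, 1.0, 8) for _ in range(4)]
            if stats.f_oneway(*groups).pvalue < 0.05:
                rej += 1
        assert rej / n_sim == pytest.approx(0.05, abs=0.02)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(4)
        ps = [stats.f_oneway(*[rng.normal(0, 1, 8) for _ in range(4)]).pvalue for _ in range(1000)]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_group_size_validation(self):
        df = _null_table(np.random.default_rng(5), n_dates=1)
        df = df.drop(df[(df.cultivar == "c0")].index[1:])  # one plot left in c0
        with pytest.raises(ValueError, match=">= 2 plots"):
            lc.cultivar_anova(df, "max_ch")


class TestTraitYieldRegression:
    def _tables(self, rng, n=32, slope=None):
        trait = rng.uniform(0.5, 1.5, n)
        if slope is None:
            yld = rng.normal(900, 100, n)
        else:
            yld = slope * trait
        traits = pd.DataFrame(
            {"plot_id": [f"p{i}" for i in range(n)], "cultivar": "c1", "dap": 67.0, "max_ch": trait}
        )
        yields = pd.DataFrame(
            {"plot_id": [f"p{i}" for i in range(n)], "cultivar": "c1", "yield_g": np.abs(yld)}
        )
        return traits, yields

    def test_exact_linear_relation_r2_one(self):
        traits, yields = self._tables(np.random.default_rng(6), slope=2.0)
        out = lc.trait_yield_regression(traits, yields, "max_ch")
        assert out["r2"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert out["slope"].iloc[0] == pytest.approx(2.0)

    def test_null_mean_r2_is_one_over_n_minus_1(self):
        """E[R^2] under independence is 1/(n-1); checked at n=32, 500 sims."""
        rng = np.random.default_rng(7)
        n = 32
        r2s = []
        for _ in range(500):
            x = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n)
            r2s.append(stats.linregress(x, y).rvalue ** 2)
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), abs=0.01)

    def test_constant_trait_flagged_nan(self):
        traits, yields = self._tables(np.random.default_rng(8))
        traits["max_ch"] = 1.0
        out = lc.trait_yield_regression(traits, yields, "max_ch")
        assert np.isnan(out["r2"].iloc[0])

    def test_affine_trait_rescaling_leaves_r2(self):
        traits, yields = self._tables(np.random.default_rng(9))
        base = lc.trait_yield_regression(traits, yields, "max_ch")["r2"].iloc[0]
        traits2 = traits.assign(max_ch=3.5 * traits["max_ch"] - 1.2)
        again = lc.trait_yield_regression(traits2, yields, "max_ch")["r2"].iloc[0]
        assert again == pytest.approx(base, rel=1e-10)

    def test_too_few_matched_plots_rejected(self):
        traits, yields = self._tables(np.random.default_rng(10), n=2)
        with pytest.raises(ValueError, match="fewer than 3"):
            lc.trait_yield_regression(traits, yields, "max_ch")

    def test_pooled_mode_single_row_per_trait_date(self):
        rng = np.random.default_rng(11)
        tdf, ydf = simulate_field_season(seed=1, plots_per_cultivar=6)
        out = lc.trait_yield_regression(tdf, ydf, ["max_ch", "pv"], by="pooled")
        assert set(out["cultivar"]) == {"all"}
        assert len(out) == 2 * tdf["dap"].nunique()


class TestSimulatedSeason:
    def test_tables_shapes_and_invariants(self):
        tdf, ydf = simulate_field_season(seed=0)
        assert len(ydf) == 4 * 32
        assert len(tdf) == 4 * 32 * 8
        assert (ydf["yield_g"] >= 0).all()
        assert (tdf[["max_ch", "pca", "pv"]] > 0).all().all()

    def test_seeded_determinism(self):
        a = simulate_field_season(seed=5)
        b = simulate_field_season(seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_cultivar_effect_detectable(self):
        tdf, _ = simulate_field_season(seed=2)
        out = lc.cultivar_anova(tdf, ["max_ch", "pv"])
        # real between-cultivar differences: significant on most dates
        assert (out["p"] < 0.05).mean() > 0.8

    def test_season_fits_recover_cultivar_ordering(self):
        tdf, _ = simulate_field_season(seed=3)
        means = tdf.groupby(["cultivar", "dap"])["max_ch"].mean().reset_index()
        fits = {}
        for cult, sub in means.groupby("cultivar"):
            fits[cult] = lc.LogisticGrowth(sub["dap"], sub["max_ch"], T=45).fit().xn
        assert fits["cultivar1"] > fits["cultivar4"]
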