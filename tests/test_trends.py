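"""Aggregation, trend, Pearson screening, attribution and dominance tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from forelule.trends import (
    AttributionResult,
    InsufficientDataError,
    aggregate,
    contribution_glm,
    dominance,
    fit_trend,
    pearson_screen,
    sensitivity_excluding_sparse_years,
)


def series_df(periods, values, n_scenes=1):
    return pd.DataFrame(
        {"period": periods, "mean_fui": values,
         "n_scenes": np.broadcast_to(n_scenes, len(periods))}
    )


class TestAggregate:
    def test_one_scene_per_period_is_the_identity(self):
        df = pd.DataFrame(
            {"date": ["2013-04-01", "2014-05-01", "2015-06-01"],
             "mean_fui": [8.0, 9.0, 10.0]}
        )
        out = aggregate(df, "yearly")
        assert out["period"].tolist() == [2013, 2014, 2015]
        assert out["mean_fui"].tolist() == [8.0, 9.0, 10.0]
        assert out["n_scenes"].tolist() == [1, 1, 1]

    def test_two_scenes_in_one_year_average(self):
        df = pd.DataFrame(
            {"date": ["2013-04-01", "2013-09-01"], "mean_fui": [8.0, 10.0]}
        )
        out = aggregate(df, "yearly")
        assert out["mean_fui"].tolist() == [9.0]
        assert out["n_scenes"].tolist() == [2]

    def test_monthly_pools_across_years(self):
        df = pd.DataFrame(
            {"date": ["2013-06-15", "2014-06-20", "2013-01-15"],
             "mean_fui": [11.0, 13.0, 7.0]}
        )
        out = aggregate(df, "monthly")
        assert out.set_index("period").loc[6, "mean_fui"] == 12.0
        assert out.set_index("period").loc[1, "mean_fui"] == 7.0

    def test_matches_brute_force_grouping(self, rng):
        dates = pd.to_datetime(
            rng.integers(
                pd.Timestamp("2013-01-01").value // 10**9,
                pd.Timestamp("2023-12-31").value // 10**9,
                60,
            ),
            unit="s",
        ).normalize()
        vals = rng.uniform(5, 15, 60)
        df = pd.DataFrame({"date": dates, "mean_fui": vals})
        for mode, keyfun in (
            ("yearly", lambda d: d.year),
            ("monthly", lambda d: d.month),
        ):
            expected = {}
            for d, v in zip(dates, vals):
                expected.setdefault(keyfun(d), []).append(v)
            out = aggregate(df, mode).set_index("period")
            assert set(out.index) == set(expected)
            for k, vs in expected.items():
                assert out.loc[k, "mean_fui"] == pytest.approx(np.mean(vs))
                assert out.loc[k, "n_scenes"] == len(vs)

    def test_missing_scene_means_are_ignored(self):
        df = pd.DataFrame(
            {"date": ["2013-04-01", "2013-09-01"], "mean_fui": [8.0, np.nan]}
        )
        out = aggregate(df, "yearly")
        assert out["mean_fui"].tolist() == [8.0]
        assert out["n_scenes"].tolist() == [1]

    def test_empty_input_gives_empty_series(self):
        out = aggregate(pd.DataFrame(columns=["date", "mean_fui"]), "yearly")
        assert out.empty


class TestTrend:
    def test_constant_series_has_zero_slope(self):
        res = fit_trend(series_df(range(2013, 2020), [9.0] * 7))
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovered(self):
        t = np.arange(11)
        res = fit_trend(series_df(t, 2.0 * t + 1.0))
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_matches_hand_computed_normal_equations(self, rng):
        t = np.arange(2013, 2024, dtype=float)
        y = 9.0 + 0.14 * (t - 2013) + rng.normal(0, 0.5, t.size)
        res = fit_trend(series_df(t, y))
        # closed-form OLS evaluated independently
        tc, yc = t - t.mean(), y - y.mean()
        slope = float((tc * yc).sum() / (tc * tc).sum())
        intercept = float(y.mean() - slope * t.mean())
        assert res.slope == pytest.approx(slope, abs=1e-12)
        assert res.intercept == pytest.approx(intercept, rel=1e-9)
        assert res.ci_low < slope < res.ci_high

    def test_missing_periods_skipped_not_interpolated(self):
        df = series_df([0, 1, 2, 3, 4], [1.0, np.nan, 5.0, 7.0, 9.0])
        res = fit_trend(df)
        assert res.n == 4
        assert res.slope == pytest.approx(2.0)

    def test_too_few_points_raise(self):
        with pytest.raises(InsufficientDataError):
            fit_trend(series_df([0, 1], [1.0, 2.0]))


class TestPearson:
    def test_perfect_correlations(self):
        s = series_df(range(12), np.linspace(7, 13, 12))
        drivers = pd.DataFrame(
            {"period": range(12),
             "up": 2.0 * np.linspace(7, 13, 12) + 3.0,
             "down": -np.linspace(7, 13, 12)}
        )
        out = pearson_screen(s, drivers).set_index("driver")
        assert out.loc["up", "r"] == pytest.approx(1.0)
        assert out.loc["down", "r"] == pytest.approx(-1.0)

    def test_matches_manual_covariance_arithmetic(self):
        y = np.array([9.0, 8.5, 10.2, 11.0, 9.7, 12.1])
        d = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        s = series_df(range(6), y)
        out = pearson_screen(
            s, pd.DataFrame({"period": range(6), "d": d})
        ).iloc[0]
        yc, dc = y - y.mean(), d - d.mean()
        r = float((yc * dc).sum() / np.sqrt((yc**2).sum() * (dc**2).sum()))
        tstat = r * np.sqrt(4 / (1 - r**2))
        p = 2 * stats.t.sf(abs(tstat), df=4)
        assert out["r"] == pytest.approx(r, abs=1e-12)
        assert out["p"] == pytest.approx(p, rel=1e-9)

    def test_pairwise_deletion(self):
        s = series_df(range(6), [9, 10, 11, 12, 13, 14])
        drivers = pd.DataFrame(
            {"period": range(6), "d": [1.0, np.nan, 3.0, 4.0, 5.0, 6.0]}
        )
        assert pearson_screen(s, drivers).iloc[0]["n"] == 5

    def test_zero_variance_driver_is_undefined(self):
        s = series_df(range(6), [9, 10, 11, 12, 13, 14])
        drivers = pd.DataFrame({"period": range(6), "flat": [2.0] * 6})
        assert np.isnan(pearson_screen(s, drivers).iloc[0]["r"])


class TestAttribution:
    def test_single_true_driver_takes_nearly_all_contribution(self, rng):
        n = 400
        d = rng.normal(size=(n, 5))
        y = 3.0 * d[:, 2] + rng.normal(0, 0.01, n)
        s = series_df(range(n), y)
        drivers = pd.DataFrame(
            {"period": range(n), **{f"d{i}": d[:, i] for i in range(5)}}
        )
        res = contribution_glm(s, drivers)
        assert res.table.set_index("driver").loc["d2", "contribution"] > 90
        assert res.residual_pct < 2

    def test_pure_noise_fui_leaves_the_residual_dominant(self, rng):
        n = 400
        s = series_df(range(n), rng.normal(9, 1, n))
        drivers = pd.DataFrame(
            {"period": range(n),
             **{f"d{i}": rng.normal(size=n) for i in range(5)}}
        )
        res = contribution_glm(s, drivers)
        assert res.residual_pct > 90

    def test_matches_explicit_normal_equations(self, rng):
        n = 12
        d = rng.normal(size=(n, 3))
        y = 9 + d @ [0.8, -0.4, 0.1] + rng.normal(0, 0.3, n)
        s = series_df(range(n), y)
        drivers = pd.DataFrame(
            {"period": range(n), "a": d[:, 0], "b": d[:, 1], "c": d[:, 2]}
        )
        res = contribution_glm(s, drivers)
        # independent step-by-step solve on standardized variables
        z = (y - y.mean()) / y.std()
        X = (d - d.mean(0)) / d.std(0)
        beta = np.linalg.solve(X.T @ X, X.T @ z)
        r2 = 1 - ((z - X @ beta) ** 2).sum() / (z**2).sum()
        contrib = np.abs(beta) / np.abs(beta).sum() * r2 * 100
        assert np.allclose(res.table["beta"], beta, atol=1e-10)
        assert np.allclose(res.table["contribution"], contrib, atol=1e-8)
        assert res.residual_pct == pytest.approx((1 - r2) * 100, abs=1e-8)

    def test_conservation_sums_to_100(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 40))
            s = series_df(range(n), rng.normal(9, 1, n))
            drivers = pd.DataFrame(
                {"period": range(n),
                 **{f"d{i}": rng.normal(size=n) for i in range(5)}}
            )
            res = contribution_glm(s, drivers)
            total = res.table["contribution"].sum() + res.residual_pct
            assert total == pytest.approx(100.0, abs=1e-6)

    def test_contributions_invariant_under_affine_driver_rescaling(self, rng):
        n = 12
        s = series_df(range(n), rng.normal(9, 1, n))
        d = rng.normal(size=(n, 2))
        base = pd.DataFrame({"period": range(n), "a": d[:, 0], "b": d[:, 1]})
        scaled = base.assign(a=1000.0 * base["a"] - 7.0, b=base["b"] / 3.0 + 2.0)
        ca = contribution_glm(s, base).table["contribution"]
        cb = contribution_glm(s, scaled).table["contribution"]
        assert np.allclose(ca, cb, atol=1e-9)

    def test_collinear_driver_dropped_with_warning(self, rng):
        n = 20
        a = rng.normal(size=n)
        s = series_df(range(n), 9 + a + rng.normal(0, 0.1, n))
        drivers = pd.DataFrame(
            {"period": range(n), "a": a, "twice_a": 2.0 * a}
        )
        with pytest.warns(UserWarning, match="collinear"):
            res = contribution_glm(s, drivers)
        assert res.dropped == ("twice_a",)
        total = res.table["contribution"].sum() + res.residual_pct
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_more_drivers_than_periods_rejected(self, rng):
        s = series_df(range(4), rng.normal(9, 1, 4))
        drivers = pd.DataFrame(
            {"period": range(4),
             **{f"d{i}": rng.normal(size=4) for i in range(5)}}
        )
        with pytest.raises(InsufficientDataError):
            contribution_glm(s, drivers)


class TestDominance:
    @pytest.mark.parametrize(
        "contribution, r, p, expected",
        [
            (40.0, 0.1, 0.9, True),    # outright > 35%
            (20.0, 0.7, 0.01, True),   # 10-35% with corroborating r and p
            (20.0, 0.5, 0.01, False),  # |r| below 0.6
            (20.0, -0.8, 0.20, False), # p above 0.05
            (9.0, 0.9, 0.001, False),  # contribution below 10%
            (20.0, -0.7, 0.01, True),  # negative r counts by magnitude
        ],
    )
    def test_rule(self, contribution, r, p, expected):
        res = AttributionResult(
            table=pd.DataFrame(
                {"driver": ["d"], "r": [r], "p": [p], "beta": [0.5],
                 "contribution": [contribution]}
            ),
            residual_pct=100.0 - contribution,
            r_squared=contribution / 100.0,
            n=12,
        )
        assert dominance(res)[0] == expected


class TestSensitivity:
    def test_equally_sampled_years_change_nothing(self):
        s = series_df(range(2013, 2024), np.linspace(9, 10.4, 11), n_scenes=20)
        res = sensitivity_excluding_sparse_years(s, min_scenes=5)
        assert res.full == res.filtered
        assert res.excluded_periods == ()

    def test_min_scenes_zero_is_a_no_op(self):
        vals = [9.1, 9.0, 9.4, 9.3, 9.8, 9.6, 10.0, 9.9, 10.3, 10.1, 10.6]
        s = series_df(range(2013, 2024), vals, n_scenes=[3] * 10 + [0])
        res = sensitivity_excluding_sparse_years(s, min_scenes=0)
        assert res.full == res.filtered

    def test_excluded_trend_matches_subset_ols(self, rng):
        periods = np.arange(2013, 2024)
        vals = 9 + 0.1 * (periods - 2013) + rng.normal(0, 0.3, 11)
        counts = np.array([1, 8, 9, 2, 7, 8, 9, 1, 8, 9, 8])
        vals[counts < 3] -= 2.0  # sparse years biased low
        s = series_df(periods, vals, n_scenes=counts)
        res = sensitivity_excluding_sparse_years(s, min_scenes=3)
        keep = counts >= 3
        t, y = periods[keep].astype(float), vals[keep]
        tc = t - t.mean()
        slope = float((tc * (y - y.mean())).sum() / (tc * tc).sum())
        assert res.filtered.slope == pytest.approx(slope, abs=1e-10)
        assert res.excluded_periods == (2013, 2016, 2020)

    def test_exclusion_leaving_too_few_years_raises(self):
        s = series_df(range(2013, 2018), [9, 9, 9, 9, 9],
                      n_scenes=[1, 1, 1, 9, 9])
        with pytest.raises(InsufficientDataError):
            sensitivity_excluding_sparse_years(s, min_scenes=5)
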