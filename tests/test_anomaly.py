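"""Anomaly decomposition: OLS oracle agreement, SS partition, scaling,
peak ordering, environmental variance explanation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seacycle import (
    SeasonalAnomalyModel,
    env_variance_explained,
    fit_anomaly,
    order_by_peak,
    scale_anomaly,
    simulate_community,
)
from seacycle import SimulationConfig
from tests.conftest import balanced_dates


def statsmodels_sum_coded_fit(y, dates):
    """Independent oracle: statsmodels OLS with Sum (effects) coding."""
    smf = pytest.importorskip("statsmodels.formula.api")
    frame = pd.DataFrame(
        {"y": y, "month": dates.month, "year": dates.year}
    )
    fit = smf.ols("y ~ C(month, Sum) + C(year, Sum)", data=frame).fit()
    months = np.sort(frame["month"].unique())
    years = np.sort(frame["year"].unique())
    month_eff = {
        m: fit.params[f"C(month, Sum)[S.{m}]"] for m in months[:-1]
    }
    month_eff[months[-1]] = -sum(month_eff.values())
    year_eff = {y_: fit.params[f"C(year, Sum)[S.{y_}]"] for y_ in years[:-1]}
    year_eff[years[-1]] = -sum(year_eff.values())
    return fit, month_eff, year_eff


class TestFit:
    def test_constant_series_all_zero_effects(self):
        dates = balanced_dates(3)
        res = fit_anomaly(pd.Series(2.5, index=dates))
        assert np.allclose(res.monthly_effects, 0, atol=1e-12)
        assert np.allclose(res.yearly_effects, 0, atol=1e-12)
        assert res.ss_residual == pytest.approx(0, abs=1e-18)
        assert res.intercept == pytest.approx(2.5)

    def test_july_spike_peaks_in_july(self):
        dates = balanced_dates(4)
        y = np.where(dates.month == 7, 1.0, -1.0)
        res = fit_anomaly(pd.Series(y, index=dates))
        assert res.peak_month == 7
        assert res.monthly_effects.idxmax() == 7

    def test_effects_match_sum_coded_ols_oracle(self, rng):
        dates = balanced_dates(4)  # n = 48
        y = rng.normal(size=48)
        res = fit_anomaly(pd.Series(y, index=dates))
        fit, month_eff, year_eff = statsmodels_sum_coded_fit(y, dates)
        for m, v in month_eff.items():
            assert res.monthly_effects[m] == pytest.approx(v, abs=1e-8)
        for yr, v in year_eff.items():
            assert res.yearly_effects[yr] == pytest.approx(v, abs=1e-8)
        assert res.intercept == pytest.approx(fit.params["Intercept"], abs=1e-8)
        # sequential SS against statsmodels Type-I ANOVA
        sm_api = pytest.importorskip("statsmodels.api")
        anova = sm_api.stats.anova_lm(fit, typ=1)
        assert res.ss_month == pytest.approx(anova.loc["C(month, Sum)", "sum_sq"])
        assert res.ss_year == pytest.approx(anova.loc["C(year, Sum)", "sum_sq"])
        assert res.ss_residual == pytest.approx(anova.loc["Residual", "sum_sq"])

    def test_unbalanced_design_pinv_oracle(self, rng):
        # drop a third of the samples: effects must match a direct
        # pseudo-inverse solve of the same sum-to-zero design
        dates = balanced_dates(4)
        keep = rng.choice(48, size=32, replace=False)
        dates = dates[np.sort(keep)]
        y = rng.normal(size=len(dates))
        res = fit_anomaly(pd.Series(y, index=dates))
        _, month_eff, year_eff = statsmodels_sum_coded_fit(y, dates)
        for m, v in month_eff.items():
            assert res.monthly_effects[m] == pytest.approx(v, abs=1e-8)
        for yr, v in year_eff.items():
            assert res.yearly_effects[yr] == pytest.approx(v, abs=1e-8)

    def test_sums_to_zero_and_ss_partition(self, rng):
        dates = balanced_dates(5)
        y = rng.normal(size=len(dates))
        res = fit_anomaly(pd.Series(y, index=dates))
        assert abs(res.monthly_effects.sum()) < 1e-9
        assert abs(res.yearly_effects.sum()) < 1e-9
        assert res.ss_month + res.ss_year + res.ss_residual == pytest.approx(
            res.ss_total, rel=1e-9
        )

    def test_balanced_monthly_effect_is_month_mean_minus_grand_mean(self, rng):
        dates = balanced_dates(6)
        y = pd.Series(rng.normal(size=len(dates)), index=dates)
        res = fit_anomaly(y)
        grand = y.mean()
        for m in range(1, 13):
            expect = y[dates.month == m].mean() - grand
            assert res.monthly_effects[m] == pytest.approx(expect, abs=1e-10)

    def test_shift_equivariance(self, rng):
        dates = balanced_dates(3)
        y = pd.Series(rng.normal(size=len(dates)), index=dates)
        r1 = fit_anomaly(y)
        r2 = fit_anomaly(y + 10.0)
        assert r2.intercept - r1.intercept == pytest.approx(10.0)
        pd.testing.assert_series_equal(r1.monthly_effects, r2.monthly_effects)
        pd.testing.assert_series_equal(r1.yearly_effects, r2.yearly_effects)

    def test_requires_two_months_and_two_years(self):
        dates = pd.DatetimeIndex(["2011-01-01", "2011-01-15", "2011-02-01"])
        with pytest.raises(ValueError, match="two distinct"):
            fit_anomaly(pd.Series([1.0, 2.0, 3.0], index=dates))

    def test_missing_month_warns_and_is_not_estimable(self, rng):
        dates = balanced_dates(3)
        keep = dates.month != 6
        y = pd.Series(rng.normal(size=keep.sum()), index=dates[keep])
        with pytest.warns(UserWarning, match="no observations"):
            res = fit_anomaly(y)
        assert np.isnan(res.monthly_effects[6])
        assert abs(res.monthly_effects.dropna().sum()) < 1e-9


class TestScaling:
    def test_example_vector(self):
        assert np.allclose(scale_anomaly([2.0, -4.0, 0.0]), [0.5, -1.0, 0.0])

    def test_all_zero_passthrough(self):
        assert np.allclose(scale_anomaly(np.zeros(12)), 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6), min_size=2, max_size=12
        )
    )
    def test_max_abs_is_one_or_all_zero(self, values):
        scaled = scale_anomaly(values)
        peak = np.max(np.abs(scaled))
        assert peak == pytest.approx(1.0) or peak == 0.0

    def test_results_scaled_monthly_peak(self, rng):
        dates = balanced_dates(3)
        y = pd.Series(rng.normal(size=len(dates)), index=dates)
        res = fit_anomaly(y)
        assert np.nanmax(np.abs(res.scaled_monthly)) == pytest.approx(1.0)


class TestOrdering:
    def test_two_features_ordered_by_peak(self):
        dates = balanced_dates(3)
        frame = pd.DataFrame(
            {
                "march": np.cos(2 * np.pi * (dates.month - 3) / 12),
                "october": np.cos(2 * np.pi * (dates.month - 10) / 12),
            }
        ).T
        frame.columns = dates
        fits = SeasonalAnomalyModel(frame, dates).fit()
        assert order_by_peak(fits) == ["march", "october"]

    def test_singleton(self):
        dates = balanced_dates(2)
        res = fit_anomaly(pd.Series(np.cos(np.arange(24)), index=dates))
        assert order_by_peak([res]) == [res.name]

    def test_recovers_injected_phase_order(self):
        cfg = SimulationConfig.default(n_taxa=8, seed=9, noise_sd=0.25)
        tables, _ = simulate_community(cfg)
        from seacycle import filter_rare, to_proportions, zscore

        z = zscore(filter_rare(to_proportions(tables["family"])))
        fits = SeasonalAnomalyModel(z.data, z.dates).fit()
        recovered = order_by_peak(fits)
        true_peak = {
            f"{name}aceae": peak
            for name, peak in zip(cfg.taxon_names, cfg.seasonal_peak_month)
        }
        peaks = [true_peak[f] for f in recovered]
        # peak month is circular: compositional competition can push a
        # January peak to December, so the recovered sequence must be sorted
        # up to rotation around the year boundary
        k = len(peaks)
        assert any(
            all(
                peaks[(r + i) % k] <= peaks[(r + i + 1) % k]
                for i in range(k - 1)
            )
            for r in range(k)
        ), f"no rotation of {peaks} is sorted"


class TestVarianceFractions:
    def test_pure_seasonal_noiseless(self):
        dates = balanced_dates(4)
        y = pd.Series(np.cos(2 * np.pi * dates.month / 12), index=dates)
        sf, yf, rf = fit_anomaly(y).variance_fractions()
        assert sf == pytest.approx(1.0, abs=1e-10)
        assert yf == pytest.approx(0.0, abs=1e-10)

    def test_fractions_sum_to_one(self, rng):
        dates = balanced_dates(4)
        y = pd.Series(rng.normal(size=len(dates)), index=dates)
        assert sum(fit_anomaly(y).variance_fractions()) == pytest.approx(1.0)

    def test_constant_series_raises(self):
        dates = balanced_dates(2)
        res = fit_anomaly(pd.Series(1.0, index=dates))
        with pytest.raises(ValueError, match="constant"):
            res.variance_fractions()

    def test_iid_noise_fraction_matches_direct_ols(self, rng):
        dates = balanced_dates(10)
        y = rng.normal(size=len(dates))
        res = fit_anomaly(pd.Series(y, index=dates))
        # direct OLS on explicit dummies (independent construction)
        X = np.ones((len(dates), 1))
        for m in range(1, 12):
            X = np.hstack([X, (dates.month == m).astype(float)[:, None]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss_month_model = ((y - X @ beta) ** 2).sum()
        ss_month = ((y - y.mean()) ** 2).sum() - rss_month_model
        assert res.ss_month == pytest.approx(ss_month, rel=1e-8)


class TestEnvVarianceExplained:
    def years_frame(self, rng, n_feat=20, n_years=8):
        years = np.arange(2011, 2011 + n_years)
        env = pd.DataFrame(
            {
                "temperature": rng.normal(size=n_years),
                "nitrate": rng.normal(size=n_years),
            },
            index=years,
        )
        return years, env

    def test_exact_linear_combination_gives_one(self, rng):
        years, env = self.years_frame(rng)
        W = rng.normal(size=(20, 2))
        Y = W @ env.to_numpy().T
        frac = env_variance_explained(
            pd.DataFrame(Y, columns=years), env
        )
        assert frac == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_covariates_give_zero(self):
        years = np.arange(2011, 2019)
        env = pd.DataFrame(
            {"a": [1, -1] * 4, "b": [1, 1, -1, -1] * 2}, index=years, dtype=float
        )
        # feature yearly effects orthogonal to both covariates and centered
        y = np.array([1, 1, 1, 1, -1, -1, -1, -1], dtype=float)
        assert abs(y @ env["a"]) < 1e-12 and abs(y @ env["b"]) < 1e-12
        frac = env_variance_explained(
            pd.DataFrame([y], columns=years), env
        )
        assert frac == pytest.approx(0.0, abs=1e-10)

    def test_collinear_covariates_rejected(self, rng):
        years, env = self.years_frame(rng)
        env["nitrate"] = 2 * env["temperature"]
        with pytest.raises(ValueError, match="collinear"):
            env_variance_explained(
                pd.DataFrame(rng.normal(size=(5, len(years))), columns=years),
                env,
            )

    def test_recovers_injected_half_env_driven_variance(self, rng):
        # 12 years, 200 features, ~50% of yearly-effect variance injected
        # as a linear combination of the two covariates
        years = np.arange(2010, 2022)
        env = pd.DataFrame(
            {"temperature": rng.normal(size=12), "nitrate": rng.normal(size=12)},
            index=years,
        )
        Xc = (env - env.mean()).to_numpy()
        signal = rng.normal(size=(200, 2)) @ Xc.T
        signal *= 1.0 / signal.std()
        # noise strictly non-env-driven: orthogonal to the covariate span
        noise = rng.normal(size=(200, 12))
        noise -= noise.mean(axis=1, keepdims=True)
        Q, _ = np.linalg.qr(Xc)
        noise -= (noise @ Q) @ Q.T
        noise *= 1.0 / noise.std()
        Y = signal + noise
        frac = env_variance_explained(pd.DataFrame(Y, columns=years), env)
        assert frac == pytest.approx(0.5, abs=0.1)
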