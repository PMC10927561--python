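import numpy as np
import pandas as pd
import pytest

from rivertrends import model as Mo
from rivertrends.model import (
    HierarchicalTrendModel,
    ModelSpec,
    build_design,
    classify_evidence,
    hpd_interval,
    percent_per_decade,
    response_spec,
    trend_characteristics_check,
    units_per_decade,
    vif,
)
from rivertrends.simulate import SimConfig, simulate_from_model
from ._oracles import conjugate_posterior


class TestHPD:
    def test_constant_draws(self):
        assert hpd_interval(np.full(500, 3.2), 0.9) == (3.2, 3.2)

    def test_uniform_grid_shortest_window(self):
        lo, hi = hpd_interval(np.arange(1, 101), 0.95)
        assert hi - lo == 94
        assert (lo, hi) == (1.0, 95.0)  # first window on ties

    def test_standard_normal_limit(self):
        draws = np.random.default_rng(0).standard_normal(1_000_000)
        lo, hi = hpd_interval(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.01)
        assert hi == pytest.approx(1.96, abs=0.01)

    def test_invalid_mass_errors(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(10), 1.5)

    def test_mass_check(self):
        """Empirical mass inside the interval is >= nominal and <= nominal
        plus one draw's worth of slack."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            draws = rng.gamma(2.0, 1.0, 999)
            for mass in (0.8, 0.9, 0.95):
                lo, hi = hpd_interval(draws, mass)
                frac = np.mean((draws >= lo) & (draws <= hi))
                assert mass <= frac <= mass + 2.0 / len(draws)


class TestEvidence:
    def test_strong_when_95_excludes_zero(self):
        rng = np.random.default_rng(1)
        assert classify_evidence(rng.normal(0.025, 0.007, 4000)) == "strong"

    def test_moderate_when_only_90_excludes_zero(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(-0.0047, 0.0027, 4000)
        lo95, hi95 = hpd_interval(draws, 0.95)
        assert lo95 < 0 < hi95
        assert classify_evidence(draws) == "moderate"

    def test_symmetric_draws_none(self):
        rng = np.random.default_rng(3)
        assert classify_evidence(rng.normal(0, 1, 4000)) == "none"


class TestBackTransforms:
    @pytest.mark.parametrize(
        "slope, pct",
        [(0.0, 0.0), (0.1, (11 ** 0.1 - 1) * 100), (-0.1, (11 ** -0.1 - 1) * 100)],
    )
    def test_percent_per_decade(self, slope, pct):
        assert percent_per_decade(slope) == pytest.approx(pct)

    def test_units_per_decade(self):
        assert units_per_decade(0.2) == pytest.approx(0.2 * np.log(11))


class TestVIF:
    def test_orthogonal_columns_are_one(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(100, 3)))
        assert np.allclose(vif(q), 1.0, atol=1e-8)

    def test_duplicated_column_is_infinite(self):
        x = np.random.default_rng(1).normal(size=(50, 1))
        X = np.column_stack([x, x])
        assert np.isinf(vif(X)).all()

    def test_known_correlation(self):
        rng = np.random.default_rng(2)
        n = 200_000
        a = rng.standard_normal(n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        got = vif(np.column_stack([a, b]))
        assert got.iloc[0] == pytest.approx(1 / (1 - 0.81), rel=0.02)


class TestDesign:
    def _data(self, n_units=2):
        rng = np.random.default_rng(0)
        rows = []
        units = ["count", "density_100m2"][:n_units]
        for s in range(6):
            for t in range(5):
                rows.append(
                    {"site_id": f"s{s}", "basin_id": f"b{s % 2}", "t": t,
                     "unit": units[s % n_units],
                     "total_abundance": float(rng.uniform(5, 50)),
                     "jaccard": rng.uniform(0, 1) if t else 0.0,
                     "X_past": rng.normal(), "X_change": rng.normal(),
                     "X_stream": rng.normal()}
                )
        return pd.DataFrame(rows)

    def test_abundance_driver_design_has_13_columns(self):
        d = build_design(self._data(), response_spec("total_abundance", with_drivers=True))
        # intercept + 1 unit dummy + Time + Time:unit + 3 mains + 3 two-way + 3 three-way
        assert len(d.names) == 13

    def test_dissimilarity_design_has_7_columns_no_intercept(self):
        d = build_design(self._data(), response_spec("jaccard", with_drivers=True))
        assert len(d.names) == 7
        assert "intercept" not in d.names
        assert not any(n in d.names for n in ("X_past", "X_change", "X_stream"))

    def test_time_is_log_year_plus_one(self):
        d = build_design(self._data(), response_spec("total_abundance"))
        t0_rows = d.time[np.asarray([r == 0 for r in
                                     self._data()["t"]])[: len(d.time)]]
        assert (d.time >= 0).all()
        assert np.isclose(d.time.min(), 0.0)

    def test_baseline_rows_dropped_for_dissimilarity(self):
        full = self._data()
        d = build_design(full, response_spec("jaccard"))
        assert len(d.y) == (full["t"] > 0).sum()

    def test_missing_driver_errors_with_sites(self):
        data = self._data()
        data.loc[data["site_id"] == "s3", "X_past"] = np.nan
        with pytest.raises(ValueError, match="s3"):
            build_design(data, response_spec("total_abundance", with_drivers=True))


def _plain_spec(**kw):
    return ModelSpec("y", log_response=False, scale_response=False, **kw)


class TestSampler:
    def test_conjugate_case_matches_closed_form(self):
        """With no random effects and a known residual SD the posterior is
        available in closed form; the Gibbs draws must reproduce it."""
        rng = np.random.default_rng(0)
        n = 200
        t = np.tile(np.arange(10), 20)
        df = pd.DataFrame(
            {"site_id": np.repeat([f"s{i}" for i in range(20)], 10),
             "basin_id": "b0", "t": t,
             "y": 1.0 + 0.5 * np.log(t + 1) + rng.normal(0, 0.3, n)}
        )
        spec = _plain_spec(random_intercepts=False, random_slopes=False)
        m = HierarchicalTrendModel(
            spec=spec, n_chains=2, n_draws=3000, n_warmup=200, seed=1,
            fix_resid_sd=0.3,
        ).fit(df)
        mean, cov = conjugate_posterior(m.design_.X, m.design_.y, 0.3, 1000.0)
        got_mean = m.draws_["beta"].mean(axis=0)
        got_sd = m.draws_["beta"].std(axis=0)
        assert np.allclose(got_mean, mean, atol=4 * np.sqrt(np.diag(cov) / 6000) * 10)
        assert np.allclose(got_sd, np.sqrt(np.diag(cov)), rtol=0.1)

    def test_zero_noise_concentrates_on_ols(self):
        t = np.tile(np.arange(8), 5)
        df = pd.DataFrame(
            {"site_id": np.repeat([f"s{i}" for i in range(5)], 8),
             "basin_id": "b0", "t": t, "y": 2.0 + 0.7 * np.log(t + 1)}
        )
        spec = _plain_spec(random_intercepts=False, random_slopes=False)
        m = HierarchicalTrendModel(
            spec=spec, n_chains=1, n_draws=500, n_warmup=200, seed=2,
            fix_resid_sd=1e-4,
        ).fit(df)
        X, y = m.design_.X, m.design_.y
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(m.draws_["beta"].mean(axis=0), ols, atol=1e-3)

    def test_parameter_recovery_on_nested_simulation(self):
        """50 basins x 10 sites x 10 years: the global slope is recovered
        within 3 posterior SDs and the simulated slope/residual SDs within
        25% relative error; site slope SD exceeds basin slope SD both in
        truth and in the fit."""
        cfg = SimConfig(
            n_basins=50, sites_per_basin=10, n_years=10, completeness=1.0,
            mu=0.3, sigma_b_basin=0.1, sigma_b_site=0.2, sigma_eps=0.5,
        )
        data, truth = simulate_from_model(cfg, seed=7)
        m = HierarchicalTrendModel(
            spec=_plain_spec(), n_chains=2, n_draws=600, n_warmup=400, seed=3
        ).fit(data)
        j = m.design_.names.index("Time")
        mu_draws = m.draws_["beta"][:, j]
        assert abs(mu_draws.mean() - 0.3) < 3 * mu_draws.std()
        for key, true in [("sigma_b_basin", 0.1), ("sigma_b_site", 0.2),
                          ("sigma_eps", 0.5)]:
            est = m.draws_[key].mean()
            assert abs(est - true) / true < 0.25, (key, est)
        assert m.draws_["sigma_b_site"].mean() > m.draws_["sigma_b_basin"].mean()

        st = m.site_trends().merge(truth.site_slopes, on="site_id")
        from scipy.stats import spearmanr
        assert spearmanr(st["slope"], st["true_slope"]).statistic >= 0.8
        # partial pooling shrinks the spread of estimated slopes
        assert st["slope"].std() <= st["true_slope"].std()

    def test_all_site_trends_equal_global_when_slope_variance_zero(self):
        cfg = SimConfig(n_basins=10, sites_per_basin=4, n_years=8,
                        completeness=1.0, mu=0.4,
                        sigma_b_basin=0.0, sigma_b_site=0.0, sigma_eps=0.05)
        data, _ = simulate_from_model(cfg, seed=1)
        m = HierarchicalTrendModel(
            spec=_plain_spec(), n_chains=1, n_draws=400, n_warmup=400, seed=2
        ).fit(data)
        st = m.site_trends()
        g = m.global_trend()
        assert np.allclose(st["slope"], g["slope_mean"], atol=0.02)

    def test_same_seed_same_posterior(self):
        cfg = SimConfig(n_basins=6, sites_per_basin=3, n_years=6, completeness=1.0)
        data, _ = simulate_from_model(cfg, seed=5)
        kw = dict(spec=_plain_spec(), n_chains=2, n_draws=100, n_warmup=100, seed=9)
        m1 = HierarchicalTrendModel(**kw).fit(data)
        m2 = HierarchicalTrendModel(**kw).fit(data)
        assert np.array_equal(m1.draws_["beta"], m2.draws_["beta"])
        assert m1.waic() == m2.waic()


class TestFitSummaries:
    @pytest.fixture(scope="class")
    def partition_fit(self):
        """Variance partition by construction: fixed ~30%, basin intercept
        ~20%, site intercept ~30%, noise ~20% of total variance."""
        t_values = np.log(np.arange(10) + 1.0)
        var_time = t_values.var()
        cfg = SimConfig(
            n_basins=40, sites_per_basin=8, n_years=10, completeness=1.0,
            alpha0=0.0, mu=np.sqrt(0.3 / var_time),
            sigma_a_basin=np.sqrt(0.2), sigma_a_site=np.sqrt(0.3),
            sigma_b_basin=0.0, sigma_b_site=0.0, sigma_eps=np.sqrt(0.2),
        )
        data, _ = simulate_from_model(cfg, seed=21)
        return HierarchicalTrendModel(
            spec=_plain_spec(), n_chains=1, n_draws=500, n_warmup=500, seed=4
        ).fit(data)

    def test_r2_matches_constructed_partition(self, partition_fit):
        r2 = partition_fit.r2()
        assert r2["r2_marginal"] == pytest.approx(0.3, abs=0.05)
        assert r2["r2_conditional"] == pytest.approx(0.8, abs=0.05)
        assert 0 <= r2["r2_marginal"] <= r2["r2_conditional"] <= 1

    def test_r2_equal_without_random_intercepts(self):
        rng = np.random.default_rng(0)
        t = np.tile(np.arange(8), 10)
        df = pd.DataFrame(
            {"site_id": np.repeat([f"s{i}" for i in range(10)], 8),
             "basin_id": np.repeat([f"b{i % 3}" for i in range(10)], 8),
             "t": t, "y": 0.5 * np.log(t + 1) + rng.normal(0, 0.5, 80)}
        )
        spec = _plain_spec(random_intercepts=False, include_intercept=False)
        m = HierarchicalTrendModel(
            spec=spec, n_chains=1, n_draws=300, n_warmup=300, seed=1
        ).fit(df)
        r2 = m.r2()
        assert r2["r2_marginal"] == pytest.approx(r2["r2_conditional"])

    def test_waic_reproducible_and_noise_covariate_harmless(self):
        cfg = SimConfig(n_basins=15, sites_per_basin=5, n_years=8, completeness=1.0)
        data, _ = simulate_from_model(cfg, seed=3)
        rng = np.random.default_rng(0)
        data["X_past"] = 0.0
        data["X_change"] = 0.0
        data["X_stream"] = 0.0
        base = HierarchicalTrendModel(
            spec=_plain_spec(), n_chains=1, n_draws=400, n_warmup=400, seed=6
        ).fit(data)
        noisy = data.copy()
        per_site = {s: rng.normal() for s in noisy["site_id"].unique()}
        noisy["X_past"] = noisy["site_id"].map(per_site)
        spec_noise = _plain_spec(drivers=("X_past",))
        with_noise = HierarchicalTrendModel(
            spec=spec_noise, n_chains=1, n_draws=400, n_warmup=400, seed=6
        ).fit(noisy)
        assert abs(base.waic() - with_noise.waic()) < 10


class TestBaselinePredictions:
    @pytest.fixture(scope="class")
    def driver_fit(self):
        cfg = SimConfig(
            n_basins=25, sites_per_basin=6, n_years=10, completeness=1.0,
            alpha0=1.5, mu=0.1,
            beta_x={"X_past": -0.4, "X_change": 0.2, "X_stream": 0.3},
            sigma_a_basin=0.05, sigma_a_site=0.1,
            sigma_b_basin=0.02, sigma_b_site=0.05, sigma_eps=0.3,
        )
        rng = np.random.default_rng(13)
        sites = cfg.n_basins * cfg.sites_per_basin
        drv = pd.DataFrame(
            {"site_id": [f"B{b:03d}S{s:03d}" for b in range(cfg.n_basins)
                         for s in range(cfg.sites_per_basin)],
             "X_past": rng.normal(0, 1, sites),
             "X_change": rng.normal(0, 1, sites),
             "X_stream": rng.normal(0, 1, sites)}
        )
        data, truth = simulate_from_model(cfg, drivers=drv, seed=13)
        spec = ModelSpec("y", log_response=True, scale_response=False,
                         drivers=("X_past", "X_change", "X_stream"))
        data = data.rename(columns={"y": "logy"})
        data["y"] = np.exp(data["logy"])
        fit = HierarchicalTrendModel(
            spec=spec, n_chains=1, n_draws=500, n_warmup=500, seed=5
        ).fit(data)
        return fit, truth

    def test_baseline_prediction_is_backtransformed_intercept(self, driver_fit):
        fit, _ = driver_fit
        d = fit.design_
        pred = fit.predict_baseline(
            {"X_past": 0.0, "X_change": 0.0, "X_stream": 0.0}
        )
        j = d.names.index("intercept")
        expect = np.exp(fit.draws_["beta"][:, j]).mean()
        assert pred["mean"] == pytest.approx(expect, rel=1e-6)

    def test_contrast_matches_closed_form(self, driver_fit):
        fit, _ = driver_fit
        c = fit.baseline_contrast("X_past", 1.0, 0.0)
        j = fit.design_.names.index("X_past")
        beta = fit.draws_["beta"][:, j].mean()
        # log-scale model: ratio of predictions is e^{beta * dx}
        assert c["mean"] == pytest.approx(
            100 * (np.exp(beta) - 1), abs=3.0
        )
        # recovers the simulated effect direction and size
        assert abs(beta - (-0.4)) < 0.1

    def test_contrast_reciprocity(self, driver_fit):
        fit, _ = driver_fit
        ab = fit.baseline_contrast("X_stream", 1.0, -1.0)["draws"]
        ba = fit.baseline_contrast("X_stream", -1.0, 1.0)["draws"]
        assert np.allclose((1 + ab / 100) * (1 + ba / 100), 1.0, atol=1e-10)

    def test_identical_values_zero_contrast(self, driver_fit):
        fit, _ = driver_fit
        c = fit.baseline_contrast("X_past", 0.3, 0.3)
        assert c["mean"] == pytest.approx(0.0, abs=1e-10)

    def test_out_of_range_warns(self, driver_fit):
        fit, _ = driver_fit
        with pytest.warns(UserWarning, match="outside observed range"):
            fit.predict_baseline({"X_past": 99.0})


class TestTrendCharacteristics:
    def _tables(self, rho_span):
        rng = np.random.default_rng(0)
        n = 500
        span = rng.integers(9, 40, n).astype(float)
        noise = rng.normal(0, 1, n)
        trend = rho_span * span + (1 - abs(rho_span)) * noise
        trends = pd.DataFrame({"site_id": [f"s{i}" for i in range(n)],
                               "trend_per_decade": trend})
        summary = pd.DataFrame(
            {"site_id": trends["site_id"], "span_years": span,
             "completeness": rng.uniform(0.4, 1, n),
             "first_year": rng.integers(1980, 2005, n)}
        )
        return trends, summary

    def test_independent_trends_uncorrelated(self):
        rep = trend_characteristics_check(*self._tables(0.0))
        assert (rep["spearman_rho"].abs() < 0.1).all()

    def test_confounded_trends_detected(self):
        rep = trend_characteristics_check(*self._tables(1.0))
        row = rep[rep["characteristic"] == "span_years"]
        assert abs(row["spearman_rho"].iloc[0]) > 0.99

    def test_constant_trends_undefined(self):
        trends, summary = self._tables(0.0)
        trends["trend_per_decade"] = 1.0
        rep = trend_characteristics_check(trends, summary)
        assert rep["spearman_rho"].isna().all()
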