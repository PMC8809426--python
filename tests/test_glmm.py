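from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trapid.glmm import (
    FitError,
    ModelSpec,
    backward_select,
    compare_aic,
    diagnostics,
    fit_poisson_glmm,
    parse_formula_terms,
    percent_change_per_day,
    season_of,
    type3_anova,
)
from trapid.simulate import SimScenario, simulate_detection_history


def small_frame(rng, n=300, beta_acd=0.0, beta_deploy=0.0, base_rate=0.5):
    """Minimal site-day frame with two covariates and no group structure."""
    days = rng.integers(0, 200, size=n).astype(float)
    acd = rng.random(n) < 0.5
    scrape = rng.random(n) < 0.4
    deploy_z = (days - days.mean()) / days.std()
    eta = np.log(base_rate) + beta_deploy * deploy_z + beta_acd * acd
    return pd.DataFrame(
        {
            "site_id": [f"S{i % 10}" for i in range(n)],
            "date": pd.Timestamp("2018-06-01"),
            "count": rng.poisson(np.exp(eta)),
            "days_since_deploy": days,
            "days_since_lure": rng.integers(0, 30, size=n).astype(float),
            "has_acd": acd,
            "is_scrape": scrape,
            "season": "JJA",
            "year": "2018",
        }
    )


class TestGlmOracle:
    def test_matches_statsmodels_irls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        data = small_frame(rng, beta_acd=0.4, beta_deploy=-0.3)
        spec = ModelSpec(fixed_terms=["deploy", "acd"], random_intercepts=[])
        fit = fit_poisson_glmm(data, spec)

        mean, sd = fit.spec.scaling["deploy"]
        x = np.column_stack(
            [
                np.ones(len(data)),
                (data["days_since_deploy"] - mean) / sd,
                data["has_acd"].astype(float),
            ]
        )
        oracle = sm.GLM(data["count"].to_numpy(), x, family=sm.families.Poisson()).fit()
        assert fit.beta == pytest.approx(oracle.params, abs=1e-6)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)
        assert fit.se == pytest.approx(oracle.bse, rel=1e-4)
        assert fit.aic == pytest.approx(oracle.aic, abs=1e-5)

    def test_laplace_with_tiny_sigma_equals_glm(self):
        rng = np.random.default_rng(2)
        data = small_frame(rng, beta_acd=0.3)
        spec_glm = ModelSpec(fixed_terms=["acd"], random_intercepts=[])
        spec_mixed = ModelSpec(fixed_terms=["acd"], random_intercepts=["site"])
        glm = fit_poisson_glmm(data, spec_glm)
        laplace = fit_poisson_glmm(data, spec_mixed, fix_sd=1e-6)
        assert laplace.beta == pytest.approx(glm.beta, abs=1e-6)
        assert laplace.loglik == pytest.approx(glm.loglik, abs=1e-4)

    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(3)
        data = small_frame(rng, base_rate=1.7)
        fit = fit_poisson_glmm(data, ModelSpec())
        assert fit.beta[0] == pytest.approx(np.log(data["count"].mean()), abs=1e-8)

    def test_all_zero_response_rejected(self):
        rng = np.random.default_rng(4)
        data = small_frame(rng)
        data["count"] = 0
        with pytest.raises(FitError):
            fit_poisson_glmm(data, ModelSpec())

    def test_rank_deficiency_names_alias(self):
        rng = np.random.default_rng(5)
        data = small_frame(rng)
        data["dup"] = data["has_acd"].astype(float)
        spec = ModelSpec(fixed_terms=["acd", "dup"])
        with pytest.raises(FitError, match="alias"):
            fit_poisson_glmm(data, spec)


class TestLaplaceRecovery:
    def test_paper_scale_estimates_near_truth(self):
        scenario = SimScenario(
            seed=11,
            glmm_betas={"deploy": -0.3, "acd": 0.2, "scrape": 0.8, "acd:scrape": 0.5},
            re_sds={"site": 0.3, "season": 0.15, "year": 0.1},
        )
        frame, truth = simulate_detection_history(scenario)
        assert len(frame) == 13375
        spec = ModelSpec(
            fixed_terms=list(truth["betas"]), random_intercepts=list(truth["re_sds"])
        )
        fit = fit_poisson_glmm(frame, spec)
        assert fit.converged
        expected = [truth["intercept"]] + [truth["betas"][t] for t in fit.terms[1:]]
        for term, b, se, target in zip(fit.terms, fit.beta, fit.se, expected):
            assert abs(b - target) < 4 * se, f"{term}: {b} vs {target} (se {se})"

    def test_random_effect_modes_sum_near_zero(self):
        scenario = SimScenario(seed=12, glmm_betas={"acd": 0.3}, re_sds={"site": 0.4})
        frame, _ = simulate_detection_history(scenario)
        fit = fit_poisson_glmm(frame, ModelSpec(fixed_terms=["acd"], random_intercepts=["site"]))
        modes = np.array(list(fit.re_modes["site"].values()))
        assert len(modes) == scenario.n_sites
        assert abs(modes.mean()) < 0.15


class TestBackwardSelect:
    def test_marginality_interaction_removed_first(self):
        rng = np.random.default_rng(6)
        data = small_frame(rng, beta_acd=0.0)
        spec = ModelSpec(fixed_terms=["deploy", "acd", "deploy:acd"])
        _, _, trail = backward_select(data, spec)
        removed = [step["term"] for step in trail if step["action"] == "removed"]
        if "deploy" in removed and "deploy:acd" in removed:
            assert removed.index("deploy:acd") < removed.index("deploy")
        if "acd" in removed and "deploy:acd" in removed:
            assert removed.index("deploy:acd") < removed.index("acd")

    def test_true_effect_retained_noise_dropped(self):
        kept_true = 0
        dropped_noise = 0
        n_reps = 60
        for seed in range(n_reps):
            rng = np.random.default_rng(1000 + seed)
            data = small_frame(rng, n=400, beta_acd=0.8, base_rate=1.0)
            spec = ModelSpec(fixed_terms=["deploy", "lure", "acd", "scrape"])
            selected, _, _ = backward_select(data, spec)
            if "acd" in selected.fixed_terms:
                kept_true += 1
            dropped_noise += sum(
                t not in selected.fixed_terms for t in ("deploy", "lure", "scrape")
            )
        assert kept_true / n_reps >= 0.9
        assert dropped_noise / (3 * n_reps) >= 0.8

    def test_null_model_reaches_intercept_only(self):
        reached = 0
        n_reps = 40
        for seed in range(n_reps):
            rng = np.random.default_rng(2000 + seed)
            data = small_frame(rng, n=300, base_rate=1.0)
            selected, _, _ = backward_select(data, ModelSpec(fixed_terms=["acd", "scrape"]))
            if not selected.fixed_terms:
                reached += 1
        # two independent alpha=.05 chances to stop early
        assert reached / n_reps >= 0.75

    def test_trail_records_ll_changes(self):
        rng = np.random.default_rng(7)
        data = small_frame(rng)
        _, _, trail = backward_select(data, ModelSpec(fixed_terms=["acd"]))
        assert trail
        for step in trail:
            assert step["chi2"] == pytest.approx(
                2 * (step["ll_full"] - step["ll_reduced"]), abs=1e-9
            )


class TestCompareAic:
    def test_identical_fits_delta_zero(self):
        rng = np.random.default_rng(8)
        data = small_frame(rng)
        fit = fit_poisson_glmm(data, ModelSpec(fixed_terms=["acd"]))
        table = compare_aic([fit, fit])
        assert table["delta_aic"].tolist() == [0.0, 0.0]

    def test_delta_arithmetic(self):
        rng = np.random.default_rng(9)
        data = small_frame(rng)
        f1 = fit_poisson_glmm(data, ModelSpec(fixed_terms=["acd"]))
        f2 = fit_poisson_glmm(data, ModelSpec())
        # AIC = -2 ll + 2 p exactly
        for f in (f1, f2):
            assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.n_params)
        table = compare_aic([f1, f2])
        assert table["delta_aic"].iloc[0] == 0.0
        assert table["delta_aic"].iloc[1] == pytest.approx(abs(f1.aic - f2.aic))

    def test_mismatched_data_rejected(self):
        rng = np.random.default_rng(10)
        d1, d2 = small_frame(rng), small_frame(rng)
        f1 = fit_poisson_glmm(d1, ModelSpec())
        f2 = fit_poisson_glmm(d2, ModelSpec())
        with pytest.raises(FitError):
            compare_aic([f1, f2])

    def test_aic_invariant_to_covariate_scaling(self):
        rng = np.random.default_rng(11)
        data = small_frame(rng, beta_deploy=-0.4)
        z_fit = fit_poisson_glmm(data, ModelSpec(fixed_terms=["deploy"]))
        raw_fit = fit_poisson_glmm(
            data, ModelSpec(fixed_terms=["deploy"], scaling={"deploy": (0.0, 1.0)})
        )
        assert raw_fit.loglik == pytest.approx(z_fit.loglik, abs=1e-6)
        assert raw_fit.aic == pytest.approx(z_fit.aic, abs=1e-6)


class TestType3Anova:
    def test_wald_identity_single_df(self):
        rng = np.random.default_rng(12)
        data = small_frame(rng, beta_acd=0.5)
        spec = ModelSpec(fixed_terms=["deploy", "acd"], coding="sum")
        fit = fit_poisson_glmm(data, spec)
        anova = type3_anova(data, spec, fit)
        for _, row in anova.iterrows():
            i = fit.terms.index(row["term"])
            assert row["chi2"] == pytest.approx((fit.beta[i] / fit.se[i]) ** 2, rel=1e-9)
            assert row["df"] == 1

    def test_refits_with_sum_coding(self):
        rng = np.random.default_rng(13)
        data = small_frame(rng, beta_acd=0.5)
        spec = ModelSpec(fixed_terms=["acd"], coding="treatment")
        fit = fit_poisson_glmm(data, spec)
        anova = type3_anova(data, spec, fit)  # must refit internally
        assert set(anova["term"]) == {"acd"}
        assert (anova["p"] < 0.05).all()

    def test_null_term_p_uniform(self):
        p_values = []
        for seed in range(200):
            rng = np.random.default_rng(3000 + seed)
            data = small_frame(rng, n=250, base_rate=1.0)
            anova = type3_anova(data, ModelSpec(fixed_terms=["acd"], coding="sum"))
            p_values.append(anova["p"].iloc[0])
        ks = stats.kstest(p_values, "uniform")
        assert ks.pvalue > 0.01


class TestDiagnostics:
    def test_well_specified_ratios_near_one(self):
        rng = np.random.default_rng(14)
        n = 20_000
        data = small_frame(rng, n=n, base_rate=0.8)
        fit = fit_poisson_glmm(data, ModelSpec())
        dispersion, zero_inflation = diagnostics(fit, data)
        assert dispersion == pytest.approx(1.0, abs=0.1)
        assert zero_inflation == pytest.approx(1.0, abs=0.1)

    def test_doubled_counts_dispersion_two(self):
        rng = np.random.default_rng(15)
        data = small_frame(rng, n=5000, base_rate=2.0)
        data["count"] = 2 * data["count"]
        fit = fit_poisson_glmm(data, ModelSpec())
        dispersion, _ = diagnostics(fit, data)
        assert dispersion == pytest.approx(2.0, rel=0.15)

    def test_injected_zeros_inflate_ratio(self):
        rng = np.random.default_rng(16)
        data = small_frame(rng, n=5000, base_rate=2.0)
        mask = rng.random(len(data)) < 0.2
        data.loc[mask, "count"] = 0
        fit = fit_poisson_glmm(data, ModelSpec())
        _, zero_inflation = diagnostics(fit, data)
        assert zero_inflation > 1.0


class TestPercentChange:
    def test_zero_beta(self):
        assert percent_change_per_day(0.0, 63.0) == 0.0

    def test_one_percent_definition(self):
        sd = 50.0
        beta = np.log(1.01) * sd
        assert percent_change_per_day(beta, sd) == pytest.approx(1.0)

    def test_sd_zero_rejected(self):
        with pytest.raises(ValueError):
            percent_change_per_day(0.5, 0.0)

    def test_recovery_of_per_day_multiplier(self):
        daily_change = -0.003  # -0.3% per day
        scenario = SimScenario(
            seed=17, n_sites=40, total_ct_days=8000,
            glmm_intercept=np.log(0.2), re_sds={},
        )
        # find the scaled beta matching the daily multiplier for this schedule
        frame, truth = simulate_detection_history(
            SimScenario(seed=17, n_sites=40, total_ct_days=8000, re_sds={})
        )
        sd_days = frame["days_since_deploy"].std(ddof=0)
        beta_scaled = np.log(1 + daily_change) * sd_days
        scenario.glmm_betas = {"deploy": beta_scaled}
        frame, truth = simulate_detection_history(scenario)
        fit = fit_poisson_glmm(frame, ModelSpec(fixed_terms=["deploy"]))
        i = fit.terms.index("deploy")
        recovered = percent_change_per_day(fit.beta[i], fit.spec.scaling["deploy"][1])
        se_pct = percent_change_per_day(fit.beta[i] + fit.se[i], fit.spec.scaling["deploy"][1]) - recovered
        assert recovered == pytest.approx(daily_change * 100, abs=4 * abs(se_pct))


def test_parse_formula_terms():
    assert parse_formula_terms("deploy*acd + lure") == ["deploy", "acd", "lure", "deploy:acd"]
    assert parse_formula_terms("a:b + a + b") == ["a", "b", "a:b"]
    terms = parse_formula_terms("a*b*c")
    assert set(terms) == {"a", "b", "c", "a:b", "a:c", "b:c", "a:b:c"}
    assert terms.index("a:b:c") > terms.index("a:b")


def test_season_of():
    import datetime

    assert season_of(datetime.date(2018, 12, 5)) == "DJF"
    assert season_of(datetime.date(2018, 2, 5)) == "DJF"
    assert season_of(datetime.date(2018, 4, 5)) == "MAM"
    assert season_of(datetime.date(2018, 7, 5)) == "JJA"
    assert season_of(datetime.date(2018, 10, 5)) == "SON"
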