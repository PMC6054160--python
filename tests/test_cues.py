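"""Abiotic summaries, mixed-model fitting, AICc selection and R2."""

import warnings

import numpy as np
import pandas as pd
import pytest

from phenosync import cues, io_cli, synth
from phenosync.cues import (
    ModelFit,
    ModelSpec,
    aicc,
    build_candidate_grid,
    fit_lmm,
    marginal_slope,
    r2_glmm,
    rank_models,
    run_cue_analysis,
    summarize_abiotic,
)


def _abiotic_frame(rows):
    return pd.DataFrame(rows, columns=list(cues.ABIOTIC_COLUMNS))


def _plot_rows(site, plot, doys, t1, t25, m):
    return [
        {"site": site, "plot": plot, "doy": d, "temp_1cm": a, "temp_25cm": b, "moisture": c}
        for d, a, b, c in zip(doys, t1, t25, m)
    ]


def _lmm_frame(rng, n_sites=5, plots_per_site=6, beta=(100.0, -10.0),
               sd_site=0.0, sd_resid=1.0):
    """Plot-level table with response linear in t25_max (+ optional noise)."""
    rows = []
    for s in range(n_sites):
        u = rng.normal(0, sd_site)
        for p in range(plots_per_site):
            t = rng.uniform(10, 14)
            m = rng.uniform(0.1, 0.3)
            y = beta[0] + beta[1] * t + u + rng.normal(0, sd_resid)
            rows.append({"site": f"S{s}", "plot": f"S{s}-P{p}", "t25_max": t,
                         "t25_ave": t - rng.uniform(1, 2), "m_ave": m, "start_doy": y})
    return pd.DataFrame(rows)


class TestSummarizeAbiotic:
    def test_min_max_mean(self):
        df = _abiotic_frame(_plot_rows("S1", "P1", [40, 50, 60],
                                       [8, 10, 12], [9, 10, 11], [0.2, 0.3, 0.4]))
        out = summarize_abiotic(df)
        row = out.iloc[0]
        assert (row.t1_min, row.t1_ave, row.t1_max) == (8, 10, 12)
        assert (row.t25_min, row.t25_ave, row.t25_max) == (9, 10, 11)
        assert row.m_ave == pytest.approx(0.3)

    def test_constant_series_collapses(self):
        df = _abiotic_frame(_plot_rows("S1", "P1", [40, 50], [7, 7], [7, 7], [0.2, 0.2]))
        row = summarize_abiotic(df).iloc[0]
        assert row.t1_min == row.t1_ave == row.t1_max == 7

    def test_matches_brute_force_on_random_records(self, rng):
        doys = np.arange(35, 150, 6)
        t1 = rng.uniform(5, 20, doys.size)
        t25 = rng.uniform(5, 15, doys.size)
        m = rng.uniform(0.05, 0.45, doys.size)
        out = summarize_abiotic(_abiotic_frame(_plot_rows("S1", "P1", doys, t1, t25, m)))
        row = out.iloc[0]
        assert row.t1_min == pytest.approx(min(t1))
        assert row.t1_max == pytest.approx(max(t1))
        assert row.t25_ave == pytest.approx(sum(t25) / len(t25))
        assert row.m_ave == pytest.approx(sum(m) / len(m))

    def test_window_filters_out_of_season_rows(self):
        rows = _plot_rows("S1", "P1", [20, 40, 50, 160], [99, 8, 10, 99],
                          [99, 9, 11, 99], [0.2, 0.2, 0.2, 0.2])
        row = summarize_abiotic(_abiotic_frame(rows), window=(32, 151)).iloc[0]
        assert row.t1_max == 10  # doy 20 and 160 excluded

    def test_too_few_in_window_records_error_names_plot(self):
        df = _abiotic_frame(_plot_rows("S1", "P9", [40], [8], [9], [0.2]))
        with pytest.raises(ValueError, match="P9"):
            summarize_abiotic(df)

    def test_moisture_out_of_range_rejected(self):
        df = _abiotic_frame(_plot_rows("S1", "P1", [40, 50], [8, 9], [9, 9], [0.2, 1.2]))
        with pytest.raises(ValueError, match="moisture"):
            summarize_abiotic(df)


class TestCandidateGrid:
    def test_stage_sizes(self):
        stage1 = build_candidate_grid(1)
        assert len(stage1) == 8
        assert [s.label for s in stage1[:2]] == ["null", "M_ave"]
        stage2 = build_candidate_grid(2, best_temp="T25_max")
        assert len(stage2) == 3
        assert stage2[-1].interaction

    def test_null_parameter_count(self):
        null = build_candidate_grid(1)[0]
        assert null.n_fixed == 1  # k = 1 + 2 variance components = 3

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError):
            ModelSpec("bad", temp="t25_max", moisture=False, interaction=True)


class TestAicc:
    @pytest.mark.parametrize(
        "k, n, extra",
        [(4, 30, 1.6), (3, 17, 24 / 13), (3, 10_000, 24 / 9996)],
    )
    def test_correction_term(self, k, n, extra):
        ll = -123.4
        assert aicc(ll, k, n) == pytest.approx(-2 * ll + 2 * k + extra)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            aicc(-10.0, k=5, n=6)


class TestFitLmm:
    def test_matches_ols_with_site_variance_constrained(self, rng):
        data = _lmm_frame(rng, sd_site=3.0, sd_resid=2.0)
        spec = ModelSpec("T25_max", temp="t25_max")
        fit = fit_lmm(spec, data, "start_doy", constrain_site_variance=True)
        X = spec.design_matrix(data)
        beta_ols, *_ = np.linalg.lstsq(X, data["start_doy"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-6)
        assert fit.var_site == 0.0

    def test_single_site_reduces_to_ols(self, rng):
        data = _lmm_frame(rng, n_sites=1, plots_per_site=12, sd_resid=2.0)
        spec = ModelSpec("T25_max", temp="t25_max")
        fit = fit_lmm(spec, data, "start_doy")
        X = spec.design_matrix(data)
        beta_ols, *_ = np.linalg.lstsq(X, data["start_doy"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-6)

    def test_exact_linear_response_recovered(self, rng):
        data = _lmm_frame(rng, sd_site=0.0, sd_resid=1e-8)
        fit = fit_lmm(ModelSpec("T25_max", temp="t25_max"), data, "start_doy")
        assert fit.beta[1] == pytest.approx(-10.0, abs=1e-4)
        assert fit.var_site == 0.0 and fit.singular

    def test_constant_response_gives_zero_slope(self, rng):
        data = _lmm_frame(rng, beta=(100.0, 0.0), sd_site=0.0, sd_resid=0.0)
        data["start_doy"] = 100.0
        fit = fit_lmm(ModelSpec("T25_max", temp="t25_max"), data, "start_doy")
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-8)
        assert fit.var_site == pytest.approx(0.0, abs=1e-8)

    def test_translation_of_response_changes_only_intercept(self, rng):
        data = _lmm_frame(rng, sd_site=2.0, sd_resid=2.0)
        spec = ModelSpec("TM", temp="t25_max", moisture=True)
        f0 = fit_lmm(spec, data, "start_doy")
        shifted = data.copy()
        shifted["start_doy"] = shifted["start_doy"] + 17.0
        f1 = fit_lmm(spec, shifted, "start_doy")
        assert f1.beta[0] == pytest.approx(f0.beta[0] + 17.0, abs=1e-5)
        np.testing.assert_allclose(f1.beta[1:], f0.beta[1:], atol=1e-6)
        assert f1.loglik == pytest.approx(f0.loglik, abs=1e-6)

    def test_k_counts_fixed_plus_two_variances(self, rng):
        data = _lmm_frame(rng, sd_site=2.0, sd_resid=2.0)
        fit = fit_lmm(ModelSpec("null"), data, "start_doy")
        assert fit.k == 3
        fit2 = fit_lmm(
            ModelSpec("full", temp="t25_max", moisture=True, interaction=True),
            data, "start_doy",
        )
        assert fit2.k == 6

    def test_matches_statsmodels_mixedlm(self, rng):
        """Independent oracle: statsmodels MixedLM on an interior-optimum fit."""
        import statsmodels.api as sm

        data = _lmm_frame(rng, n_sites=6, plots_per_site=8, sd_site=8.0, sd_resid=2.0)
        spec = ModelSpec("T25_max", temp="t25_max")
        mine = fit_lmm(spec, data, "start_doy")
        X = spec.design_matrix(data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(
                data["start_doy"].to_numpy(), X, groups=data["site"].to_numpy()
            ).fit(reml=False)
        # the profile solver should never find a worse optimum
        assert mine.loglik >= float(ref.llf) - 1e-4
        np.testing.assert_allclose(mine.beta, np.asarray(ref.fe_params), rtol=2e-3)
        assert mine.var_site == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), rel=0.05)
        assert mine.var_resid == pytest.approx(float(ref.scale), rel=0.05)

    def test_reml_matches_statsmodels_reml_variances(self, rng):
        import statsmodels.api as sm

        data = _lmm_frame(rng, n_sites=6, plots_per_site=8, sd_site=8.0, sd_resid=2.0)
        spec = ModelSpec("T25_max", temp="t25_max")
        mine = fit_lmm(spec, data, "start_doy", reml=True)
        X = spec.design_matrix(data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.MixedLM(
                data["start_doy"].to_numpy(), X, groups=data["site"].to_numpy()
            ).fit(reml=True)
        np.testing.assert_allclose(mine.beta, np.asarray(ref.fe_params), rtol=2e-3)
        assert mine.var_site == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), rel=0.05)


class TestRanking:
    def _stub(self, label, ll, k=4, n=30):
        spec = ModelSpec(label, temp="t25_max" if label != "null" else None)
        return ModelFit(
            spec=spec, response="start_doy", coef_names=spec.coef_names,
            beta=np.zeros(spec.n_fixed), se=np.zeros(spec.n_fixed),
            var_site=1.0, var_resid=1.0, loglik=ll, n=n, k=k,
            aicc=aicc(ll, k, n), r2m=0.1, r2c=0.2,
        )

    def test_single_model_delta_zero(self):
        tab = rank_models([self._stub("T25_max", -100.0)])
        assert tab["delta_aicc"].iloc[0] == 0.0
        assert tab["co_best"].iloc[0]

    def test_within_one_unit_flagged_co_best(self):
        # AICc values 2433.6 and 2433.9: 0.3 apart -> both co-best
        f1 = self._stub("T1_ave", -(2433.6 - 2 * 4 - 1.6) / 2)
        f2 = self._stub("T25_ave", -(2433.9 - 2 * 4 - 1.6) / 2)
        tab = rank_models([f2, f1])
        assert tab["aicc"].iloc[0] == pytest.approx(2433.6)
        assert tab["delta_aicc"].iloc[1] == pytest.approx(0.3)
        assert tab["co_best"].all()

    def test_mixed_responses_rejected(self):
        a = self._stub("T25_max", -100.0)
        b = ModelFit(
            spec=a.spec, response="peak_doy", coef_names=a.coef_names,
            beta=a.beta, se=a.se, var_site=1.0, var_resid=1.0,
            loglik=-90.0, n=30, k=4, aicc=aicc(-90.0, 4, 30), r2m=0.1, r2c=0.2,
        )
        with pytest.raises(ValueError):
            rank_models([a, b])


class TestR2:
    def test_variance_partition_arithmetic(self):
        # fixed predictor variance 4, site 1, residual 1 -> 2/3 and 5/6
        data = pd.DataFrame({
            "site": ["A", "B", "C"], "plot": list("abc"),
            "t25_max": [-2.0, 0.0, 2.0], "start_doy": [0.0, 0.0, 0.0],
        })
        spec = ModelSpec("T25_max", temp="t25_max")
        fit = ModelFit(
            spec=spec, response="start_doy", coef_names=spec.coef_names,
            beta=np.array([0.0, 1.0]), se=np.zeros(2), var_site=1.0, var_resid=1.0,
            loglik=0.0, n=3, k=4, aicc=0.0, r2m=0.0, r2c=0.0,
        )
        r2m, r2c = r2_glmm(fit, data)
        assert r2m == pytest.approx(2 / 3)
        assert r2c == pytest.approx(5 / 6)

    def test_no_site_variance_makes_marginal_equal_conditional(self, rng):
        data = _lmm_frame(rng, sd_site=0.0, sd_resid=2.0)
        fit = fit_lmm(ModelSpec("T25_max", temp="t25_max"), data, "start_doy")
        assert fit.r2m == pytest.approx(fit.r2c)

    def test_null_model_marginal_r2_zero(self, rng):
        data = _lmm_frame(rng, sd_site=2.0, sd_resid=2.0)
        fit = fit_lmm(ModelSpec("null"), data, "start_doy")
        assert fit.r2m == 0.0
        assert 0.0 <= fit.r2m <= fit.r2c <= 1.0


class TestMarginalSlope:
    def test_no_interaction_returns_main_effect(self, rng):
        data = _lmm_frame(rng, sd_site=1.0, sd_resid=2.0)
        fit = fit_lmm(ModelSpec("TM", temp="t25_max", moisture=True), data, "start_doy")
        slopes = marginal_slope(fit, data)
        assert slopes["temperature"] == pytest.approx(fit.coef("t25_max"))

    def test_matches_finite_difference_of_fitted_surface(self, rng):
        data = _lmm_frame(rng, sd_site=1.0, sd_resid=2.0)
        fit = fit_lmm(
            ModelSpec("full", temp="t25_max", moisture=True, interaction=True),
            data, "start_doy",
        )
        slopes = marginal_slope(fit, data)
        mean_t = data["t25_max"].mean()
        mean_m = data["m_ave"].mean()

        def surface(t, m):
            return (fit.coef("intercept") + fit.coef("t25_max") * t
                    + fit.coef("m_ave") * m + fit.coef("t25_max:m_ave") * t * m)

        h = 1e-6
        fd_t = (surface(mean_t + h, mean_m) - surface(mean_t - h, mean_m)) / (2 * h)
        fd_m = (surface(mean_t, mean_m + h) - surface(mean_t, mean_m - h)) / (2 * h)
        assert slopes["temperature"] == pytest.approx(fd_t, rel=1e-6)
        assert slopes["moisture"] == pytest.approx(fd_m, rel=1e-6)

    def test_temperature_only_model_rejected(self, rng):
        data = _lmm_frame(rng, sd_site=1.0, sd_resid=2.0)
        fit = fit_lmm(ModelSpec("T25_max", temp="t25_max"), data, "start_doy")
        with pytest.raises(ValueError):
            marginal_slope(fit, data)


class TestRunCueAnalysis:
    def test_minimal_two_site_dataset_runs(self):
        # smallest design on which the full grid is estimable: the
        # interaction model has k = 6, so each role needs n > 7 plots
        cfg = synth.SynthConfig(n_sites=2, bee_plots_per_site=4,
                                flower_plots_per_site=4, seed=3)
        data = synth.generate_dataset(cfg)
        pheno = io_cli.phenology_table(io_cli.read_census_frame(data.census))
        report = run_cue_analysis(pheno, data.summaries)
        models = report["models"]
        assert set(models["role"]) == {"bee", "flower"}
        assert set(models["phenophase"]) == {"start", "peak", "end"}
        assert not report["marginal_slopes"].empty

    def test_tidy_output_schema(self, default_dataset, default_phenology):
        report = run_cue_analysis(default_phenology, default_dataset.summaries)
        models = report["models"]
        for col in ("role", "phenophase", "stage", "model", "terms", "aicc",
                    "delta_aicc", "r2m", "r2c", "coef_name", "estimate", "se",
                    "var_site", "var_resid", "n", "k"):
            assert col in models.columns
        stage1 = models[models["stage"] == 1]
        # 8 candidate models per role x phenophase in stage 1
        assert stage1.groupby(["role", "phenophase"])["model"].nunique().eq(8).all()
        assert (models["r2m"] <= models["r2c"] + 1e-12).all()
        assert models["aicc"].notna().all()

    def test_plots_missing_abiotic_are_dropped_not_imputed(self, default_dataset,
                                                           default_phenology, caplog):
        summaries = default_dataset.summaries.iloc[:-2]
        import logging

        with caplog.at_level(logging.WARNING):
            report = run_cue_analysis(default_phenology, summaries)
        assert "lack abiotic summaries" in caplog.text
        models = report["models"]
        # within a role every candidate model sees the same plot set, and the
        # dropped plots are really gone
        per_role = models.groupby("role")["n"].agg(["nunique", "first"])
        assert (per_role["nunique"] == 1).all()
        kept = default_phenology.merge(summaries, on=["site", "plot"])
        for role, row in per_role.iterrows():
            assert row["first"] == (kept["role"] == role).sum()
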