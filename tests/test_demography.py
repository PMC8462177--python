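"""Measurement conversions, standardization, model fitting and stepwise AIC."""

import numpy as np
import pandas as pd
import pytest

from edelweiss import demography
from edelweiss.demography import (
    braun_blanquet_to_cover,
    build_design,
    fresh_to_dry,
    plot_totals,
    prepare_predictors,
    r2_nakagawa,
    seeds_per_inflorescence,
    significance_flags,
    stepwise_backward,
)


class TestConverters:
    @pytest.mark.parametrize(
        "rank,cover",
        [("+", 0.5), ("1", 5.0), ("2", 17.5), ("3", 37.5), ("4", 62.5), ("5", 87.5), (0, 0.0)],
    )
    def test_braun_blanquet_midpoints(self, rank, cover):
        assert braun_blanquet_to_cover(rank) == cover

    def test_unknown_rank_raises(self):
        with pytest.raises(ValueError, match="rank"):
            braun_blanquet_to_cover("6")

    def test_fresh_to_dry_coefficient(self):
        assert fresh_to_dry(1.0) == pytest.approx(0.89)
        assert fresh_to_dry(0.0) == 0.0
        assert fresh_to_dry(100.0) == pytest.approx(89.0)
        with pytest.raises(ValueError):
            fresh_to_dry(-1.0)

    def test_seeds_per_inflorescence_rounding(self):
        assert seeds_per_inflorescence(5.0, 20) == 100
        assert seeds_per_inflorescence(5.0, 0) == 0
        assert seeds_per_inflorescence(4.6, 7) == 32  # 32.2 rounds down
        assert seeds_per_inflorescence(4.5, 7) == 32  # 31.5 rounds half-up

    def test_plot_totals(self):
        assert plot_totals(100.0, 6) == 600.0
        assert plot_totals(42.0, 0) == 0.0

    def test_chain_consistency_oracle(self):
        # anthodium -> inflorescence -> plot equals the one-shot product
        seeds_anth, n_anth, n_infl = 4.0, 10, 6
        per_infl = seeds_per_inflorescence(seeds_anth, n_anth)
        assert plot_totals(per_infl, n_infl) == seeds_anth * n_anth * n_infl


class TestPreparePredictors:
    def test_logit_values(self):
        tab = pd.DataFrame({"favorability": [0.5, 0.95, 0.2], "other": [1.0, 2.0, 3.0]})
        design, scal = prepare_predictors(tab, ["favorability", "other"])
        # recover the un-standardized logit from stored constants
        raw = design["favorability"] * scal["favorability"]["sd"] + scal["favorability"]["mean"]
        assert raw.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert raw.iloc[1] == pytest.approx(np.log(19), abs=1e-9)
        assert scal["favorability"]["logit"] and not scal["other"]["logit"]

    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({"favorability": rng.uniform(0.1, 0.9, 50), "a": rng.normal(5, 2, 50)})
        design, _ = prepare_predictors(tab, ["favorability", "a"])
        assert np.allclose(design.mean(), 0, atol=1e-12)
        assert np.allclose(design.std(ddof=1), 1, atol=1e-12)

    def test_round_trip_via_stored_constants(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({"a": rng.normal(10, 3, 30)})
        design, scal = prepare_predictors(tab, ["a"])
        back = design["a"] * scal["a"]["sd"] + scal["a"]["mean"]
        np.testing.assert_allclose(back, tab["a"], atol=1e-12)

    def test_zero_sd_raises_naming_column(self):
        tab = pd.DataFrame({"a": np.ones(10)})
        with pytest.raises(ValueError, match="'a'"):
            prepare_predictors(tab, ["a"])


class TestSignificance:
    def _model_with_ci(self, cis):
        class _F:
            terms = [f"t{i}" for i in range(len(cis))]
            ci = np.array(cis)

        m = demography.FitnessModel("x", "gaussian", _F(), {}, list(_F.terms))
        return m

    def test_ci_rule(self):
        m = self._model_with_ci([[0.02, 1.00], [-0.94, 0.009], [-1.0, 1.0], [-0.8, -0.1]])
        flags = significance_flags(m)
        assert flags == {"t0": True, "t1": False, "t2": False, "t3": True}


class TestFitModels:
    def test_noise_off_recovery_within_1e3(self, demo_tables_noise_off):
        plots, _, info = demo_tables_noise_off
        terms = list(info["count_beta"])[1:]  # skip intercept key ordering
        terms = [
            "favorability", "trail_distance_m", "hemiparasite_cover", "cushion_cover",
            "woody_cover", "mean_inflorescence_height_cm", "favorability:trail_distance_m",
        ]
        std, scal = prepare_predictors(plots, terms[:-1])
        groups = {"site": plots["site_id"].to_numpy(), "plot_olre": np.arange(len(plots))}
        m = demography.fit_count_model(
            plots["seed_number_per_m2"].to_numpy(), std, terms, groups, olre="plot_olre"
        )
        for t, b in zip(m.fit.terms, m.fit.beta):
            assert b == pytest.approx(info["count_beta"][t], abs=1e-3), t

    def test_mass_noise_off_exact(self, demo_tables_noise_off):
        plots, _, info = demo_tables_noise_off
        terms = ["favorability", "trail_distance_m", "hemiparasite_cover",
                 "woody_cover", "mean_inflorescence_height_cm"]
        std, _ = prepare_predictors(plots, terms)
        m = demography.fit_mass_model(
            plots["dry_seed_mass_mg_per_m2"].to_numpy(), std, terms,
            {"site": plots["site_id"].to_numpy()},
        )
        for t, b in zip(m.fit.terms, m.fit.beta):
            assert b == pytest.approx(info["mass_gamma"][t], abs=1e-3), t

    def test_cube_root_round_trip(self, demo_tables_noise_off):
        plots, _, info = demo_tables_noise_off
        terms = ["favorability", "trail_distance_m", "hemiparasite_cover",
                 "woody_cover", "mean_inflorescence_height_cm"]
        std, scal = prepare_predictors(plots, terms)
        m = demography.fit_mass_model(
            plots["dry_seed_mass_mg_per_m2"].to_numpy(), std, terms,
            {"site": plots["site_id"].to_numpy()}, scaling=scal,
        )
        pred = m.predict({"favorability": plots["favorability"].to_numpy(),
                          "trail_distance_m": plots["trail_distance_m"].to_numpy(),
                          "hemiparasite_cover": plots["hemiparasite_cover"].to_numpy(),
                          "woody_cover": plots["woody_cover"].to_numpy(),
                          "mean_inflorescence_height_cm": plots["mean_inflorescence_height_cm"].to_numpy()})
        np.testing.assert_allclose(
            np.cbrt(pred) ** 3, pred, atol=1e-9
        )
        # noiseless truth: predictions match observed masses
        np.testing.assert_allclose(pred, plots["dry_seed_mass_mg_per_m2"], rtol=1e-3)

    def test_negative_counts_rejected(self, demo_tables_noise_off):
        plots, _, _ = demo_tables_noise_off
        std, _ = prepare_predictors(plots, ["favorability"])
        with pytest.raises(ValueError, match="non-negative"):
            demography.fit_count_model(
                np.array([-1] * len(plots)), std, ["favorability"], {}, olre=None
            )


class TestR2:
    def test_zero_fixed_effects_zero_rm2(self):
        rng = np.random.default_rng(0)
        n = 200
        y = rng.normal(3, 1, n)
        X = pd.DataFrame({"(Intercept)": np.ones(n)})
        from edelweiss.mixed import fit_glmm

        f = fit_glmm(y, X, groups={"g": rng.integers(0, 5, n)}, family="gaussian")
        m = demography.FitnessModel("x", "gaussian", f, {}, ["(Intercept)"])
        rm2, rc2 = r2_nakagawa(m)
        assert rm2 == pytest.approx(0.0, abs=1e-9)
        assert rc2 >= rm2

    def test_gaussian_variance_decomposition_oracle(self):
        rng = np.random.default_rng(1)
        n, n_g = 3000, 60
        x = rng.standard_normal(n)
        g = rng.integers(0, n_g, n)
        u = rng.normal(0, 0.8, n_g)
        y = 1.0 + 0.9 * x + u[g] + rng.normal(0, 0.6, n)
        from edelweiss.mixed import fit_glmm

        X = pd.DataFrame({"(Intercept)": np.ones(n), "x": x})
        f = fit_glmm(y, X, groups={"g": g}, family="gaussian")
        m = demography.FitnessModel("x", "gaussian", f, {}, ["x"])
        rm2, rc2 = r2_nakagawa(m)
        # oracle: direct decomposition from the fitted quantities
        var_f = np.var(f.fitted_linear)
        denom = var_f + f.vc["g"] + f.vc["residual"]
        assert rm2 == pytest.approx(var_f / denom, abs=1e-6)
        assert rc2 == pytest.approx((var_f + f.vc["g"]) / denom, abs=1e-6)
        # sanity against generative shares: fixed ~ 0.81/(0.81+0.64+0.36)
        assert rm2 == pytest.approx(0.81 / 1.81, abs=0.05)

    def test_zero_random_variance_rm_equals_rc(self):
        rng = np.random.default_rng(2)
        n = 300
        x = rng.standard_normal(n)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.5, n)
        from edelweiss.mixed import fit_glmm

        X = pd.DataFrame({"(Intercept)": np.ones(n), "x": x})
        f = fit_glmm(y, X, groups={}, family="gaussian")
        m = demography.FitnessModel("x", "gaussian", f, {}, ["x"])
        rm2, rc2 = r2_nakagawa(m)
        assert rm2 == pytest.approx(rc2)


@pytest.fixture(scope="module")
def stepwise_fit(demo_tables):
    plots, _, info = demo_tables
    terms = [
        "favorability", "trail_distance_m", "hemiparasite_cover", "cushion_cover",
        "woody_cover", "mean_inflorescence_height_cm", "favorability:trail_distance_m",
    ]
    std, scal = prepare_predictors(plots, terms[:-1])
    groups = {"site": plots["site_id"].to_numpy(), "plot_olre": np.arange(len(plots))}
    return stepwise_backward(
        plots["seed_number_per_m2"].to_numpy(), std, terms, groups,
        family="poisson", olre="plot_olre", scaling=scal, label="number_plot",
    )


class TestStepwise:
    def test_interaction_protects_main_effects(self, stepwise_fit):
        terms = stepwise_fit.terms
        for t in terms:
            if ":" in t:
                for parent in t.split(":"):
                    assert parent in terms

    def test_trace_and_final_aic_bound(self, stepwise_fit):
        trace_aics = [a for _, a in stepwise_fit.aic_trace]
        assert stepwise_fit.aic <= min(trace_aics) + 2.0

    def test_null_covariate_dropped_often(self, truth, favorability, trails):
        """The truly-zero covariates (cushion cover, Env x Trail) should be
        pruned in most replicates at a scaled-up sample size."""
        from edelweiss import synthetic

        terms = [
            "favorability", "trail_distance_m", "hemiparasite_cover", "cushion_cover",
            "woody_cover", "mean_inflorescence_height_cm", "favorability:trail_distance_m",
        ]
        dropped = 0
        reps = 10
        for k in range(reps):
            plots, _, _ = synthetic.make_demography(
                truth, favorability, trails, n_sites=15, plots_per_site=10,
                seed=600 + k, noise=True,
            )
            std, _ = prepare_predictors(plots, terms[:-1])
            groups = {"site": plots["site_id"].to_numpy(), "plot_olre": np.arange(len(plots))}
            m = stepwise_backward(
                plots["seed_number_per_m2"].to_numpy(), std, terms, groups,
                family="poisson", olre="plot_olre",
            )
            if "cushion_cover" not in m.terms:
                dropped += 1
        assert dropped >= 0.9 * reps

    def test_kept_terms_match_generative_signal(self, stepwise_fit):
        # strong true effects should survive selection at default sizes
        assert "favorability" in stepwise_fit.terms or "trail_distance_m" in stepwise_fit.terms
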