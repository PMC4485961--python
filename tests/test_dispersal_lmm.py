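import dataclasses
import math

import numpy as np
import pytest

import samaradisp as sd
from samaradisp.dispersal_lmm import (
    DataError,
    FitError,
    build_design,
    compare_wind_covariates,
    design_from_frame,
    fit_lmm,
    fit_lmm_direct,
    predict_median_distance,
    read_fit_json,
    variance_decomposition,
    write_fit_json,
)


class TestBuildDesign:
    def test_transform_rows(self):
        y, X, g, levels = build_design(
            distance=[1.0, 2.0], iwl=[0.0, 44.60], wind=[1.72, 1.72],
            species=["a", "b"],
        )
        np.testing.assert_allclose(y, [0.0, math.log(2.0)])
        np.testing.assert_allclose(
            X[0], [1.0, 0.0, math.log(2.72), 0.0], rtol=1e-9
        )
        row = X[1]
        assert row[1] == pytest.approx(math.log(45.60), rel=1e-9)
        assert row[3] == pytest.approx(math.log(45.60) * math.log(2.72), rel=1e-9)
        assert levels == ["a", "b"]

    def test_rejects_nonpositive_distance_and_bad_wind_choice(self, study_dataset):
        with pytest.raises(DataError):
            build_design([0.0], [1.0], [1.0], ["a"])
        with pytest.raises(DataError):
            design_from_frame(study_dataset, wind_choice="gust")

    def test_single_species_still_fittable(self):
        rng = np.random.default_rng(0)
        n = 60
        iwl = rng.uniform(1, 40, n)
        wind = rng.gamma(1.0, 1.72, n)
        d = np.exp(0.5 + 0.2 * np.log1p(iwl) + rng.normal(0, 0.5, n))
        y, X, g, levels = build_design(d, iwl, wind, ["only"] * n)
        fit = fit_lmm(y, X, g)
        assert len(levels) == 1
        assert fit.params.sigma_species <= 1e-3


class TestFitLMM:
    def test_zero_species_variance_matches_ols(self, table2_truth, study_config):
        truth0 = dataclasses.replace(table2_truth, sigma_species=0.0)
        cfg = dataclasses.replace(study_config, truth=truth0, rng_seed=21)
        df, _ = sd.generate_releases(cfg)
        y, X, g, _ = design_from_frame(df)
        fit = fit_lmm(y, X, g)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert fit.params.sigma_species <= 1e-3
        np.testing.assert_allclose(fit.params.betas, beta_ols, atol=1e-6)

    def test_matches_dense_likelihood_oracle(self, small_dataset):
        """Profiled 1-D search equals direct 2-parameter maximization."""
        y, X, g, _ = design_from_frame(small_dataset)
        fit = fit_lmm(y, X, g)
        direct = fit_lmm_direct(y, X, {"species": g})
        assert fit.reml_criterion == pytest.approx(direct["criterion"], abs=1e-6)
        np.testing.assert_allclose(fit.params.betas, direct["betas"], atol=1e-4)
        assert fit.params.sigma_species == pytest.approx(direct["sigmas"]["species"], abs=1e-4)
        assert fit.params.sigma_resid == pytest.approx(direct["sigma_resid"], abs=1e-4)

    def test_matches_statsmodels_mixedlm(self, small_dataset):
        """Independent library cross-check: the profiled optimum is at least
        as good as statsmodels' MixedLM optimum of the same REML criterion,
        and coincides with it when statsmodels converges cleanly."""
        smf = pytest.importorskip("statsmodels.formula.api")
        import warnings

        import pandas as pd

        from samaradisp.dispersal_lmm import _dense_loglik

        y, X, g, _ = design_from_frame(small_dataset)
        fit = fit_lmm(y, X, g)
        d = pd.DataFrame({"y": y, "li": X[:, 1], "lw": X[:, 2], "ix": X[:, 3], "sp": g})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = smf.mixedlm("y ~ li + lw + ix", d, groups=d["sp"]).fit(reml=True)
        Z = np.zeros((y.size, int(np.max(g)) + 1))
        Z[np.arange(y.size), g] = 1.0
        crit_sm = _dense_loglik(y, X, [Z], [m.cov_re.iloc[0, 0]], m.scale, "REML")
        assert fit.reml_criterion >= crit_sm - 1e-6
        if abs(fit.reml_criterion - crit_sm) < 1e-6:
            np.testing.assert_allclose(fit.params.betas, m.fe_params.values, atol=1e-4)
            assert fit.params.sigma_resid == pytest.approx(np.sqrt(m.scale), abs=1e-4)
            assert fit.params.sigma_species == pytest.approx(
                np.sqrt(m.cov_re.iloc[0, 0]), abs=1e-3
            )

    def test_aic_identity_and_reml_criterion_finite(self, small_fit):
        fit, _, _ = small_fit
        assert fit.aic_ml == pytest.approx(-2 * fit.loglik_ml + 2 * 6)
        assert math.isfinite(fit.reml_criterion)
        assert fit.converged

    def test_lambda_zero_equals_ordinary_regression_criterion(self, small_dataset):
        """With the variance ratio pinned at 0 the profiled REML criterion
        coincides with the ordinary-regression (no random effect) criterion."""
        y, X, g, _ = design_from_frame(small_dataset)
        from samaradisp.dispersal_lmm import _Profile, _dense_loglik

        prof = _Profile(y, X, np.asarray(g))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        sigma2 = float(r @ r) / (y.size - X.shape[1])
        dense = _dense_loglik(y, X, [], [], sigma2, "REML")
        assert prof.criterion(0.0, "REML") == pytest.approx(dense, abs=1e-8)

    def test_rank_deficient_design_raises(self):
        y = np.arange(10.0)
        X = np.ones((10, 2))
        with pytest.raises(FitError):
            fit_lmm(y, X, np.zeros(10, dtype=int))

    def test_fit_json_round_trip(self, small_fit, tmp_path):
        fit, _, _ = small_fit
        path = tmp_path / "fit.json"
        write_fit_json(fit, path)
        back = read_fit_json(path)
        assert back.params == fit.params
        assert back.aic_ml == pytest.approx(fit.aic_ml)
        np.testing.assert_allclose(back.fixed_cov, fit.fixed_cov)


class TestVarianceDecomposition:
    def test_published_variance_share(self):
        dec = variance_decomposition({"species": 0.154, "residual": 0.558})
        assert dec.shares["species"] == pytest.approx(
            0.154**2 / (0.154**2 + 0.558**2), rel=1e-9
        )
        assert dec.shares["species"] == pytest.approx(0.0708, abs=5e-4)
        assert not dec.droppable

    def test_negligible_terms_flagged_droppable(self):
        dec = variance_decomposition(
            {"species": 0.154, "mother_tree": 0.003, "genus": 0.0, "residual": 0.558}
        )
        assert set(dec.droppable) == {"mother_tree", "genus"}
        assert sum(dec.shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_nested_terms_with_no_true_variance_are_droppable_after_direct_fit(self):
        """Three-term dense fit on data with species-only variance screens out
        the mother-tree and genus terms at the 0.1% rule."""
        rng = np.random.default_rng(0)
        n_sp, per = 10, 18
        species = np.repeat(np.arange(n_sp), per)
        mother = np.repeat(np.arange(n_sp * 3), per // 3)[: species.size]
        genus = species % 2
        X = np.column_stack([np.ones(species.size), rng.normal(size=species.size)])
        y = (
            0.4
            + 0.2 * X[:, 1]
            + rng.normal(0, 0.3, n_sp)[species]
            + rng.normal(0, 0.5, species.size)
        )
        res = fit_lmm_direct(
            y, X, {"species": species, "mother_tree": mother, "genus": genus}
        )
        dec = variance_decomposition({**res["sigmas"], "residual": res["sigma_resid"]})
        assert "mother_tree" in dec.droppable
        assert "genus" in dec.droppable
        assert dec.shares["species"] > 0.05


class TestWindCovariateComparison:
    def test_identical_columns_tie(self, small_dataset):
        df = small_dataset.copy()
        df["mean_wind_ms"] = df["max_wind_ms"]
        aic_max, aic_mean, _ = compare_wind_covariates(df)
        assert abs(aic_max - aic_mean) < 1e-6

    def test_true_covariate_selected(self, study_config):
        """Data generated from max wind: AIC prefers max in most replicates."""
        wins = 0
        reps = 20
        for r in range(reps):
            cfg = dataclasses.replace(study_config, rng_seed=100 + r)
            df, _ = sd.generate_releases(cfg)
            _, _, selected = compare_wind_covariates(df)
            wins += selected == "max"
        assert wins >= int(0.9 * reps)


class TestPredictMedianDistance:
    @pytest.mark.parametrize(
        "iwl, wind, expected",
        [
            (0.0, 1.72, 1.618),  # wingless at mean max wind
            (44.60, 1.72, 6.83),  # highest-IWL species
        ],
    )
    def test_closed_form_values(self, table2_truth, iwl, wind, expected):
        assert predict_median_distance(table2_truth, iwl, wind) == pytest.approx(
            expected, abs=0.01
        )

    def test_null_parameters_give_one_metre(self):
        p = sd.ModelParameters(0, 0, 0, 0, 0, 1e-9)
        assert predict_median_distance(p, 17.0, 3.0) == pytest.approx(1.0)

    def test_increasing_in_iwl_at_published_estimates(self, table2_truth):
        for wind in (0.0, 1.72, 5.0, 10.0):
            vals = [predict_median_distance(table2_truth, a, wind) for a in (0, 1, 5, 20, 50)]
            assert np.all(np.diff(vals) > 0)

    def test_negative_inputs_rejected(self, table2_truth):
        with pytest.raises(DataError):
            predict_median_distance(table2_truth, -1.0, 1.0)
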