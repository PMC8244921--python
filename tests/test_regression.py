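import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import special

from tonegenes import regression
from tonegenes.regression import ModelSpec, build_design


class TestDesign:
    def test_intercept_always_included(self, study_like_dataset):
        X = build_design(study_like_dataset, ())
        assert list(X.columns) == ["intercept"]
        assert (X["intercept"] == 1.0).all()

    def test_macroarea_dummies_drop_africa(self, study_like_dataset):
        X = build_design(study_like_dataset, ("aspm_z", "macroarea"))
        assert "macroarea_Africa" not in X.columns
        dummy_cols = [c for c in X.columns if c.startswith("macroarea_")]
        assert len(dummy_cols) == study_like_dataset["macroarea"].nunique() - 1

    def test_interaction_term(self, study_like_dataset):
        X = build_design(study_like_dataset, ("aspm_z", "mcph1_z", "aspm_z:mcph1_z"))
        prod = X["aspm_z"] * X["mcph1_z"]
        assert np.allclose(X["aspm_z:mcph1_z"], prod)

    def test_unknown_family_errors(self):
        with pytest.raises(ValueError, match="unknown family"):
            ModelSpec("tone1", "gamma")


class TestBoundaryAdjust:
    def test_pulls_boundaries_inside(self):
        out = regression.beta_boundary_adjust([0.0, 0.5, 1.0])
        assert out[0] == pytest.approx(1e-7)
        assert out[1] == 0.5
        assert out[2] == pytest.approx(1 - 1e-7)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            regression.beta_boundary_adjust([1.2])


class TestFitGLM:
    def test_binomial_intercept_only_mle(self, study_like_dataset):
        fit = regression.fit_glm(ModelSpec("tone1", "binomial"), study_like_dataset)
        p_hat = (study_like_dataset["tone1"] == "Yes").mean()
        assert fit.params["intercept"] == pytest.approx(special.logit(p_hat), abs=1e-6)

    def test_poisson_intercept_only_mle(self, study_like_dataset):
        fit = regression.fit_glm(ModelSpec("count", "poisson"), study_like_dataset)
        assert fit.params["intercept"] == pytest.approx(
            np.log(study_like_dataset["count"].mean()), abs=1e-6)

    def test_aic_identity(self, study_like_dataset):
        fit = regression.fit_glm(
            ModelSpec("tone1", "binomial", ("aspm_z", "mcph1_z")), study_like_dataset)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
        assert fit.k == 3

    def test_beta_regression_recovers_parameters(self, rng):
        n = 4000
        x = rng.normal(size=n)
        mu = special.expit(0.5 - 0.8 * x)
        phi = 40.0
        y = rng.beta(mu * phi, (1 - mu) * phi)
        table = pd.DataFrame({"freq": y, "x": x})
        fit = regression.fit_glm(ModelSpec("freq", "beta", ("x",)), table)
        assert fit.params["intercept"] == pytest.approx(0.5, abs=0.05)
        assert fit.params["x"] == pytest.approx(-0.8, abs=0.05)
        assert fit.phi == pytest.approx(40.0, rel=0.15)

    def test_beta_handles_boundary_values(self):
        table = pd.DataFrame({"freq": [0.0, 0.2, 0.5, 0.9, 1.0, 0.4, 0.6]})
        fit = regression.fit_glm(ModelSpec("freq", "beta"), table)
        assert np.isfinite(fit.loglik)

    def test_mixed_spec_rejected(self, study_like_dataset):
        with pytest.raises(ValueError, match="random intercept"):
            regression.fit_glm(ModelSpec("tone1", "binomial", (), "family"),
                               study_like_dataset)

    def test_wald_ci_contains_estimate(self, study_like_dataset):
        fit = regression.fit_glm(ModelSpec("tone1", "binomial", ("aspm_z",)),
                                 study_like_dataset)
        lo, hi = fit.wald_ci("aspm_z")
        assert lo < fit.params["aspm_z"] < hi


class TestFitMixed:
    def test_sigma_zero_recovers_glm(self, study_like_dataset):
        spec = ModelSpec("tone1", "binomial", ("aspm_z",), "family")
        mixed = regression.fit_mixed(spec, study_like_dataset, sigma2_fixed=0.0)
        glm = regression.fit_glm(ModelSpec("tone1", "binomial", ("aspm_z",)),
                                 study_like_dataset)
        assert mixed.loglik == pytest.approx(glm.loglik, abs=1e-6)
        assert mixed.params["aspm_z"] == pytest.approx(glm.params["aspm_z"], abs=1e-4)

    def test_quadrature_order_stability(self, study_like_dataset):
        spec = ModelSpec("tone1", "binomial", ("aspm_z",), "family")
        f9 = regression.fit_mixed(spec, study_like_dataset, n_quad=9)
        f15 = regression.fit_mixed(spec, study_like_dataset, n_quad=15)
        assert f9.loglik == pytest.approx(f15.loglik, abs=1e-3)
        assert f9.params["aspm_z"] == pytest.approx(f15.params["aspm_z"], abs=1e-3)

    def test_against_lme4_oracle(self, study_like_dataset, tmp_path):
        """Independent oracle: lme4::glmer with 15-node adaptive quadrature."""
        tsv = tmp_path / "d.tsv"
        study_like_dataset.to_csv(tsv, sep="\t", index=False)
        script = tmp_path / "oracle.R"
        script.write_text(f"""
            suppressMessages(library(lme4))
            d <- read.delim("{tsv}")
            d$y <- as.integer(d$tone1 == "Yes")
            m <- glmer(y ~ aspm_z + (1 | family), data = d, family = binomial, nAGQ = 15)
            cat(fixef(m), as.numeric(unlist(VarCorr(m))), as.numeric(logLik(m)), sep = "\\n")
        """)
        proc = subprocess.run(["Rscript", "--vanilla", str(script)],
                              capture_output=True, text=True, check=True)
        b0, b1, s2, ll = map(float, proc.stdout.strip().splitlines())

        spec = ModelSpec("tone1", "binomial", ("aspm_z",), "family")
        fit = regression.fit_mixed(spec, study_like_dataset, n_quad=15)
        assert fit.params["intercept"] == pytest.approx(b0, abs=1e-3)
        assert fit.params["aspm_z"] == pytest.approx(b1, abs=1e-3)
        assert fit.sigma2_family == pytest.approx(s2, abs=5e-3)
        assert fit.loglik == pytest.approx(ll, abs=1e-3)

    def test_poisson_mixed_runs(self, study_like_dataset):
        spec = ModelSpec("count", "poisson", ("aspm_z",), "family")
        fit = regression.fit_mixed(spec, study_like_dataset, n_quad=9)
        assert fit.converged
        assert fit.sigma2_family > 0
        assert np.isfinite(fit.se["aspm_z"])

    def test_effect_recovery_large_sample(self, large_dataset):
        spec = ModelSpec("tone1", "binomial", ("aspm_z",), "family")
        fit = regression.fit_mixed(spec, large_dataset, n_quad=9)
        # 200 families with a generating coefficient of -1: the estimate
        # should land well away from 0 and near the truth
        assert -1.6 < fit.params["aspm_z"] < -0.4


class TestVarianceDecompositions:
    def _null_fit(self, sigma2, family="binomial", intercept=0.0, phi=None):
        spec = ModelSpec("y", family, (), "family")
        return regression.FitResult(
            params=pd.Series({"intercept": intercept}),
            se=pd.Series({"intercept": 0.1}), pvalues=pd.Series({"intercept": 0.5}),
            loglik=-10.0, aic=24.0, n=100, k=2, family=family,
            sigma2_family=sigma2, phi=phi, spec=spec,
            fixed_linpred=np.full(100, intercept))

    def test_icc_binomial_analytic(self):
        s2 = np.pi ** 2 / 3
        assert regression.adjusted_icc(self._null_fit(s2)) == pytest.approx(0.5)

    def test_icc_poisson_analytic(self):
        fit = self._null_fit(1.0, family="poisson", intercept=0.0)
        assert regression.adjusted_icc(fit) == pytest.approx(1.0 / (1.0 + np.log(2.0)))

    def test_icc_beta_analytic(self):
        fit = self._null_fit(1.0, family="beta", intercept=0.0, phi=10.0)
        resid = 2 * special.polygamma(1, 5.0)
        assert regression.adjusted_icc(fit) == pytest.approx(1.0 / (1.0 + resid))

    def test_icc_requires_null_mixed_model(self, study_like_dataset):
        glm = regression.fit_glm(ModelSpec("tone1", "binomial"), study_like_dataset)
        with pytest.raises(ValueError, match="mixed"):
            regression.adjusted_icc(glm)
        spec = ModelSpec("tone1", "binomial", ("aspm_z",), "family")
        fit = regression.fit_mixed(spec, study_like_dataset, n_quad=5)
        with pytest.raises(ValueError, match="null model"):
            regression.adjusted_icc(fit)

    def test_icc_on_generated_data_near_target(self, large_dataset):
        # the generator's tone_family_sd is calibrated for a latent ICC ~ 0.7
        spec = ModelSpec("tone1", "binomial", (), "family")
        fit = regression.fit_mixed(spec, large_dataset, n_quad=9)
        assert 0.5 < regression.adjusted_icc(fit) < 0.9

    def test_marginal_r2_null_is_zero(self, study_like_dataset):
        spec = ModelSpec("tone1", "binomial", (), "family")
        fit = regression.fit_mixed(spec, study_like_dataset, n_quad=5)
        assert regression.marginal_r2(fit) == 0.0

    def test_marginal_r2_in_unit_interval(self, study_like_dataset):
        spec = ModelSpec("tone1", "binomial", ("aspm_z", "mcph1_z"), "family")
        fit = regression.fit_mixed(spec, study_like_dataset, n_quad=5)
        assert 0.0 < regression.marginal_r2(fit) < 1.0


class TestModelComparison:
    def test_lrt_basic(self, study_like_dataset):
        full = regression.fit_glm(ModelSpec("tone1", "binomial", ("aspm_z",)),
                                  study_like_dataset)
        reduced = regression.fit_glm(ModelSpec("tone1", "binomial"), study_like_dataset)
        out = regression.lrt_compare(full, reduced)
        assert out["df"] == 1
        assert out["chi2"] >= 0
        assert out["delta_aic"] == pytest.approx(full.aic - reduced.aic)

    def test_lrt_errors(self, study_like_dataset):
        full = regression.fit_glm(ModelSpec("tone1", "binomial", ("aspm_z",)),
                                  study_like_dataset)
        reduced = regression.fit_glm(ModelSpec("tone1", "binomial"), study_like_dataset)
        with pytest.raises(ValueError, match="fewer parameters"):
            regression.lrt_compare(reduced, full)
        smaller = regression.fit_glm(ModelSpec("tone1", "binomial"),
                                     study_like_dataset.iloc[:50])
        with pytest.raises(ValueError, match="different data"):
            regression.lrt_compare(full, smaller)


class TestPower:
    def test_power_smoke_fixed_effects(self, study_like_dataset, rng):
        spec = ModelSpec("tone1", "binomial", ("aspm_z",))
        params = pd.Series({"intercept": -0.5, "aspm_z": -2.0})
        out = regression.power_by_simulation(spec, study_like_dataset, params,
                                             sigma2_family=0.0, effect_name="aspm_z",
                                             n_sims=40, rng=rng)
        assert out["power"] > 0.8  # a huge fixed effect is essentially always seen
        assert 0 <= out["ci95"][0] <= out["power"] <= out["ci95"][1] <= 1

    def test_unsupported_family_errors(self, study_like_dataset, rng):
        spec = ModelSpec("aspm_freq", "beta", ("mcph1_z",))
        with pytest.raises(ValueError, match="binomial and poisson"):
            regression.power_by_simulation(spec, study_like_dataset,
                                           pd.Series({"intercept": 0.0}), 0.0,
                                           "mcph1_z", n_sims=2, rng=rng)
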