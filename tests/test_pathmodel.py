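import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from tonegenes import pathmodel
from tonegenes.pathmodel import PathSpec, fit_indices, fit_path


def path_system(n, rng, a1=-0.8, a2=-0.5, b1=-0.6, b2=0.0, cp=0.4,
                binary_dv=False, mediator_res_cov=0.0):
    """Data generated exactly from the recursive two-mediator model."""
    t = rng.normal(size=n)
    cov = np.array([[1.0, mediator_res_cov], [mediator_res_cov, 1.0]])
    e12 = rng.multivariate_normal([0, 0], cov, size=n)
    m1 = a1 * t + e12[:, 0]
    m2 = a2 * t + e12[:, 1]
    y = cp * t + b1 * m1 + b2 * m2 + rng.normal(size=n)
    if binary_dv:
        y = np.where(y > np.median(y), "Yes", "No")
    return pd.DataFrame({"africa": t, "aspm_z": m1, "mcph1_z": m2, "tone1": y})


SPEC = PathSpec()


class TestSpec:
    def test_columns_must_be_distinct(self):
        with pytest.raises(ValueError, match="distinct"):
            PathSpec(iv="africa", mv1="africa").columns()


class TestFitPath:
    def test_paths_match_ols_oracle(self, rng):
        table = path_system(500, rng)
        fit = fit_path(SPEC, table)
        # oracle: the standardized slopes from independent least-squares fits
        d = table[["africa", "aspm_z", "mcph1_z", "tone1"]].to_numpy(dtype=float)
        sds = d.std(axis=0, ddof=1)
        X1 = np.column_stack([np.ones(len(d)), d[:, 0]])
        a1 = np.linalg.lstsq(X1, d[:, 1], rcond=None)[0][1]
        a2 = np.linalg.lstsq(X1, d[:, 2], rcond=None)[0][1]
        X3 = np.column_stack([np.ones(len(d)), d[:, 0], d[:, 1], d[:, 2]])
        cp, b1, b2 = np.linalg.lstsq(X3, d[:, 3], rcond=None)[0][1:]
        assert fit.paths["a1"] == pytest.approx(a1 * sds[0] / sds[1], abs=1e-6)
        assert fit.paths["a2"] == pytest.approx(a2 * sds[0] / sds[2], abs=1e-6)
        assert fit.paths["b1"] == pytest.approx(b1 * sds[1] / sds[3], abs=1e-6)
        assert fit.paths["b2"] == pytest.approx(b2 * sds[2] / sds[3], abs=1e-6)
        assert fit.paths["c_prime"] == pytest.approx(cp * sds[0] / sds[3], abs=1e-6)

    def test_chi2_matches_brute_force_sem_oracle(self, rng):
        """Independent oracle: minimize the ML discrepancy numerically."""
        table = path_system(300, rng, mediator_res_cov=0.3)  # misspecified on purpose
        fit = fit_path(SPEC, table)

        d = table.to_numpy(dtype=float)
        n = len(d)
        S_ml = np.cov(d, rowvar=False, ddof=1) * (n - 1) / n
        var_iv = d[:, 0].var(ddof=0)

        def implied(theta):
            a1, a2, b1, b2, cp, p1, p2, p3 = theta
            B = np.array([[0, 0, 0, 0], [a1, 0, 0, 0], [a2, 0, 0, 0],
                          [cp, b1, b2, 0]], dtype=float)
            inv = np.linalg.inv(np.eye(4) - B)
            return inv @ np.diag([var_iv, p1, p2, p3]) @ inv.T

        def discrepancy(theta):
            sigma = implied(theta)
            sign, ld = np.linalg.slogdet(sigma)
            if sign <= 0:
                return 1e6
            return ld - np.linalg.slogdet(S_ml)[1] + np.trace(
                S_ml @ np.linalg.inv(sigma)) - 4

        x0 = np.array([0, 0, 0, 0, 0, 1, 1, 1], dtype=float)
        rough = optimize.minimize(discrepancy, x0, method="Nelder-Mead",
                                  options={"maxiter": 20000})
        best = optimize.minimize(discrepancy, rough.x, method="BFGS",
                                 options={"gtol": 1e-12})
        assert fit.chi2 == pytest.approx((n - 1) * best.fun, abs=1e-3)

    def test_null_dv_paths_centred_at_zero(self):
        rng = np.random.default_rng(99)
        estimates = []
        for _ in range(40):
            table = path_system(400, rng, b1=0.0, b2=0.0, cp=0.0)
            fit = fit_path(SPEC, table)
            estimates.append(fit.paths[["b1", "b2", "c_prime"]].to_numpy())
        means = np.mean(estimates, axis=0)
        assert np.all(np.abs(means) < 0.03)

    def test_chi2_invariant_to_rescaling(self, rng):
        table = path_system(300, rng)
        fit = fit_path(SPEC, table)
        scaled = table.copy()
        scaled["aspm_z"] = scaled["aspm_z"] * 13.7
        scaled["tone1"] = scaled["tone1"] * 0.01
        refit = fit_path(SPEC, scaled)
        assert refit.chi2 == pytest.approx(fit.chi2, abs=1e-8)
        # standardized paths are scale-free too
        assert np.allclose(refit.paths, fit.paths, atol=1e-10)

    def test_df_one_and_indices_bounded(self, rng):
        fit = fit_path(SPEC, path_system(250, rng, binary_dv=True))
        assert fit.df == 1
        assert 0.0 <= fit.cfi <= 1.0
        assert fit.tli == fit.nnfi

    def test_saturated_variant(self, rng):
        fit = fit_path(SPEC, path_system(250, rng), free_mediator_covariance=True)
        assert fit.chi2 == 0.0 and fit.df == 0 and fit.p == 1.0
        assert np.isnan(fit.cfi) and np.isnan(fit.tli)

    def test_singular_covariance_errors(self):
        table = pd.DataFrame({"africa": [1.0] * 20, "aspm_z": np.arange(20.0),
                              "mcph1_z": np.arange(20.0) * 2,
                              "tone1": np.ones(20)})
        with pytest.raises(np.linalg.LinAlgError):
            fit_path(SPEC, table)


class TestFitIndices:
    def test_exact_fit_gives_cfi_one(self):
        cfi, tli, nnfi, rfi = fit_indices(1.0, 1, 50.0, 6)
        assert cfi == 1.0
        assert tli == nnfi

    def test_baseline_equals_model_gives_cfi_zero(self):
        cfi, *_ = fit_indices(20.0, 6, 20.0, 6)
        assert cfi == 0.0

    def test_zero_df_errors(self):
        with pytest.raises(ValueError, match="zero degrees of freedom"):
            fit_indices(0.0, 0, 10.0, 6)

    def test_formulas(self):
        chi2, df, b_chi2, b_df = 3.0, 1, 60.0, 6
        cfi, tli, nnfi, rfi = fit_indices(chi2, df, b_chi2, b_df)
        assert cfi == pytest.approx(1 - 2.0 / 54.0)
        assert tli == pytest.approx((10.0 - 3.0) / (10.0 - 1.0))
        assert rfi == pytest.approx(1 - 3.0 / 10.0)


class TestChi2Calibration:
    def test_rejection_rate_near_alpha(self):
        """Data from the df=1 model: the chi-square test rejects ~5%."""
        rng = np.random.default_rng(314)
        n_rep = 300
        rejections = sum(
            fit_path(SPEC, path_system(300, rng)).p < 0.05 for _ in range(n_rep))
        rate = rejections / n_rep
        assert 0.01 <= rate <= 0.10

    def test_power_against_correlated_residuals(self):
        rng = np.random.default_rng(555)
        fit = fit_path(SPEC, path_system(2000, rng, mediator_res_cov=0.5))
        assert fit.p < 0.001  # strong violation is detected


class TestRestrictedPath:
    def test_summary_structure(self, study_like_dataset):
        out = pathmodel.restricted_path(study_like_dataset, PathSpec(),
                                        n_resamples=15,
                                        rng=np.random.default_rng(8))
        fit_block = out[out["block"] == "fit"]
        path_block = out[out["block"] == "path"]
        assert list(fit_block["estimate"]) == ["chi2_ns", "CFI", "TLI", "NNFI", "RFI"]
        assert list(path_block["estimate"]) == ["c_prime", "a1", "b1", "a2", "b2"]
        assert out.attrs["n_fits"] + out.attrs["n_failures"] == 15
        assert path_block["pct_expected_direction"].between(0, 100).all()

    def test_needs_multiple_families(self, study_like_dataset):
        one = study_like_dataset[study_like_dataset["family"] == "F000"]
        with pytest.raises(ValueError, match=">= 2 families"):
            pathmodel.restricted_path(one, PathSpec(), 2)
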