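"""One-hot design matrix, per-protein OLS, coefficient tests and contrasts."""

import numpy as np
import pandas as pd
import pytest

from dimerscope.design import FACTORS, generate_design
from dimerscope.errors import ConfigurationError, DataError
from dimerscope.io_filter import collapse_technical_replicates, log2_transform, \
    from_dataframe
from dimerscope.regression import (CONTRAST_PRESETS, build_design_matrix,
                                   coefficient_tests, contrast, fit_ols,
                                   measured_vs_predicted, predict_log_lfq)
from dimerscope.synthetic import GroundTruth, simulate_lfq
from dimerscope.matrix import IntensityMatrix

import oracles
from conftest import make_matrix, make_toy_design


class TestBuildDesignMatrix:
    def test_control_row_is_intercept_only(self):
        design = generate_design(1, 1)
        X = build_design_matrix(design)
        row = X.loc["frbfkbp_ac_b1_t1"]
        # the FRB+FKBP control received the dimerizer drug
        assert tuple(row) == (1, 0, 0, 1, 0, 0)

    def test_braf_sor_ac_row(self):
        design = generate_design(1, 1)
        X = build_design_matrix(design)
        assert tuple(X.loc["braf_s_ac_b1_t1"]) == (1, 1, 0, 1, 1, 0)

    def test_full_design_has_rank_six(self):
        X = build_design_matrix(generate_design(3, 2))
        # independent rank check via SVD of the raw array
        s = np.linalg.svd(X.to_numpy(), compute_uv=False)
        assert (s > 1e-8).sum() == 6

    def test_constant_factor_raises_named_error(self):
        design = generate_design(1, 1)
        design = design[design["sorafenib"] == 0].reset_index(drop=True)
        design = design[design["vemurafenib"] == 0].reset_index(drop=True)
        with pytest.raises(ConfigurationError, match="sorafenib|vemurafenib"):
            build_design_matrix(design)


def _noise_free_dataset(n=15, seed=0):
    design = generate_design(2, 1)
    rng = np.random.default_rng(seed)
    truth = GroundTruth(
        [f"P{i}" for i in range(n)], rng.normal(26, 2, n),
        rng.normal(0, 1.5, (n, len(FACTORS))),
        sigma_bio=0.0, sigma_tech=0.0,
        censor_midpoint=-1000.0, censor_slope=0.0,
        n_contaminant=0, n_reverse=0, n_onlysite=0,
    )
    ds = simulate_lfq(design, truth, seed=seed)
    matrix = log2_transform(from_dataframe(ds.table), design)
    return matrix, truth


class TestFitOLS:
    def test_noise_free_recovers_truth_exactly(self):
        matrix, truth = _noise_free_dataset()
        fit = fit_ols(matrix, build_design_matrix(matrix.design))
        np.testing.assert_allclose(fit.beta["intercept"], truth.baseline,
                                   atol=1e-8)
        np.testing.assert_allclose(fit.beta[list(FACTORS)].to_numpy(),
                                   truth.beta, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n, p = int(rng.integers(8, 20)), 3
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            y = rng.normal(size=n)
            design = make_toy_design({"A": n})
            Xdf = pd.DataFrame(X, index=design["run_id"],
                               columns=["intercept", "x1", "x2"])
            m = make_matrix(y[None, :], {"A": n})
            fit = fit_ols(m, Xdf)
            beta_o, se_o, sigma2_o, _ = oracles.ols_normal_equations(X, y)
            np.testing.assert_allclose(fit.beta.iloc[0].to_numpy(), beta_o,
                                       atol=1e-8)
            np.testing.assert_allclose(fit.se.iloc[0].to_numpy(), se_o,
                                       atol=1e-8)
            assert fit.sigma2.iloc[0] == pytest.approx(sigma2_o, abs=1e-8)

    def test_df_resid_and_r2_bounds(self, filtered_matrix):
        from dimerscope.imputation import impute_lognormal
        m = impute_lognormal(filtered_matrix, seed=0)
        fit = fit_ols(m, build_design_matrix(m.design))
        assert fit.df_resid == len(m.run_ids) - 6
        assert ((fit.r2 >= 0) & (fit.r2 <= 1)).all()

    def test_incomplete_matrix_rejected(self):
        vals = np.array([[20.0, np.nan, 21.0, 22.0]])
        m = make_matrix(vals, {"A": 4})
        X = pd.DataFrame({"intercept": np.ones(4)}, index=m.run_ids)
        with pytest.raises(DataError):
            fit_ols(m, X)

    def test_bias_shrinks_with_replication(self):
        """Mean absolute coefficient bias decreases as n_bio grows."""
        rng = np.random.default_rng(10)
        n = 40
        biases = []
        for n_bio in (3, 10, 30):
            design = generate_design(n_bio, 2)
            truth = GroundTruth(
                [f"P{i}" for i in range(n)], rng.normal(26, 2, n),
                np.tile(np.array([1.5, -1.0, 0.5, 2.0, -0.5]), (n, 1)),
                censor_midpoint=-1000.0,
                n_contaminant=0, n_reverse=0, n_onlysite=0,
            )
            ds = simulate_lfq(design, truth, seed=int(rng.integers(2**31)))
            m = collapse_technical_replicates(
                log2_transform(from_dataframe(ds.table), design))
            fit = fit_ols(m, build_design_matrix(m.design))
            bias = np.abs(fit.beta[list(FACTORS)].to_numpy() - truth.beta).mean()
            biases.append(bias)
        assert biases[2] < biases[0]


class TestCoefficientTests:
    def test_zero_estimate_gives_p_one(self):
        # y = 20 + x + e with e orthogonal to intercept, x and z, so the z
        # coefficient is exactly 0 while residual variance stays positive
        vals = np.array([[21.0, 19.0, 20.0, 22.0, 19.0, 21.0, 22.0, 20.0]])
        design = make_toy_design({"A": 8})
        X = pd.DataFrame(
            {"intercept": np.ones(8), "x": [0, 0, 1, 1, 0, 0, 1, 1],
             "z": [0, 1, 0, 1, 0, 1, 0, 1]},
            index=design["run_id"])
        m = make_matrix(vals, {"A": 8})
        fit = fit_ols(m, X)
        tests = coefficient_tests(fit)
        z_row = tests[tests["coefficient"] == "z"].iloc[0]
        assert z_row["estimate"] == pytest.approx(0.0, abs=1e-12)
        assert z_row["t_stat"] == pytest.approx(0.0, abs=1e-9)
        assert z_row["p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_p_matches_tail_oracle(self):
        rng = np.random.default_rng(6)
        n = 12
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        design = make_toy_design({"A": n})
        Xdf = pd.DataFrame(X, index=design["run_id"],
                           columns=["intercept", "x1", "x2"])
        m = make_matrix(rng.normal(size=(20, n)), {"A": n})
        fit = fit_ols(m, Xdf)
        tests = coefficient_tests(fit)
        for _, row in tests.iterrows():
            expected = oracles.t_two_sided(row["t_stat"], fit.df_resid)
            assert row["p_value"] == pytest.approx(expected, abs=1e-10)

    def test_q_adjusted_within_coefficient(self):
        matrix, _ = _noise_free_dataset(n=10, seed=2)
        rng = np.random.default_rng(0)
        noisy = matrix.values + rng.normal(0, 0.3, matrix.values.shape)
        m = IntensityMatrix(noisy, matrix.design)
        fit = fit_ols(m, build_design_matrix(m.design))
        tests = coefficient_tests(fit)
        for coef, grp in tests.groupby("coefficient"):
            np.testing.assert_allclose(
                grp["q_value"].to_numpy(),
                oracles.bh_stepup(grp["p_value"].to_numpy()), atol=1e-12)


class TestContrast:
    def _fit(self, seed=0, n=25):
        design = generate_design(2, 1)
        rng = np.random.default_rng(seed)
        vals = rng.normal(24, 1, (n, len(design)))
        m = IntensityMatrix(
            pd.DataFrame(vals, index=[f"P{i}" for i in range(n)],
                         columns=design["run_id"]), design)
        return fit_ols(m, build_design_matrix(m.design))

    def test_equal_true_effects_give_zero_contrast(self):
        design = generate_design(2, 1)
        n = 8
        rng = np.random.default_rng(1)
        beta = np.zeros((n, len(FACTORS)))
        beta[:, 0] = 1.7   # brafwt
        beta[:, 1] = 1.7   # v600e: identical effect
        truth = GroundTruth([f"P{i}" for i in range(n)], rng.normal(26, 2, n),
                            beta, sigma_bio=0.0, sigma_tech=0.0,
                            censor_midpoint=-1000.0, censor_slope=0.0,
                            n_contaminant=0, n_reverse=0, n_onlysite=0)
        ds = simulate_lfq(design, truth, seed=1)
        m = log2_transform(from_dataframe(ds.table), design)
        fit = fit_ols(m, build_design_matrix(m.design))
        res = contrast(fit, "v600e_minus_brafwt")
        np.testing.assert_allclose(res["estimate"], 0.0, atol=1e-8)

    def test_elementary_vector_reduces_to_coefficient_test(self):
        fit = self._fit()
        c = np.array([0.0, 0.0, 0.0, 1.0, 0.0, 0.0])  # dimerizer column
        res = contrast(fit, c)
        tests = coefficient_tests(fit)
        dim = tests[tests["coefficient"] == "dimerizer"].set_index("protein")
        np.testing.assert_allclose(res["estimate"],
                                   dim.loc[res.index, "estimate"], atol=1e-12)
        np.testing.assert_allclose(res["p_value"],
                                   dim.loc[res.index, "p_value"], atol=1e-12)

    def test_matches_quadratic_form_oracle(self):
        fit = self._fit(seed=3)
        rng = np.random.default_rng(5)
        for _ in range(30):
            c = rng.normal(size=6)
            res = contrast(fit, c)
            for pid in fit.protein_ids[:5]:
                cov = fit.cov(pid).to_numpy()
                est = float(c @ fit.beta.loc[pid].to_numpy())
                se = float(np.sqrt(c @ cov @ c))
                assert res.loc[pid, "estimate"] == pytest.approx(est, abs=1e-10)
                assert res.loc[pid, "se"] == pytest.approx(se, abs=1e-10)

    def test_sign_convention(self):
        fit = self._fit(seed=8)
        res = contrast(fit, "sorafenib_minus_vemurafenib")
        manual = fit.beta["sorafenib"] - fit.beta["vemurafenib"]
        np.testing.assert_array_equal(res["sign"].to_numpy(),
                                      np.sign(manual).astype(int))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ConfigurationError):
            contrast(self._fit(), np.ones(4))

    def test_unknown_preset_raises(self):
        with pytest.raises(ConfigurationError):
            contrast(self._fit(), "not_a_preset")


class TestPrediction:
    def test_noise_free_predictions_equal_measurements(self):
        matrix, _ = _noise_free_dataset(n=8, seed=5)
        fit = fit_ols(matrix, build_design_matrix(matrix.design))
        pred = predict_log_lfq(fit)
        np.testing.assert_allclose(pred.to_numpy(), matrix.values.to_numpy(),
                                   atol=1e-8)

    def test_residuals_sum_to_zero_per_protein(self):
        rng = np.random.default_rng(9)
        design = generate_design(2, 1)
        vals = rng.normal(24, 1, (12, len(design)))
        m = IntensityMatrix(
            pd.DataFrame(vals, index=[f"P{i}" for i in range(12)],
                         columns=design["run_id"]), design)
        fit = fit_ols(m, build_design_matrix(m.design))
        resid = m.values.to_numpy() - predict_log_lfq(fit).to_numpy()
        np.testing.assert_allclose(resid.sum(axis=1), 0.0, atol=1e-8)

    def test_measured_vs_predicted_long_table(self, filtered_matrix):
        from dimerscope.imputation import impute_lognormal
        m = impute_lognormal(filtered_matrix, seed=1)
        fit = fit_ols(m, build_design_matrix(m.design))
        long = measured_vs_predicted(m, fit)
        assert set(long.columns) == {"protein", "run_id", "measured",
                                     "predicted", "condition_label"}
        assert len(long) == m.values.size


class TestCoverage:
    def test_ci_coverage_near_nominal(self):
        """95% intervals cover true coefficients at ~0.95 on uncensored data."""
        from scipy import stats as sps
        design = generate_design(3, 2)
        rng = np.random.default_rng(12)
        n = 250
        truth = GroundTruth(
            [f"P{i}" for i in range(n)], rng.normal(26, 2, n),
            rng.uniform(1, 3, (n, len(FACTORS))) * rng.choice([0, 1], (n, len(FACTORS)), p=[0.8, 0.2]),
            censor_midpoint=-1000.0,
            n_contaminant=0, n_reverse=0, n_onlysite=0)
        ds = simulate_lfq(design, truth, seed=12)
        m = collapse_technical_replicates(
            log2_transform(from_dataframe(ds.table), design))
        fit = fit_ols(m, build_design_matrix(m.design))
        tcrit = sps.t.ppf(0.975, fit.df_resid)
        B = fit.beta[list(FACTORS)].to_numpy()
        SE = fit.se[list(FACTORS)].to_numpy()
        coverage = (np.abs(B - truth.beta) <= tcrit * SE).mean()
        assert coverage == pytest.approx(0.95, abs=0.02)
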