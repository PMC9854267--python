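"""Discontinuity estimator: weights, oracle equivalence, inference, sweep."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, norm

from rdd_gxe.rdd import (
    RDDSpec,
    bandwidth_sweep,
    conditional_effect,
    fit_gxe_rdd,
    fit_sharp_rdd,
    fit_stratified,
    linear_combination,
    post_cutoff_slope,
    sweep_summary,
    triangular_weights,
)
from rdd_gxe.synthetic import SyntheticConfig, generate_cohort


def _table(r, y, extra=None):
    df = pd.DataFrame({"r": r})
    df["T"] = (df["r"] >= 0).astype(int)
    df["cesd_w3"] = y
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


class TestWeights:
    def test_kernel_shape(self):
        w = triangular_weights(np.array([-10.0, -5.0, 0.0, 5.0, 10.0]), 0.0, 10.0)
        assert np.allclose(w, [0.0, 0.5, 1.0, 0.5, 0.0])

    def test_infinite_bandwidth_uniform(self):
        assert np.allclose(triangular_weights(np.arange(-50, 50), 0.0, None), 1.0)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            triangular_weights(np.arange(3), 0.0, 0.0)


class TestSharpFit:
    def test_noiseless_exact_interpolation(self, rng):
        r = rng.integers(-50, 51, 300)
        T = (r >= 0).astype(float)
        y = 1.0 + 2.0 * T + 0.1 * r - 0.05 * T * r
        fit = fit_sharp_rdd(_table(r, y), RDDSpec(bandwidth=50))
        expect = {"const": 1.0, "T": 2.0, "r": 0.1, "T:r": -0.05}
        for term, val in expect.items():
            assert fit.params[term] == pytest.approx(val, abs=1e-8)

    def test_normal_equations_oracle_eight_rows(self):
        """Coefficients equal the brute-force (X'WX)^-1 X'Wy solve."""
        r = np.array([-4, -3, -2, -1, 0, 1, 2, 3], dtype=float)
        y = np.array([3.0, 2.5, 4.0, 3.5, 6.0, 5.0, 5.5, 7.0])
        h = 5.0
        fit = fit_sharp_rdd(_table(r, y), RDDSpec(bandwidth=h))
        T = (r >= 0).astype(float)
        X = np.column_stack([np.ones(8), T, r, T * r])
        W = np.diag(1.0 - np.abs(r) / h)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        assert np.allclose(fit.params.values, beta, rtol=1e-10, atol=1e-10)

    def test_hc1_sandwich_oracle_small_fixture(self):
        """Robust covariance equals the element-wise hand-expanded sandwich."""
        r = np.array([-3, -2, -1, 0, 1, 2], dtype=float)
        y = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 9.0])
        h = 4.0
        fit = fit_sharp_rdd(_table(r, y), RDDSpec(bandwidth=h, robust="HC1"))
        T = (r >= 0).astype(float)
        X = np.column_stack([np.ones(6), T, r, T * r])
        w = 1.0 - np.abs(r) / h
        A = X.T @ (w[:, None] * X)
        beta = np.linalg.solve(A, X.T @ (w * y))
        e = y - X @ beta
        meat = sum(
            (w[i] * e[i]) ** 2 * np.outer(X[i], X[i]) for i in range(6)
        )
        cov = np.linalg.inv(A) @ meat @ np.linalg.inv(A) * 6 / (6 - 4)
        assert np.allclose(fit.cov.values, cov, rtol=1e-8, atol=1e-12)

    def test_uniform_hc0_equals_statsmodels_white(self, small_cohort):
        import statsmodels.api as sm

        fit = fit_sharp_rdd(small_cohort, RDDSpec(bandwidth=None, robust="HC0"))
        df = small_cohort
        X = pd.DataFrame(
            {
                "const": 1.0,
                "T": df["T"].astype(float),
                "r": df["r"].astype(float),
                "T:r": (df["T"] * df["r"]).astype(float),
            }
        )
        ols = sm.OLS(df["cesd_w3"].astype(float), X).fit(cov_type="HC0")
        assert np.allclose(fit.params.values, ols.params.values, atol=1e-10)
        assert np.allclose(fit.cov.values, ols.cov_params().values, atol=1e-10)

    def test_translation_equivariance_of_late(self, small_cohort):
        fit0 = fit_sharp_rdd(small_cohort, RDDSpec(bandwidth=30))
        shifted = small_cohort.copy()
        shifted["r"] = shifted["r"] + 17
        fit1 = fit_sharp_rdd(shifted, RDDSpec(bandwidth=30, cutoff=17))
        assert fit1.late == pytest.approx(fit0.late, abs=1e-10)

    def test_one_sided_window_rejected(self, small_cohort):
        right = small_cohort.loc[small_cohort["r"] >= 5]
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            fit_sharp_rdd(right, RDDSpec(bandwidth=50))

    def test_moderated_spec_routed_to_gxe(self, small_cohort):
        with pytest.raises(ValueError, match="fit_gxe_rdd"):
            fit_sharp_rdd(small_cohort, RDDSpec(moderator="varPGS_z"))


class TestGxEFit:
    def test_noiseless_exact_gxe_interpolation(self, rng):
        """Exact recovery of the full interaction set on noiseless data."""
        r = rng.integers(-30, 31, 200).astype(float)
        T = (r >= 0).astype(float)
        G = rng.integers(0, 2, 200).astype(float)
        y = (
            1.0 + 2.0 * T + 0.1 * r - 0.05 * T * r
            + 0.5 * G + 1.4 * T * G + 0.02 * r * G - 0.01 * T * r * G
        )
        t = _table(r, y, extra={"G": G})
        fit = fit_gxe_rdd(t, RDDSpec(bandwidth=30, moderator="G"))
        expect = {"const": 1.0, "T": 2.0, "r": 0.1, "T:r": -0.05,
                  "G": 0.5, "T:G": 1.4, "r:G": 0.02, "T:r:G": -0.01}
        for term, val in expect.items():
            assert fit.params[term] == pytest.approx(val, abs=1e-8)

    def test_noiseless_interaction_recovery(self):
        cfg = SyntheticConfig(
            n_subjects=800, date_range=(-50, 50), pre_fraction=0.5,
            noise_sd=0.0, alpha=8.0, tau=2.0, slope_pre=0.0, slope_post=0.0,
            beta_meanG=0.0, delta_varG=1.40, covariate_effects={},
            missing_rates={}, seed=6,
        )
        t = generate_cohort(cfg)
        fit = fit_gxe_rdd(
            t,
            RDDSpec(
                bandwidth=50, moderator="varPGS_z", moderator_coding="continuous"
            ),
        )
        # the discretized outcome rounds the latent mean, so recovery is
        # exact only up to the rounding grain
        assert fit.params["T:G"] == pytest.approx(1.40, abs=0.05)
        assert fit.params["T"] == pytest.approx(2.0, abs=0.05)

    def test_binary_moderator_equals_split_sample_oracle(self, small_cohort):
        """With a binary moderator and no shared covariates the interaction
        model reproduces the two separate per-group fits exactly."""
        t = small_cohort.copy()
        t["varPGS_group"] = np.where(t["varPGS_z"] <= t["varPGS_z"].median(), 0, 1)
        spec = RDDSpec(bandwidth=40, moderator="varPGS_group")
        full = fit_gxe_rdd(t, spec)
        parts = fit_stratified(t, spec)
        low, high = parts["low"], parts["high"]
        assert full.params["T"] == pytest.approx(low.params["T"], abs=1e-8)
        assert full.params["T:G"] == pytest.approx(
            high.params["T"] - low.params["T"], abs=1e-8
        )
        assert full.params["G"] == pytest.approx(
            high.params["const"] - low.params["const"], abs=1e-8
        )

    def test_null_interaction_type_i_error(self):
        """With delta = 0 the 5% test of the interaction rejects ~5%."""
        n_rep, rejections = 300, 0
        spec = RDDSpec(
            bandwidth=50, moderator="varPGS_z", moderator_coding="continuous"
        )
        for i in range(n_rep):
            cfg = SyntheticConfig(
                n_subjects=2318, date_range=(-50, 50), pre_fraction=0.5,
                delta_varG=0.0, beta_meanG=0.0, covariate_effects={},
                missing_rates={}, seed=20_000 + i,
            )
            fit = fit_gxe_rdd(generate_cohort(cfg), spec)
            rejections += fit.pvalues["T:G"] < 0.05
        lo, hi = binom.ppf([0.005, 0.995], n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_constant_moderator_rejected(self, small_cohort):
        t = small_cohort.copy()
        t["grp"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_gxe_rdd(t, RDDSpec(bandwidth=30, moderator="grp"))


class TestLinearCombination:
    @pytest.fixture()
    def stored_fit(self):
        terms = ["const", "T", "r", "T:r", "G", "T:G", "r:G", "T:r:G"]
        params = pd.Series(
            [4.5, 0.25, 0.01, -0.02, -0.1, 1.40, 0.0, 0.005], index=terms
        )
        rng = np.random.default_rng(3)
        L = rng.normal(size=(8, 8)) * 0.05
        cov = pd.DataFrame(L @ L.T, index=terms, columns=terms)
        from rdd_gxe.rdd import RDDFit

        return RDDFit(params=params, cov=cov, n_used=100, bandwidth=50,
                      spec=RDDSpec(moderator="G"))

    def test_unit_vector_reproduces_term(self, stored_fit):
        res = linear_combination(stored_fit, {"T": 1.0})
        assert res["estimate"] == pytest.approx(0.25)
        assert res["se"] == pytest.approx(np.sqrt(stored_fit.cov.loc["T", "T"]))

    def test_conditional_effect_delta_method_oracle(self, stored_fit):
        res = conditional_effect(stored_fit, g=-0.5)
        assert res["estimate"] == pytest.approx(0.25 - 0.70)
        c = np.array([0, 1, 0, 0, 0, -0.5, 0, 0], dtype=float)
        se = np.sqrt(c @ stored_fit.cov.values @ c)
        assert res["se"] == pytest.approx(se, abs=1e-12)

    def test_post_slope_contrast(self, stored_fit):
        res = post_cutoff_slope(stored_fit)
        assert res["estimate"] == pytest.approx(0.01 - 0.02)

    def test_zero_contrast(self, stored_fit):
        res = linear_combination(stored_fit, np.zeros(8))
        assert res["estimate"] == 0.0 and res["se"] == 0.0

    def test_dimension_mismatch_rejected(self, stored_fit):
        with pytest.raises(ValueError, match="length"):
            linear_combination(stored_fit, np.ones(3))
        with pytest.raises(ValueError, match="unknown"):
            linear_combination(stored_fit, {"nope": 1.0})


class TestSweep:
    def test_n_monotone_and_full_sample(self, small_cohort):
        fits = bandwidth_sweep(small_cohort, RDDSpec())
        ns = [fits[h].n_used for h in (10, 20, 30, 40, 50, None)]
        assert ns == sorted(ns)
        assert fits[None].n_used == len(small_cohort)

    def test_recovery_within_three_se_all_bandwidths(self):
        cfg = SyntheticConfig(
            n_subjects=6000, date_range=(-50, 50), pre_fraction=0.5,
            tau=0.89, slope_pre=0.0, slope_post=0.0, covariate_effects={},
            missing_rates={}, beta_meanG=0.0, delta_varG=0.0, seed=77,
        )
        t = generate_cohort(cfg)
        fits = bandwidth_sweep(t, RDDSpec())
        for h, fit in fits.items():
            assert abs(fit.late - 0.89) < 3 * fit.se["T"], f"bandwidth {h}"

    def test_failing_bandwidth_reported_not_fatal(self, small_cohort):
        narrow = small_cohort.loc[small_cohort["r"].abs() >= 3]
        fits = bandwidth_sweep(narrow, RDDSpec(), bandwidths=[1, 50])
        assert isinstance(fits[1], Exception)
        assert fits[50].n_used > 0
        summary = sweep_summary(fits)
        assert (summary.loc[summary["bandwidth"] == 1, "error"] != "").all()

    def test_shrinking_bandwidth_shrinks_curvature_bias(self):
        """Quadratic truth fitted linearly: |bias| falls as h falls."""
        rng = np.random.default_rng(5)
        r = rng.integers(-50, 51, 60_000)
        T = (r >= 0).astype(float)
        y = 2.0 + 1.0 * T + 0.002 * r**2 + rng.normal(0, 0.5, r.size)
        t = _table(r, y)
        biases = []
        for h in (50, 20, 10):
            fit = fit_sharp_rdd(t, RDDSpec(bandwidth=h))
            biases.append(abs(fit.late - 1.0))
        assert biases[0] > biases[1] > biases[2]


def test_coverage_of_late_nominal():
    """95% CI coverage of the discontinuity across seeded replicates."""
    n_rep, covered = 150, 0
    spec = RDDSpec(bandwidth=50)
    for i in range(n_rep):
        cfg = SyntheticConfig(
            n_subjects=2318, date_range=(-50, 50), pre_fraction=1098 / 2318,
            covariate_effects={}, missing_rates={}, beta_meanG=0.0,
            delta_varG=0.0, seed=40_000 + i,
        )
        fit = fit_sharp_rdd(generate_cohort(cfg), spec)
        lo, hi = fit.conf_int().loc["T"]
        covered += lo <= 0.89 <= hi
    assert binom.ppf(0.005, n_rep, 0.95) <= covered <= binom.ppf(0.995, n_rep, 0.95)
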