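"""Outcome transforms, quadratic specification, binned scatter, pipeline."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import rdd_gxe
from rdd_gxe.rdd import RDDSpec, fit_sharp_rdd
from rdd_gxe.sensitivity import binned_scatter, fit_quadratic_rdd, transform_outcome
from rdd_gxe.synthetic import SyntheticConfig


class TestTransform:
    def test_log1p_at_floor(self, small_cohort):
        t = small_cohort.copy()
        t.loc[t.index[0], "cesd_w3"] = 0.0
        out = transform_outcome(t, "log1p")
        assert out["cesd_w3"].iloc[0] == 0.0
        assert np.allclose(out["cesd_w3"], np.log1p(t["cesd_w3"]))

    def test_sqrt(self):
        df = pd.DataFrame({"cesd_w3": [0.0, 4.0, 9.0]})
        assert transform_outcome(df, "sqrt")["cesd_w3"].tolist() == [0.0, 2.0, 3.0]

    def test_identity_roundtrip(self, small_cohort):
        out = transform_outcome(small_cohort, "identity")
        pd.testing.assert_series_equal(
            out["cesd_w3"], small_cohort["cesd_w3"].astype(float)
        )

    def test_negative_outcome_rejected(self):
        df = pd.DataFrame({"cesd_w3": [-1.0, 2.0]})
        with pytest.raises(ValueError, match="nonnegative"):
            transform_outcome(df, "log1p")

    def test_unknown_mode_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="transform"):
            transform_outcome(small_cohort, "boxcox")


class TestQuadratic:
    def test_noiseless_quadratic_truth_recovered_exactly(self, rng):
        r = rng.integers(-40, 41, 400).astype(float)
        T = (r >= 0).astype(float)
        y = 2.0 + 1.5 * T + 0.1 * r - 0.02 * T * r + 0.003 * r**2 - 0.001 * T * r**2
        df = pd.DataFrame({"r": r, "T": T, "cesd_w3": y})
        fit = fit_quadratic_rdd(df, RDDSpec(bandwidth=40))
        expect = {"const": 2.0, "T": 1.5, "r": 0.1, "T:r": -0.02,
                  "r2": 0.003, "T:r2": -0.001}
        for term, val in expect.items():
            assert fit.params[term] == pytest.approx(val, abs=1e-8)

    def test_normal_equations_oracle(self, rng):
        r = np.arange(-5, 5).astype(float)
        y = rng.normal(size=10)
        df = pd.DataFrame({"r": r, "T": (r >= 0).astype(float), "cesd_w3": y})
        h = 6.0
        fit = fit_quadratic_rdd(df, RDDSpec(bandwidth=h))
        T = (r >= 0).astype(float)
        X = np.column_stack([np.ones(10), T, r, T * r, r**2, T * r**2])
        W = np.diag(np.maximum(0, 1 - np.abs(r) / h))
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        assert np.allclose(fit.params.values, beta, atol=1e-10)

    def test_zero_curvature_estimates_near_zero(self):
        from rdd_gxe.synthetic import generate_cohort

        hits = 0
        for i in range(30):
            cfg = SyntheticConfig(
                n_subjects=2000, date_range=(-50, 50), pre_fraction=0.5,
                covariate_effects={}, missing_rates={}, beta_meanG=0.0,
                delta_varG=0.0, seed=70_000 + i,
            )
            fit = fit_quadratic_rdd(generate_cohort(cfg), RDDSpec(bandwidth=50))
            for term in ("r2", "T:r2"):
                hits += abs(fit.params[term]) < 3 * fit.se[term]
        assert hits >= 0.9 * 60  # ~99% expected per term


class TestBinnedScatter:
    def test_equal_bins(self, rng):
        r = np.concatenate([np.arange(-50, 0), np.arange(0, 50)])
        df = pd.DataFrame({"r": r, "cesd_w3": rng.normal(size=100)})
        out = binned_scatter(df, bins_per_side=10)
        assert len(out) == 20
        assert (out["n"] == 5).all()
        assert out.groupby("side")["n"].sum().tolist() == [50, 50]

    def test_single_bin_gives_side_means(self, small_cohort):
        out = binned_scatter(small_cohort, bins_per_side=1)
        pre = small_cohort.loc[small_cohort["r"] < 0, "cesd_w3"]
        post = small_cohort.loc[small_cohort["r"] >= 0, "cesd_w3"]
        assert out.loc[out["side"] == "pre", "y_mean"].iloc[0] == pytest.approx(pre.mean())
        assert out.loc[out["side"] == "post", "y_mean"].iloc[0] == pytest.approx(post.mean())

    def test_bin_means_match_groupby_oracle(self, small_cohort):
        out = binned_scatter(small_cohort, bins_per_side=8)
        sub = small_cohort.loc[small_cohort["r"] < 0].sort_values(
            "r", kind="mergesort"
        )
        chunks = np.array_split(np.arange(len(sub)), 8)
        for b, idx in enumerate(chunks):
            expect = sub.iloc[idx]["cesd_w3"].mean()
            got = out.loc[(out["side"] == "pre") & (out["bin"] == b), "y_mean"].iloc[0]
            assert got == pytest.approx(expect)

    def test_target_count_mode(self, small_cohort):
        out = binned_scatter(small_cohort, target_count=117)
        pre_n = (small_cohort["r"] < 0).sum()
        assert (out.loc[out["side"] == "pre", "n"].sum()) == pre_n
        mean_count = out["n"].mean()
        assert 80 < mean_count < 170

    def test_too_many_bins_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="bins"):
            binned_scatter(small_cohort, bins_per_side=10**6)

    def test_exactly_one_mode_required(self, small_cohort):
        with pytest.raises(ValueError, match="exactly one"):
            binned_scatter(small_cohort)
        with pytest.raises(ValueError, match="exactly one"):
            binned_scatter(small_cohort, bins_per_side=5, target_count=100)


def _tiny_config(seed=17):
    cfg = rdd_gxe.default_config()
    cfg["seed"] = seed
    cfg["simulate"].update({"n_subjects": 900, "seed": seed})
    cfg["impute"].update({"m": 2, "iterations": 2})
    cfg["rdd"]["bandwidths"] = [30, None]
    cfg["validity"].update({"placebo_days": [-3, 3]})
    return cfg


class TestPipeline:
    def test_report_bundle_is_byte_identical_across_runs(self, tmp_path):
        cfg = _tiny_config()
        run_a = tmp_path / "a"
        run_b = tmp_path / "b"
        rdd_gxe.run_pipeline(cfg, run_a)
        rdd_gxe.run_pipeline(cfg, run_b)
        files = sorted(p.name for p in run_a.iterdir())
        assert files == sorted(p.name for p in run_b.iterdir())
        for name in files:
            assert (run_a / name).read_bytes() == (run_b / name).read_bytes(), name

    def test_pipeline_outputs_and_manifest(self, tmp_path):
        res = rdd_gxe.run_pipeline(_tiny_config(), tmp_path / "out")
        assert res["manifest"]["errors"] == {}
        for key in (
            "exclusions", "descriptives", "rdd_treatment", "rdd_gxe_meanPGS",
            "rdd_gxe_varPGS", "placebo_scan", "balance_tests", "power",
            "sensitivity", "binned_scatter",
        ):
            assert key in res, key
        sweep = res["rdd_treatment"]
        assert set(sweep["bandwidth"]) == {30, "all"}
        assert (tmp_path / "out" / "manifest.json").exists()

    def test_noiseless_pipeline_reproduces_generating_parameters(self, tmp_path):
        cfg = _tiny_config()
        cfg["simulate"].update(
            {
                "n_subjects": 800, "noise_sd": 0.0, "alpha": 8.0, "tau": 3.0,
                "slope_pre": 0.0, "slope_post": 0.0, "beta_meanG": 0.0,
                "delta_varG": 0.0, "covariate_effects": {}, "missing_rates": {},
                "pre_fraction": 0.5, "date_range": [-50, 50],
            }
        )
        cfg["impute"]["enabled"] = False
        cfg["rdd"]["covariates"] = []
        res = rdd_gxe.run_pipeline(cfg, tmp_path / "noiseless")
        sweep = res["rdd_treatment"]
        t_rows = sweep.loc[sweep["term"] == "T", "estimate"]
        assert np.allclose(t_rows, 3.0, atol=1e-8)

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = _tiny_config()
        path = tmp_path / "config.yaml"
        rdd_gxe.save_config(cfg, path)
        back = rdd_gxe.load_config(path)
        assert back == cfg

    def test_stage_failure_is_reported_not_fatal(self, tmp_path):
        cfg = _tiny_config()
        cfg["validity"]["placebo_days"] = [500, 505]  # outside data support
        res = rdd_gxe.run_pipeline(cfg, tmp_path / "broken")
        # scan runs but flags non-estimable days rather than failing
        scan = res["placebo_scan"]
        assert (~scan["estimable"]).all()
        assert res["manifest"]["n_analytical"] == 900
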