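"""End-to-end orchestration: score -> filter -> impute -> fit -> validate.

A single YAML/dict config drives the whole analysis.  Outputs are written
as CSV/JSON tables into an output directory and also returned in memory.
Given the same input, config and seed the report bundle is byte-identical
across runs.  Stage failures are caught, recorded in the manifest under
the stage name, and do not destroy the outputs of earlier stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from . import benchmarks as bm
from .impute import fit_mice, pooled_fit
from .pgs import dichotomize_median, standardize
from .phenotype import ITEM_COLUMNS, apply_exclusions, cronbach_alpha, score_cesd
from .rdd import DEFAULT_BANDWIDTHS, RDDSpec, bandwidth_sweep, sweep_summary
from .sensitivity import binned_scatter, fit_quadratic_rdd, transform_outcome
from .synthetic import SyntheticConfig, read_cohort, simulate_study_cohort
from .validity import balance_tests, placebo_scan, power_from_design

logger = logging.getLogger(__name__)

__all__ = ["default_config", "load_config", "save_config", "run_pipeline"]

CONTINUOUS_COVARIATES = (
    "cesd_w1", "age", "pvt", "family_income",
    "neuroticism", "extraversion", "conscientiousness",
)
MODEL_COVARIATES = CONTINUOUS_COVARIATES + ("sex", "mother_edu", "state")
PC_COLUMNS = tuple(f"pc{i}" for i in range(1, 11))


def default_config() -> dict:
    """Analysis defaults mirroring the emulated study design."""
    return {
        "seed": 0,
        "simulate": SyntheticConfig().to_dict(),  # or {"cohort_csv": path}
        "impute": {"enabled": True, "m": bm.N_IMPUTATIONS, "iterations": 5, "k_pmm": 5},
        "rdd": {
            "bandwidths": list(DEFAULT_BANDWIDTHS),
            "covariates": list(MODEL_COVARIATES),
            "robust": "HC1",
        },
        "gxe": {
            "moderators": {"meanPGS": "varPGS_z", "varPGS": "meanPGS_z"},
            "coding": "binary",
        },
        "validity": {
            "placebo_days": [-20, 20],
            "placebo_bandwidth": 20,
            "balance_bandwidth": 50,
            "power_tau": bm.TREATMENT_COEF_BY_BANDWIDTH[50],
            "power_bandwidth": 50,
        },
        "sensitivity": {"bandwidth": 50, "transforms": ["log1p", "sqrt"]},
        "report": {"binned_target_pre": 117, "binned_target_post": 159,
                   "figures": False},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def _stars(p: float) -> str:
    for cut, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "+")):
        if p < cut:
            return mark
    return ""


def _descriptives(table: pd.DataFrame) -> pd.DataFrame:
    """Group means/SDs with two-sample difference tests, tiered markers.

    Continuous variables use a Welch t-test; binary/categorical levels a
    two-proportion z-test.
    """
    from scipy.stats import ttest_ind

    pre = table.loc[table["T"] == 0]
    post = table.loc[table["T"] == 1]
    rows = []

    def add_cont(name, col):
        a = pre[col].dropna().astype(float)
        b = post[col].dropna().astype(float)
        p = ttest_ind(a, b, equal_var=False).pvalue if len(a) > 1 and len(b) > 1 else np.nan
        rows.append(
            {"variable": name, "pre_mean": a.mean(), "pre_sd": a.std(ddof=1),
             "post_mean": b.mean(), "post_sd": b.std(ddof=1),
             "p": p, "sig": _stars(p) if np.isfinite(p) else ""}
        )

    def add_prop(name, indicator):
        a = indicator[table["T"] == 0].dropna()
        b = indicator[table["T"] == 1].dropna()
        p1, p2 = a.mean(), b.mean()
        pool = pd.concat([a, b]).mean()
        se = np.sqrt(pool * (1 - pool) * (1 / len(a) + 1 / len(b)))
        z = (p1 - p2) / se if se > 0 else np.nan
        p = 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append(
            {"variable": name, "pre_mean": p1, "pre_sd": np.nan,
             "post_mean": p2, "post_sd": np.nan,
             "p": p, "sig": _stars(p) if np.isfinite(p) else ""}
        )

    add_cont("cesd_w3", "cesd_w3")
    add_cont("interview_day", "r")
    for grp_col in ("meanPGS_group", "varPGS_group"):
        if grp_col in table:
            add_prop(f"{grp_col}[high]", (table[grp_col] == "high").astype(float))
    add_cont("age", "age")
    add_prop("sex[male]", (table["sex"] == "male").astype(float))
    for lv in sorted(pd.unique(table["mother_edu"].dropna())):
        ind = table["mother_edu"].where(table["mother_edu"].notna())
        add_prop(f"mother_edu[{int(lv)}]", (ind == lv).astype(float).where(ind.notna()))
    for col in ("pvt", "family_income", "cesd_w1", "neuroticism",
                "extraversion", "conscientiousness"):
        add_cont(col, col)
    for pc in PC_COLUMNS:
        add_cont(pc, pc)
    out = pd.DataFrame(rows)
    out.loc[len(out)] = {
        "variable": "n", "pre_mean": len(pre), "pre_sd": np.nan,
        "post_mean": len(post), "post_sd": np.nan, "p": np.nan, "sig": "",
    }
    return out


def pooled_sweep_table(imputations, spec: RDDSpec, bandwidths, fit_fn) -> pd.DataFrame:
    """Bandwidth sweep with Rubin pooling: one row per (bandwidth, term)."""
    rows = []
    for h in bandwidths:
        s = replace(spec, bandwidth=h)
        pooled = pooled_fit(imputations, lambda df, s=s: fit_fn(df, s))
        label = "all" if h is None else h
        for term, est in pooled.items():
            rows.append(
                {"bandwidth": label, "term": term, "estimate": est.estimate,
                 "se": est.se, "p": est.p, "df": est.df, "m": est.m,
                 "sig": _stars(est.p)}
            )
    return pd.DataFrame(rows)


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the full analysis described by ``config``.

    Returns a dict of result tables; each is also written under
    ``out_dir``.  The manifest records completed stages and any errors.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    results: dict = {}
    errors: dict = {}

    def save_df(name, df):
        results[name] = df
        df.to_csv(out_dir / f"{name}.csv", index=False)

    def save_json(name, obj):
        results[name] = obj
        with open(out_dir / f"{name}.json", "w") as fh:
            json.dump(obj, fh, indent=2, default=float)

    # --- stage: data -----------------------------------------------------
    sim = config.get("simulate") or {}
    if "cohort_csv" in sim:
        cohort = read_cohort(sim["cohort_csv"])
    else:
        sim = dict(sim)
        sim.setdefault("seed", seed)
        cohort = simulate_study_cohort(SyntheticConfig.from_dict(sim))

    # --- stage: score ----------------------------------------------------
    if "cesd_w3" not in cohort.columns and set(ITEM_COLUMNS) <= set(cohort.columns):
        cohort["cesd_w3"] = score_cesd(cohort[list(ITEM_COLUMNS)])
    if set(ITEM_COLUMNS) <= set(cohort.columns):
        try:
            save_json(
                "reliability",
                {"cronbach_alpha": cronbach_alpha(cohort[list(ITEM_COLUMNS)])},
            )
        except ValueError as err:
            errors["reliability"] = str(err)

    # --- stage: filter ---------------------------------------------------
    cohort, exclusion_log = apply_exclusions(cohort)
    save_json("exclusions", exclusion_log.to_dict())

    # --- stage: polygenic scores ----------------------------------------
    for raw, prefix in (("meanPGS_raw", "meanPGS"), ("varPGS_raw", "varPGS")):
        z = standardize(cohort[raw])
        cohort[f"{prefix}_z"] = z
        cohort[f"{prefix}_group"] = dichotomize_median(z)

    save_df("descriptives", _descriptives(cohort))

    # --- stage: imputation ----------------------------------------------
    imp_cfg = config.get("impute", {})
    rdd_cfg = config.get("rdd", {})
    covariates = tuple(rdd_cfg.get("covariates", MODEL_COVARIATES))
    if imp_cfg.get("enabled", True):
        methods = {c: "pmm" for c in CONTINUOUS_COVARIATES if c in covariates}
        if "mother_edu" in covariates:
            methods["mother_edu"] = "ordered_logit"
        predictors = ["cesd_w3", "T", "r", "meanPGS_z", "varPGS_z"]
        imputations = fit_mice(
            cohort,
            methods,
            predictors=predictors,
            m=int(imp_cfg.get("m", bm.N_IMPUTATIONS)),
            iterations=int(imp_cfg.get("iterations", 5)),
            k_pmm=int(imp_cfg.get("k_pmm", 5)),
            seed=seed,
        )
    else:
        from .impute import ImputationSet

        imputations = ImputationSet(
            m=1, datasets=[cohort.dropna(subset=[c for c in covariates
                                                 if c in cohort.columns])],
            methods={}, iterations=0, seed=seed,
        )

    # --- stage: discontinuity sweep --------------------------------------
    bandwidths = [
        None if b in (None, "all") else b for b in rdd_cfg.get("bandwidths", DEFAULT_BANDWIDTHS)
    ]
    base_spec = RDDSpec(
        covariates=covariates, pcs=PC_COLUMNS, robust=rdd_cfg.get("robust", "HC1")
    )
    from .rdd import fit_gxe_rdd, fit_sharp_rdd

    try:
        save_df(
            "rdd_treatment",
            pooled_sweep_table(imputations, base_spec, bandwidths, fit_sharp_rdd),
        )
    except Exception as err:
        errors["rdd_treatment"] = str(err)
        logger.exception("stage rdd_treatment failed")

    # --- stage: gene-environment models ----------------------------------
    gxe_cfg = config.get("gxe", {})
    coding = gxe_cfg.get("coding", "binary")
    for prefix, other in gxe_cfg.get(
        "moderators", {"meanPGS": "varPGS_z", "varPGS": "meanPGS_z"}
    ).items():
        moderator = f"{prefix}_group" if coding == "binary" else f"{prefix}_z"
        spec = replace(
            base_spec, moderator=moderator, moderator_coding=coding, other_pgs=other
        )
        try:
            save_df(
                f"rdd_gxe_{prefix}",
                pooled_sweep_table(imputations, spec, bandwidths, fit_gxe_rdd),
            )
        except Exception as err:
            errors[f"rdd_gxe_{prefix}"] = str(err)
            logger.exception("stage rdd_gxe_%s failed", prefix)

    # --- stage: validity --------------------------------------------------
    val_cfg = config.get("validity", {})
    lo, hi = val_cfg.get("placebo_days", [-20, 20])
    try:
        save_df(
            "placebo_scan",
            placebo_scan(
                cohort, days=range(int(lo), int(hi) + 1),
                h=val_cfg.get("placebo_bandwidth", 20),
            ),
        )
    except Exception as err:
        errors["placebo_scan"] = str(err)
    try:
        bal_covs = [c for c in MODEL_COVARIATES if c in cohort.columns]
        bal_covs += [c for c in PC_COLUMNS if c in cohort.columns]
        bal_covs += ["meanPGS_z", "varPGS_z", "cesd_w1"]
        bal_covs = list(dict.fromkeys(bal_covs))
        bal = balance_tests(
            cohort, bal_covs, h=val_cfg.get("balance_bandwidth", 50)
        )
        save_df("balance_tests", bal["tests"])
        save_json("balance_summary", {**bal["summary"], "notes": bal["notes"]})
    except Exception as err:
        errors["balance_tests"] = str(err)
    try:
        pw = power_from_design(
            cohort.dropna(subset=["cesd_w3"]),
            RDDSpec(bandwidth=val_cfg.get("power_bandwidth", 50)),
            tau=float(val_cfg.get("power_tau", bm.TREATMENT_COEF_BY_BANDWIDTH[50])),
        )
        save_json("power", pw)
    except Exception as err:
        errors["power"] = str(err)

    # --- stage: sensitivity ----------------------------------------------
    sens_cfg = config.get("sensitivity", {})
    sens_h = sens_cfg.get("bandwidth", 50)
    sens_rows = []
    try:
        for mode in ["identity"] + list(sens_cfg.get("transforms", [])):
            data0 = imputations.datasets[0]
            tdf = transform_outcome(data0, mode)
            fit = fit_sharp_rdd(tdf, replace(base_spec, bandwidth=sens_h))
            sens_rows.append(
                {"specification": f"linear/{mode}", "estimate": fit.late,
                 "se": float(fit.se["T"]), "p": float(fit.pvalues["T"]),
                 "n": fit.n_used}
            )
        qfit = fit_quadratic_rdd(
            imputations.datasets[0], replace(base_spec, bandwidth=sens_h)
        )
        sens_rows.append(
            {"specification": "quadratic/identity", "estimate": qfit.late,
             "se": float(qfit.se["T"]), "p": float(qfit.pvalues["T"]),
             "n": qfit.n_used}
        )
        save_df("sensitivity", pd.DataFrame(sens_rows))
    except Exception as err:
        errors["sensitivity"] = str(err)

    # --- stage: binned scatter -------------------------------------------
    rep_cfg = config.get("report", {})
    try:
        window = cohort.loc[cohort["r"].abs() <= 50]
        pre_n = int((window["r"] < 0).sum())
        post_n = int((window["r"] >= 0).sum())
        tgt_pre = rep_cfg.get("binned_target_pre", 117)
        tgt_post = rep_cfg.get("binned_target_post", 159)
        # bin each side against its own target count
        binned = pd.concat(
            [
                binned_scatter(window, bins_per_side=max(1, round(pre_n / tgt_pre)))
                .query("side == 'pre'"),
                binned_scatter(window, bins_per_side=max(1, round(post_n / tgt_post)))
                .query("side == 'post'"),
            ],
            ignore_index=True,
        )
        save_df("binned_scatter", binned)
        if rep_cfg.get("figures", False):
            from .sensitivity import plot_binned

            fit50 = fit_sharp_rdd(
                cohort.dropna(subset=["cesd_w3"]), RDDSpec(bandwidth=50)
            )
            ax = plot_binned(binned, fit50)
            ax.figure.savefig(out_dir / "binned_scatter.png", dpi=150)
    except Exception as err:
        errors["binned_scatter"] = str(err)

    manifest = {
        "seed": seed,
        "stages_completed": sorted(results.keys()),
        "errors": errors,
        "n_analytical": int(len(cohort)),
        "m_imputations": imputations.m,
    }
    save_json("manifest", manifest)
    return results
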