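"""Falsification suite: placebo-cutoff scan, covariate balance, power.

A credible discontinuity should appear only at the true cutoff and only in
the outcome.  The placebo scan re-estimates the jump at counterfactual
cutoff days (covariate-free fits); the balance tests re-estimate it with
each predetermined covariate as the outcome; the power calculation plugs
the realized design's robust standard error into the two-sided normal
power formula

    power = 1 - Phi(z_{1-a/2} - tau/se) + Phi(-z_{1-a/2} - tau/se),

which equals the test size exactly when tau = 0.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .rdd import RDDSpec, fit_sharp_rdd

__all__ = ["placebo_scan", "balance_tests", "rdd_power", "power_from_design"]

Z975 = norm.ppf(0.975)


def placebo_scan(
    table: pd.DataFrame,
    days=range(-20, 21),
    h: float = 20,
    spec: RDDSpec | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Re-estimate the discontinuity at each counterfactual cutoff day.

    For placebo day d the pseudo-treatment is 1{r >= d} and the local
    linear model is refitted at cutoff d without covariates.  The true
    cutoff (day 0) is included for comparability.  Days where the fit is
    not estimable are flagged rather than aborting the scan.
    """
    base = spec or RDDSpec()
    base = replace(
        base, covariates=(), pcs=(), moderator=None, other_pgs=None, bandwidth=h
    )
    zcrit = norm.ppf(1.0 - alpha / 2.0)
    rows = []
    work = table[[base.outcome, base.running]].copy()
    for d in days:
        work["_placeboT"] = (work[base.running] >= d).astype(int)
        s = replace(base, cutoff=float(d), treatment="_placeboT")
        try:
            fit = fit_sharp_rdd(work, s)
            est = fit.late
            se = float(fit.se["T"])
            rows.append(
                {
                    "day": d, "estimate": est, "se": se,
                    "ci_lower": est - zcrit * se, "ci_upper": est + zcrit * se,
                    "p": float(fit.pvalues["T"]),
                    "significant": bool(fit.pvalues["T"] < alpha),
                    "n_used": fit.n_used, "estimable": True,
                }
            )
        except (ValueError, np.linalg.LinAlgError):
            rows.append(
                {
                    "day": d, "estimate": np.nan, "se": np.nan,
                    "ci_lower": np.nan, "ci_upper": np.nan, "p": np.nan,
                    "significant": False, "n_used": 0, "estimable": False,
                }
            )
    return pd.DataFrame(rows)


def _expand_balance_outcomes(
    table: pd.DataFrame, covariates, h: float, spec: RDDSpec, min_state_n: int
):
    """Expand categorical covariates into indicator outcomes.

    State-of-residence indicators are restricted to states with at least
    ``min_state_n`` residents inside the bandwidth window.
    """
    in_window = table.loc[
        (table[spec.running] - spec.cutoff).abs() <= h
        if h is not None
        else np.ones(len(table), dtype=bool)
    ]
    outcomes = []
    notes = []
    for col in covariates:
        s = table[col]
        if s.dtype.kind in "OUS" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = [lv for lv in pd.unique(s.dropna())]
            if col == "state":
                counts = in_window[col].value_counts()
                dropped = [lv for lv in levels if counts.get(lv, 0) < min_state_n]
                levels = [lv for lv in levels if counts.get(lv, 0) >= min_state_n]
                if dropped:
                    notes.append(
                        f"{col}: {len(dropped)} level(s) below the "
                        f"{min_state_n}-resident floor excluded"
                    )
            for lv in sorted(map(str, levels)):
                name = f"{col}[{lv}]"
                outcomes.append((name, (s.astype(str) == lv).astype(float)))
        else:
            outcomes.append((col, s.astype(float)))
    return outcomes, notes


def balance_tests(
    table: pd.DataFrame,
    covariates,
    h: float = 50,
    spec: RDDSpec | None = None,
    alpha: float = 0.05,
    min_state_n: int = 40,
) -> dict:
    """Discontinuity test for each predetermined covariate.

    Each covariate (categoricals expanded to indicators) is regressed as
    the outcome of a covariate-free local linear discontinuity fit.
    Returns ``{"tests": DataFrame, "summary": dict, "notes": [...]}``;
    the summary reports the raw significant count next to the expected
    false-positive count alpha * n_tests -- no multiplicity correction is
    applied, matching the informal calibration this check is meant for.
    """
    base = spec or RDDSpec()
    base = replace(
        base, covariates=(), pcs=(), moderator=None, other_pgs=None, bandwidth=h
    )
    outcomes, notes = _expand_balance_outcomes(
        table, covariates, h, base, min_state_n
    )
    rows = []
    for name, values in outcomes:
        work = table[[base.running, base.treatment]].copy()
        work["_bal"] = values
        if work["_bal"].dropna().nunique() < 2:
            notes.append(f"{name}: constant, skipped")
            continue
        s = replace(base, outcome="_bal")
        try:
            fit = fit_sharp_rdd(work, s)
        except (ValueError, np.linalg.LinAlgError) as err:
            notes.append(f"{name}: not estimable ({err})")
            continue
        p = float(fit.pvalues["T"])
        rows.append(
            {
                "covariate": name,
                "estimate": fit.late,
                "se": float(fit.se["T"]),
                "p": p,
                "significant": bool(p < alpha),
                "n_used": fit.n_used,
            }
        )
    tests = pd.DataFrame(rows)
    total = len(tests)
    summary = {
        "total_tests": total,
        "n_significant": int(tests["significant"].sum()) if total else 0,
        "expected_false_positives": alpha * total,
        "alpha": alpha,
    }
    return {"tests": tests, "summary": summary, "notes": notes}


def rdd_power(tau: float, se: float, alpha: float = 0.05) -> float:
    """Two-sided normal power for detecting a discontinuity of size tau.

    ``se`` is the (robust) standard error of the treatment coefficient in
    the realized design.  At tau = 0 the value equals alpha exactly, and
    power is strictly increasing in |tau|.
    """
    if not np.isfinite(se) or se <= 0:
        raise ValueError("standard error must be positive and finite")
    z = norm.ppf(1.0 - alpha / 2.0)
    shift = tau / se
    return float(1.0 - norm.cdf(z - shift) + norm.cdf(-z - shift))


def power_from_design(
    table: pd.DataFrame, spec: RDDSpec, tau: float, alpha: float = 0.05
) -> dict:
    """Plug-in power: fit the design, take the robust SE of the treatment
    coefficient, and evaluate the closed-form power at the hypothesized
    effect."""
    fit = fit_sharp_rdd(table, spec) if spec.moderator is None else None
    if fit is None:
        raise ValueError("power is defined for the plain treatment model")
    se = float(fit.se["T"])
    return {
        "power": rdd_power(tau, se, alpha),
        "se_beta1": se,
        "tau": tau,
        "alpha": alpha,
        "n_used": fit.n_used,
    }
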