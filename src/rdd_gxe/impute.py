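"""Multiple imputation by chained equations and Rubin's-rules pooling.

Missing covariates are filled by iterated conditional draws: continuous
variables by predictive mean matching (PMM: a Bayesian draw of the linear
model parameters, then sampling an observed value from the k nearest
donors by predicted mean) and ordered categorical variables by a
proportional-odds cumulative-logit model (with a PMM fallback on numeric
codes if the likelihood fit fails to converge, e.g. under separation).

Conventions: variables are visited in ascending order of missingness; the
imputation model for each variable uses all other declared predictors --
which should include the outcome and the design variables (Y, T, r), since
a congenial imputation model must see everything the analysis model sees.
Outcome and design variables themselves are never imputed.

Estimates from the m completed datasets are combined with Rubin's rules:
pooled estimate = mean; total variance = within + (1 + 1/m) * between;
degrees of freedom by the Barnard-Rubin small-sample adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

__all__ = ["ImputationSet", "PooledEstimate", "fit_mice", "pool_rubin", "pooled_fit"]


@dataclass
class ImputationSet:
    """m completed copies of a cohort plus per-variable method labels."""

    m: int
    datasets: list
    methods: dict
    iterations: int
    seed: int


@dataclass
class PooledEstimate:
    """Rubin combination of one coefficient across imputations."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    p: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))

    def conf_int(self, level: float = 0.95) -> tuple[float, float]:
        q = t_dist.ppf(0.5 + level / 2.0, self.df) if np.isfinite(self.df) else \
            t_dist.ppf(0.5 + level / 2.0, np.inf)
        return (self.estimate - q * self.se, self.estimate + q * self.se)


def _ols_draw(Xo: np.ndarray, yo: np.ndarray, rng: np.random.Generator):
    """Least squares fit plus an approximate Bayesian parameter draw."""
    n, p = Xo.shape
    beta, _, rank, _ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta
    dof = max(n - rank, 1)
    sse = float(resid @ resid)
    sigma2_star = sse / max(rng.chisquare(dof), 1e-12)
    XtX = Xo.T @ Xo
    XtX.flat[:: p + 1] += 1e-8 * max(np.trace(XtX) / p, 1.0)  # ridge jitter
    cov = sigma2_star * np.linalg.inv(XtX)
    L = np.linalg.cholesky((cov + cov.T) / 2.0)
    beta_star = beta + L @ rng.standard_normal(p)
    return beta, beta_star


def _pmm_impute(
    Xo: np.ndarray, yo: np.ndarray, Xm: np.ndarray, rng: np.random.Generator, k: int
) -> np.ndarray:
    """Type-1 PMM: donors matched on yhat_obs(beta_hat) vs yhat_mis(beta_star)."""
    beta, beta_star = _ols_draw(Xo, yo, rng)
    yhat_obs = Xo @ beta
    yhat_mis = Xm @ beta_star
    k_eff = min(k, len(yo))
    dist = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
    nearest = np.argpartition(dist, k_eff - 1, axis=1)[:, :k_eff]
    pick = rng.integers(0, k_eff, size=len(yhat_mis))
    return yo[nearest[np.arange(len(yhat_mis)), pick]]


def _ordered_logit_impute(
    Xo: np.ndarray, yo: np.ndarray, Xm: np.ndarray, rng: np.random.Generator,
    k_pmm: int, varname: str,
) -> np.ndarray:
    """Draw categories from a fitted proportional-odds cumulative logit."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    codes = yo.astype(int)
    # drop the constant column: OrderedModel absorbs it into the thresholds
    keep = ~np.all(Xo == Xo[0, :], axis=0)
    Xo_, Xm_ = Xo[:, keep], Xm[:, keep]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(codes, Xo_, distr="logit")
            res = model.fit(method="bfgs", maxiter=200, disp=False)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("no convergence")
        probs = np.asarray(res.predict(Xm_))
    except Exception:
        warnings.warn(
            f"ordered logit failed for {varname!r}; falling back to PMM on codes"
        )
        return np.round(
            _pmm_impute(Xo, codes.astype(float), Xm, rng, k_pmm)
        ).astype(int)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(Xm_))
    draws = (u[:, None] > cum).sum(axis=1)
    levels = np.unique(codes)
    return levels[np.clip(draws, 0, len(levels) - 1)]


def _predictor_matrix(df: pd.DataFrame, cols) -> np.ndarray:
    """Constant + numeric encoding of the predictor columns."""
    pieces = [np.ones((len(df), 1))]
    for c in cols:
        s = df[c]
        if s.dtype.kind in "OUS" or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            pieces.append(d.to_numpy())
        else:
            pieces.append(s.to_numpy(dtype=float)[:, None])
    return np.concatenate(pieces, axis=1)


def fit_mice(
    table: pd.DataFrame,
    methods: dict,
    predictors=None,
    m: int = 20,
    iterations: int = 10,
    k_pmm: int = 5,
    seed: int = 0,
) -> ImputationSet:
    """Chained-equation multiple imputation.

    Parameters
    ----------
    table : DataFrame
        Input cohort; only cells that are missing on entry are ever
        modified, and observed cells are identical across all m copies.
    methods : dict
        variable -> 'pmm' | 'ordered_logit' | 'none'.  Every variable with
        missing values must carry a method (or 'none' to leave it alone).
    predictors : sequence, optional
        Additional complete columns (typically the outcome and design
        variables) entering every conditional model.  Defaults to none;
        the other imputed variables always co-predict.
    """
    methods = dict(methods)
    predictors = list(predictors or [])
    targets = [v for v, meth in methods.items() if meth != "none"]
    for v in list(methods):
        if methods[v] not in ("pmm", "ordered_logit", "none"):
            raise ValueError(f"unknown method {methods[v]!r} for {v!r}")
        if v not in table.columns:
            raise ValueError(f"no such column: {v}")
    missing_cols = [c for c in table.columns if table[c].isna().any()]
    undeclared = [c for c in missing_cols if c not in methods and
                  (c in predictors or c in targets)]
    if undeclared:
        raise ValueError(f"missing values in undeclared variables: {undeclared}")
    for p_ in predictors:
        if table[p_].isna().any():
            raise ValueError(f"predictor {p_!r} has missing values")

    na_mask = {v: table[v].isna().to_numpy() for v in targets}
    targets = [v for v in targets if na_mask[v].any()]
    # ascending-missingness visit order
    targets.sort(key=lambda v: na_mask[v].sum())

    for v in targets:
        if methods[v] == "ordered_logit":
            s = table[v]
            if isinstance(s.dtype, pd.CategoricalDtype):
                observed = set(s.dropna().unique())
                if observed != set(s.cat.categories):
                    raise ValueError(
                        f"{v!r} has category levels never observed; cannot impute"
                    )

    datasets = []
    root = np.random.SeedSequence(int(seed))
    children = root.spawn(max(m, 1))
    for j in range(m):
        rng = np.random.default_rng(children[j])
        df = table.copy()
        # initialize by random draws from the observed margins
        for v in targets:
            obs = table[v].dropna().to_numpy()
            fill = rng.choice(obs, size=int(na_mask[v].sum()), replace=True)
            col = df[v]
            if col.dtype.kind in "iub":
                df[v] = col.astype(float)
            df.loc[na_mask[v], v] = fill
        for _ in range(iterations):
            for v in targets:
                other = [w for w in targets if w != v] + predictors
                X = _predictor_matrix(df, other)
                obs_idx = ~na_mask[v]
                Xo, Xm = X[obs_idx], X[na_mask[v]]
                yo = table.loc[obs_idx, v].to_numpy(dtype=float)
                if methods[v] == "pmm":
                    imputed = _pmm_impute(Xo, yo, Xm, rng, k_pmm)
                else:
                    imputed = _ordered_logit_impute(Xo, yo, Xm, rng, k_pmm, v)
                df.loc[na_mask[v], v] = imputed.astype(float)
        datasets.append(df)
    return ImputationSet(
        m=m, datasets=datasets, methods=methods, iterations=iterations, seed=seed
    )


def pool_rubin(estimates, variances, dfcom: float = np.inf) -> PooledEstimate:
    """Combine m point estimates and their squared SEs by Rubin's rules.

    ``dfcom`` is the complete-data residual degrees of freedom used by the
    Barnard-Rubin adjustment; the default (infinite) reduces to the classic
    large-sample Rubin degrees of freedom.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1 or q.size < 1:
        raise ValueError("estimates and variances must be equal-length 1-d arrays")
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(u))):
        raise ValueError("non-finite inputs to pooling")
    m = q.size
    qbar = float(q.mean())
    ubar = float(u.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    total = ubar + (1.0 + 1.0 / m) * b
    if m == 1 or b == 0.0 or total == 0.0:
        df = np.inf
    else:
        lam = (1.0 + 1.0 / m) * b / total
        df_old = (m - 1) / lam**2
        if np.isfinite(dfcom):
            df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
    if total > 0:
        stat = qbar / np.sqrt(total)
        p = float(2.0 * t_dist.sf(abs(stat), df if np.isfinite(df) else np.inf))
    else:
        p = 1.0 if qbar == 0 else 0.0
    return PooledEstimate(
        estimate=qbar, within_var=ubar, between_var=b, total_var=total,
        df=float(df), p=p, m=m,
    )


def pooled_fit(imputations: ImputationSet, fitter) -> dict:
    """Apply ``fitter`` to each completed dataset and pool per coefficient.

    ``fitter`` maps a DataFrame to an object with ``params`` (Series) and
    ``cov`` (DataFrame) attributes, e.g. an RDD fit.  Returns a dict of
    term -> PooledEstimate.  Failures are aggregated and re-raised with the
    indices of the offending datasets.
    """
    fits, failures = [], []
    for idx, df in enumerate(imputations.datasets):
        try:
            fits.append(fitter(df))
        except Exception as err:  # collected, reported together
            failures.append((idx, err))
    if failures:
        detail = "; ".join(f"dataset {i}: {e}" for i, e in failures[:5])
        raise RuntimeError(
            f"fitter failed on {len(failures)} of {imputations.m} datasets ({detail})"
        )
    terms = list(fits[0].params.index)
    n_used = getattr(fits[0], "n_used", len(imputations.datasets[0]))
    p = len(terms)
    dfcom = max(n_used - p, 1)
    out = {}
    for term in terms:
        ests = [float(f.params[term]) for f in fits]
        vars_ = [float(f.cov.loc[term, term]) for f in fits]
        out[term] = pool_rubin(ests, vars_, dfcom=dfcom)
    return out
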