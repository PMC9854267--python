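"""Sharp regression-discontinuity estimation with kernel weights.

The treatment model is a local linear regression on each side of the cutoff,

    Y = a + b1*T + b2*(r - c) + b3*T*(r - c) + covariates + e,

fitted by weighted least squares with a triangular kernel inside the chosen
bandwidth; b1 is the local average treatment effect at the cutoff.  The
gene-environment model adds a moderator G (a median-split indicator or a
standardized continuous polygenic score) with its full interaction set
T*G, r*G and T*r*G, the genetic principal components, and the other
polygenic score as a level covariate; b5 (the T*G term) is the G x E
contrast and b1 the effect in the G = 0 reference group.

Inference uses a heteroskedasticity-robust sandwich covariance (HC1 by
default) on the kernel-weighted normal equations,

    cov(beta) = (X'WX)^-1 (X' diag(w_i^2 e_i^2) X) (X'WX)^-1 * n/(n - p),

with normal (z) critical values; pooling over multiple imputations replaces
these with t references elsewhere.

Note on slope contrasts: the post-cutoff slope of the outcome in days is
the sum of the ``r`` and ``T:r`` coefficients (b2 + b3).  Some write-ups of
this design label the post-shock slope "b1 + b3", which conflicts with the
term definitions above; :func:`post_cutoff_slope` implements b2 + b3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "RDDSpec",
    "RDDFit",
    "triangular_weights",
    "fit_sharp_rdd",
    "fit_gxe_rdd",
    "fit_stratified",
    "linear_combination",
    "post_cutoff_slope",
    "conditional_effect",
    "bandwidth_sweep",
    "sweep_summary",
]

DEFAULT_BANDWIDTHS = (10, 20, 30, 40, 50, None)


@dataclass(frozen=True)
class RDDSpec:
    """Estimation request for a sharp discontinuity fit."""

    outcome: str = "cesd_w3"
    cutoff: float = 0.0
    running: str = "r"
    treatment: str = "T"
    bandwidth: float | None = None  # None = all data, uniform weights
    kernel: str = "triangular"  # or "uniform"
    order: int = 1  # 2 adds r^2 and T:r^2 (sensitivity path)
    covariates: tuple = ()
    moderator: str | None = None
    moderator_coding: str = "binary"  # or "continuous"
    other_pgs: str | None = None
    pcs: tuple = ()
    robust: str = "HC1"  # or "HC0"

    def __post_init__(self):
        if self.bandwidth is not None and not self.bandwidth > 0:
            raise ValueError("bandwidth must be positive (or None for all data)")
        if self.kernel not in ("triangular", "uniform"):
            raise ValueError(f"unknown kernel: {self.kernel}")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if self.moderator_coding not in ("binary", "continuous"):
            raise ValueError("moderator_coding must be 'binary' or 'continuous'")
        if self.robust not in ("HC0", "HC1"):
            raise ValueError("robust must be 'HC0' or 'HC1'")


@dataclass
class RDDFit:
    """Coefficients and robust covariance of one discontinuity fit."""

    params: pd.Series
    cov: pd.DataFrame
    n_used: int
    bandwidth: float | None
    spec: RDDSpec

    @property
    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.clip(np.diag(self.cov.values), 0.0, None)),
            index=self.params.index,
        )

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.se
        return pd.Series(2.0 * norm.sf(np.abs(z)), index=self.params.index)

    @property
    def late(self) -> float:
        """The local average treatment effect (the treatment coefficient)."""
        return float(self.params["T"])

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = norm.ppf(0.5 + level / 2.0)
        lo = self.params - z * self.se
        hi = self.params + z * self.se
        return pd.DataFrame({"lower": lo, "upper": hi})

    def tidy(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.values,
                "se": self.se.values,
                "p": self.pvalues.values,
            }
        ).reset_index(drop=True)


def triangular_weights(r, cutoff: float = 0.0, h: float | None = None) -> np.ndarray:
    """Kernel weights w = max(0, 1 - |r - cutoff| / h); ones when h is None."""
    r = np.asarray(r, dtype=float)
    if h is None or np.isinf(h):
        return np.ones_like(r)
    if not h > 0:
        raise ValueError("bandwidth must be positive")
    return np.maximum(0.0, 1.0 - np.abs(r - cutoff) / h)


def _encode_covariates(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric covariates pass through; object/categorical columns are
    dummy-encoded with the first level as reference."""
    pieces = []
    for col in covariates:
        s = df[col]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            pieces.append(d)
        else:
            pieces.append(s.astype(float).to_frame(col))
    if not pieces:
        return pd.DataFrame(index=df.index)
    return pd.concat(pieces, axis=1)


def _moderator_values(table: pd.DataFrame, spec: RDDSpec) -> pd.Series:
    s = table[spec.moderator]
    if spec.moderator_coding == "binary":
        if s.dtype.kind in "OUS" or isinstance(s.dtype, pd.CategoricalDtype):
            mapping = {"low": 0.0, "high": 1.0}
            vals = s.astype(str).map(mapping)
            if vals.isna().any() and not s.isna().any():
                raise ValueError("binary moderator must be coded {low, high} or {0, 1}")
            return vals
        uniq = set(np.unique(s.dropna()))
        if not uniq <= {0, 1, 0.0, 1.0}:
            raise ValueError("binary moderator must be coded {low, high} or {0, 1}")
        return s.astype(float)
    # continuous: standardize on the full supplied table so the scale does
    # not drift with the bandwidth subset
    vals = s.astype(float)
    sd = vals.std(ddof=1)
    if not sd > 0:
        raise ValueError("continuous moderator has zero variance")
    return (vals - vals.mean()) / sd


def _build_design(table: pd.DataFrame, spec: RDDSpec):
    r = table[spec.running].astype(float) - spec.cutoff
    w = triangular_weights(
        table[spec.running].to_numpy(dtype=float), spec.cutoff, spec.bandwidth
    )
    if spec.kernel == "uniform" and spec.bandwidth is not None:
        w = (w > 0).astype(float)
    T = table[spec.treatment].astype(float)

    X = pd.DataFrame(index=table.index)
    X["const"] = 1.0
    X["T"] = T
    X["r"] = r
    X["T:r"] = T * r
    if spec.order == 2:
        X["r2"] = r**2
        X["T:r2"] = T * r**2
    if spec.moderator is not None:
        G = _moderator_values(table, spec)
        X["G"] = G
        X["T:G"] = T * G
        X["r:G"] = r * G
        X["T:r:G"] = T * r * G
        if spec.order == 2:
            X["r2:G"] = r**2 * G
            X["T:r2:G"] = T * r**2 * G
    for pc in spec.pcs:
        X[pc] = table[pc].astype(float)
    if spec.other_pgs is not None:
        X[spec.other_pgs] = table[spec.other_pgs].astype(float)
    cov_block = _encode_covariates(table, spec.covariates)
    X = pd.concat([X, cov_block], axis=1)

    y = table[spec.outcome].astype(float)
    keep = (w > 0) & y.notna().to_numpy() & X.notna().all(axis=1).to_numpy()
    y, X, w = y[keep], X.loc[keep], w[np.asarray(keep)]
    # indicator levels absent (or constant) inside the window carry no
    # information; drop them rather than failing on a singular design
    empty = [c for c in cov_block.columns if c in X and X[c].nunique() < 2]
    if empty:
        X = X.drop(columns=empty)
    return y, X, w


def _wls_sandwich(y: np.ndarray, X: np.ndarray, w: np.ndarray, robust: str):
    """Weighted least squares with a kernel-weighted sandwich covariance."""
    n, p = X.shape
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    rank = np.linalg.matrix_rank(Xw)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"singular design: rank {rank} < {p} columns "
            "(e.g. no variation on one side of the cutoff within the bandwidth)"
        )
    A = Xw.T @ Xw  # X'WX
    beta = np.linalg.solve(A, Xw.T @ yw)
    resid = y - X @ beta
    u = X * (w * resid)[:, None]
    meat = u.T @ u  # sum w_i^2 e_i^2 x_i x_i'
    Ainv = np.linalg.inv(A)
    cov = Ainv @ meat @ Ainv
    if robust == "HC1":
        if n <= p:
            raise ValueError("HC1 requires n > p")
        cov = cov * n / (n - p)
    return beta, cov


def _fit(table: pd.DataFrame, spec: RDDSpec) -> RDDFit:
    y, X, w = _build_design(table, spec)
    p = X.shape[1]
    if len(y) < p + 2:
        raise ValueError(
            f"only {len(y)} usable rows inside the bandwidth for {p} parameters"
        )
    if spec.moderator is not None and X["G"].nunique() < 2:
        raise ValueError("moderator is constant within the bandwidth")
    t = np.asarray(X["T"])
    if t.min() == t.max():
        raise ValueError("no rows on one side of the cutoff within the bandwidth")
    beta, cov = _wls_sandwich(
        y.to_numpy(), X.to_numpy(dtype=float), np.asarray(w, dtype=float), spec.robust
    )
    params = pd.Series(beta, index=X.columns)
    covdf = pd.DataFrame(cov, index=X.columns, columns=X.columns)
    return RDDFit(
        params=params, cov=covdf, n_used=len(y), bandwidth=spec.bandwidth, spec=spec
    )


def fit_sharp_rdd(table: pd.DataFrame, spec: RDDSpec) -> RDDFit:
    """Fit the plain treatment model (no moderator)."""
    if spec.moderator is not None:
        raise ValueError("use fit_gxe_rdd for a moderated specification")
    return _fit(table, spec)


def fit_gxe_rdd(table: pd.DataFrame, spec: RDDSpec) -> RDDFit:
    """Fit the moderated (gene-environment) model.

    Requires ``spec.moderator``; the moderator enters with its full
    interaction set.  With binary coding the treatment coefficient is the
    effect in the low-score reference group and ``T:G`` is the G x E
    contrast; with continuous coding ``T:G`` is the change in the
    discontinuity per SD of the score.
    """
    if spec.moderator is None:
        raise ValueError("spec.moderator is required for a moderated fit")
    return _fit(table, spec)


def fit_stratified(table: pd.DataFrame, spec: RDDSpec) -> dict:
    """Independent fits per moderator group (separate-panels style)."""
    if spec.moderator is None:
        raise ValueError("spec.moderator is required")
    G = _moderator_values(table, replace(spec, moderator_coding="binary"))
    base = replace(spec, moderator=None)
    out = {}
    for label, code in (("low", 0.0), ("high", 1.0)):
        sub = table.loc[G == code]
        out[label] = _fit(sub, base)
    return out


def linear_combination(fit: RDDFit, contrast) -> dict:
    """Estimate, SE and two-sided normal p-value of c'beta.

    ``contrast`` may be a vector aligned with ``fit.params`` or a dict of
    term -> coefficient (unlisted terms get zero).
    """
    terms = list(fit.params.index)
    if isinstance(contrast, dict):
        unknown = set(contrast) - set(terms)
        if unknown:
            raise ValueError(f"unknown terms in contrast: {sorted(unknown)}")
        c = np.array([contrast.get(t, 0.0) for t in terms], dtype=float)
    else:
        c = np.asarray(contrast, dtype=float)
        if c.shape != (len(terms),):
            raise ValueError(
                f"contrast length {c.shape} does not match {len(terms)} coefficients"
            )
    est = float(c @ fit.params.values)
    var = float(c @ fit.cov.values @ c)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        p = np.nan if est != 0 else 1.0
    else:
        p = float(2.0 * norm.sf(abs(est) / se))
    return {"estimate": est, "se": se, "p": p}


def post_cutoff_slope(fit: RDDFit) -> dict:
    """Slope of the outcome in days after the cutoff: the r + T:r contrast."""
    return linear_combination(fit, {"r": 1.0, "T:r": 1.0})


def conditional_effect(fit: RDDFit, g: float) -> dict:
    """Treatment effect at moderator value g: the T + g * T:G contrast."""
    if "T:G" not in fit.params.index:
        raise ValueError("fit has no moderator interaction term")
    return linear_combination(fit, {"T": 1.0, "T:G": float(g)})


def bandwidth_sweep(
    table: pd.DataFrame,
    spec: RDDSpec,
    bandwidths=DEFAULT_BANDWIDTHS,
) -> dict:
    """One fit per bandwidth (None = all rows, uniform weights).

    Returns {bandwidth: RDDFit}; a failing bandwidth maps to the exception
    instead of aborting the sweep.
    """
    fits: dict = {}
    for h in bandwidths:
        s = replace(spec, bandwidth=h)
        try:
            fits[h] = _fit(table, s)
        except (ValueError, np.linalg.LinAlgError) as err:
            fits[h] = err
    return fits


def sweep_summary(fits: dict) -> pd.DataFrame:
    """Tidy table of the sweep: one row per (bandwidth, term)."""
    rows = []
    for h, fit in fits.items():
        label = "all" if h is None else h
        if isinstance(fit, Exception):
            rows.append(
                {"bandwidth": label, "term": None, "estimate": np.nan,
                 "se": np.nan, "p": np.nan, "n": np.nan, "error": str(fit)}
            )
            continue
        tidy = fit.tidy()
        tidy.insert(0, "bandwidth", label)
        tidy["n"] = fit.n_used
        tidy["error"] = ""
        rows.extend(tidy.to_dict("records"))
    return pd.DataFrame(rows)
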