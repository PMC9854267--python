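"""Polygenic-score construction and the score-validity regression.

A polygenic score is the weighted sum of effect-allele dosages over a panel
of variants, score_i = sum_j w_j * g_ij with g in [0, 2].  Scores are
standardized to z-scores and, for the broad two-group contrasts, split at
the sample median (values at or below the median are "low", strictly above
are "high").  The first k genotype principal components serve as covariates
against population-structure confounding; they are plumbing for covariate
adjustment, not an ancestry-inference feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DosageMatrix",
    "read_weights",
    "write_weights",
    "compute_score",
    "standardize",
    "dichotomize_median",
    "pc_covariates",
    "pgs_validity_regression",
]

_ALLELES = {"A", "C", "G", "T"}


@dataclass
class DosageMatrix:
    """Subjects x variants dosage matrix with per-variant counted alleles.

    ``dosages`` holds 0-2 effect-allele counts (NaN = missing) with variant
    ids as columns; ``effect_alleles`` maps variant id -> the allele the
    dosage counts; ``other_alleles`` (optional) maps variant id -> the
    second allele, enabling strand-consistent allele flips when a scoring
    file counts the opposite allele.
    """

    dosages: pd.DataFrame
    effect_alleles: dict
    other_alleles: dict | None = None

    def __post_init__(self):
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
                raise ValueError("dosage entries must lie in [0, 2]")
        missing = set(self.dosages.columns) - set(self.effect_alleles)
        if missing:
            raise ValueError(f"variants without effect allele: {sorted(missing)[:5]}")


def read_weights(path) -> pd.DataFrame:
    """Read a 3-column whitespace/tab-delimited scoring file.

    Columns: variant_id, effect_allele, weight.  A header row is accepted
    if its third field is not numeric.
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["variant_id", "effect_allele", "weight"],
        dtype={"variant_id": str, "effect_allele": str},
    )
    try:
        float(df.iloc[0, 2])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    df["weight"] = df["weight"].astype(float)
    return _validate_weights(df)


def write_weights(weights: pd.DataFrame, path) -> None:
    weights.to_csv(path, sep="\t", header=False, index=False)


def _validate_weights(weights: pd.DataFrame) -> pd.DataFrame:
    if weights["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in weight table")
    if not np.all(np.isfinite(weights["weight"])):
        raise ValueError("non-finite weight")
    bad = ~weights["effect_allele"].str.upper().isin(_ALLELES)
    if bad.any():
        raise ValueError(
            f"invalid effect allele: {weights.loc[bad, 'effect_allele'].iloc[0]}"
        )
    return weights


def compute_score(dosages: DosageMatrix, weights: pd.DataFrame) -> pd.Series:
    """Weighted-sum score over the variants shared by matrix and weights.

    Missing dosages are imputed as twice the effect-allele frequency among
    observed subjects (i.e. the observed mean dosage).  Variants whose
    weight-file effect allele matches the matrix's *other* allele are
    flipped (dosage -> 2 - dosage); unresolvable allele mismatches are
    dropped with a logged count.  Raises if no variant overlaps.
    """
    weights = _validate_weights(weights)
    wmap = dict(zip(weights["variant_id"], weights["weight"]))
    amap = dict(
        zip(weights["variant_id"], weights["effect_allele"].str.upper())
    )
    shared = [v for v in dosages.dosages.columns if v in wmap]
    if not shared:
        raise ValueError(
            f"no overlapping variants ({dosages.dosages.shape[1]} in matrix, "
            f"{len(wmap)} in weights)"
        )
    other = dosages.other_alleles or {}
    used, flipped, dropped = [], [], 0
    for v in shared:
        counted = str(dosages.effect_alleles[v]).upper()
        target = amap[v]
        if counted == target:
            used.append((v, False))
        elif str(other.get(v, "")).upper() == target:
            used.append((v, True))
            flipped.append(v)
        else:
            dropped += 1
    if dropped:
        logger.warning("dropped %d variant(s) with unresolvable allele mismatch", dropped)
    if not used:
        raise ValueError("no variants remain after allele reconciliation")

    total = np.zeros(len(dosages.dosages), dtype=float)
    for v, flip in used:
        g = dosages.dosages[v].to_numpy(dtype=float)
        if flip:
            g = 2.0 - g
        if np.isnan(g).any():
            if np.isnan(g).all():
                raise ValueError(f"variant {v} has no observed dosages")
            g = np.where(np.isnan(g), np.nanmean(g), g)
        total += wmap[v] * g
    return pd.Series(total, index=dosages.dosages.index, name="pgs")


def standardize(scores) -> np.ndarray:
    """Z-score with sample (n-1) SD; missing values propagate."""
    x = np.asarray(scores, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise ValueError("standardize requires >=2 observed values")
    sd = obs.std(ddof=1)
    if not sd > 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - obs.mean()) / sd


def dichotomize_median(scores) -> np.ndarray:
    """Median split: value <= sample median -> 'low', > median -> 'high'.

    Ties at the median go to the low group (the <=50th-percentile rule).
    Missing values yield missing group labels.
    """
    x = np.asarray(scores, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size == 0:
        raise ValueError("all scores missing")
    if obs.size < 2:
        raise ValueError("median split requires >=2 observed values")
    med = np.median(obs)
    out = np.where(x <= med, "low", "high").astype(object)
    out[np.isnan(x)] = None
    return out


def pc_covariates(dosages: DosageMatrix, k: int = 10) -> pd.DataFrame:
    """Top-k principal components of the column-centered dosage matrix.

    Missing dosages are mean-imputed per variant before centering.  Each
    component is scaled to unit sample variance.  Raises if k exceeds the
    rank of the centered matrix.
    """
    M = dosages.dosages.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(M, axis=0)
    nan_mask = np.isnan(M)
    M[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    M = M - M.mean(axis=0)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    tol = s.max(initial=0.0) * max(M.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if k > rank:
        raise ValueError(f"requested k={k} components but matrix rank is {rank}")
    pcs = U[:, :k] * s[:k]
    pcs = pcs / pcs.std(axis=0, ddof=1)
    return pd.DataFrame(
        pcs, index=dosages.dosages.index, columns=[f"pc{i}" for i in range(1, k + 1)]
    )


def pgs_validity_regression(
    table: pd.DataFrame,
    outcome: str = "cesd_w3",
    group: str = "meanPGS_group",
    pcs=tuple(f"pc{i}" for i in range(1, 11)),
) -> dict:
    """OLS of the outcome on the high-vs-low score group plus the PCs.

    Returns the group coefficient (high minus low), its p-value, and the
    incremental R^2 of the group term over the PC-only model.
    """
    import statsmodels.api as sm

    df = table[[outcome, group, *pcs]].dropna()
    g = df[group]
    if g.dtype.kind in "OUS" or isinstance(g.dtype, pd.CategoricalDtype):
        gvals = g.astype(str).map({"low": 0.0, "high": 1.0})
        if gvals.isna().any():
            raise ValueError("group column must be coded {low, high} or {0, 1}")
    else:
        gvals = g.astype(float)
    if gvals.nunique() < 2:
        raise ValueError("group column is constant")
    Xpc = sm.add_constant(df[list(pcs)].astype(float), has_constant="add")
    if np.linalg.matrix_rank(Xpc.to_numpy()) < Xpc.shape[1]:
        raise ValueError("collinear principal components")
    X = Xpc.copy()
    X.insert(1, "group", gvals.to_numpy())
    full = sm.OLS(df[outcome].astype(float), X).fit()
    reduced = sm.OLS(df[outcome].astype(float), Xpc).fit()
    return {
        "coefficient": float(full.params["group"]),
        "se": float(full.bse["group"]),
        "p": float(full.pvalues["group"]),
        "partial_r2": float(full.rsquared - reduced.rsquared),
        "n": int(full.nobs),
    }
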