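"""CES-D outcome construction, scale reliability, and sample-exclusion filters.

The outcome is a 9-item CES-D screener: each item is answered 0 (never) to 3
(most/all of the time) for the past week.  Items 3 ("felt just as good as
other people") and 7 ("enjoyed life") are positively worded and are
reverse-coded (value -> 3 - value) before summing, so the total runs from 0
(least depressed) to 27 (most depressed).

Sample exclusions are applied sequentially -- genetic-ancestry homogeneity,
availability of genotype data, availability of the outcome -- and each stage
count is evaluated on the survivors of the previous stage.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

#: 1-based indices of the reverse-coded (positive-affect) items.
REVERSE_CODED_ITEMS = (3, 7)

#: Number of screener items.
N_ITEMS = 9

#: Conventional clinical cut-off: a score of 8 or above flags significant
#: depressive symptoms.
CLINICAL_CUTOFF = 8

ITEM_COLUMNS = tuple(f"cesd_item{i}" for i in range(1, N_ITEMS + 1))


def _as_item_matrix(items) -> np.ndarray:
    """Coerce items to a float (n, 9) matrix, NaN for missing."""
    arr = np.asarray(items, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} items, got {arr.shape[1]}")
    return arr


def _validate_items(arr: np.ndarray) -> None:
    with np.errstate(invalid="ignore"):
        bad = ~np.isnan(arr) & ((arr < 0) | (arr > 3) | (arr != np.round(arr)))
    if bad.any():
        _, cols = np.where(bad)
        raise ValueError(
            f"item values must be integers in 0-3; first offending item index "
            f"(1-based): {cols[0] + 1}"
        )


def reverse_code(items) -> np.ndarray:
    """Return the item matrix with the positive-affect items reverse-coded."""
    arr = _as_item_matrix(items).copy()
    _validate_items(arr)
    for i in REVERSE_CODED_ITEMS:
        arr[:, i - 1] = 3.0 - arr[:, i - 1]
    return arr


def score_cesd(items):
    """Sum the nine screener items after reverse-coding items 3 and 7.

    Parameters
    ----------
    items : array-like
        Either a length-9 vector (single subject) or an (n, 9) matrix /
        DataFrame of item responses in {0, 1, 2, 3}; NaN marks missing.

    Returns
    -------
    float or ndarray
        Total score in [0, 27].  Any missing item propagates to a missing
        total -- no prorating is applied, matching the study rule that
        subjects without outcome information are dropped rather than
        partially scored.
    """
    single = np.asarray(items, dtype=float).ndim == 1
    recoded = reverse_code(items)
    totals = recoded.sum(axis=1)  # NaN propagates
    return float(totals[0]) if single else totals


def clinical_flag(scores, cutoff: int = CLINICAL_CUTOFF):
    """Convenience indicator: 1 if score >= cutoff (default 8), NaN-safe."""
    s = np.asarray(scores, dtype=float)
    flag = np.where(np.isnan(s), np.nan, (s >= cutoff).astype(float))
    return flag


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha of the reverse-coded screener on complete cases.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total),
    with k the number of items.  Population (ddof=0) variances are used;
    the choice is a documented constant and cancels nothing either way.

    Raises
    ------
    ValueError
        If fewer than two complete cases are available or the total score
        has zero variance (alpha undefined).
    """
    arr = _as_item_matrix(item_matrix)
    _validate_items(arr)
    complete = arr[~np.isnan(arr).any(axis=1)]
    if complete.shape[0] < 2:
        raise ValueError("cronbach_alpha requires >=2 complete cases")
    for i in REVERSE_CODED_ITEMS:
        complete[:, i - 1] = 3.0 - complete[:, i - 1]
    k = complete.shape[1]
    item_vars = complete.var(axis=0, ddof=0)
    total_var = complete.sum(axis=1).var(ddof=0)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return (k / (k - 1)) * (1.0 - item_vars.sum() / total_var)


@dataclass
class ExclusionLog:
    """Per-stage accounting of the sequential sample filters."""

    n_input: int
    n_dropped_ancestry: int
    n_dropped_no_genotype: int
    n_dropped_no_outcome: int
    n_final: int

    def to_dict(self) -> dict:
        return asdict(self)

    def __post_init__(self) -> None:
        drops = (
            self.n_dropped_ancestry
            + self.n_dropped_no_genotype
            + self.n_dropped_no_outcome
        )
        if self.n_final != self.n_input - drops:
            raise ValueError("inconsistent exclusion log counts")


_FLAG_ORDER = (
    ("ancestry_ok", "n_dropped_ancestry"),
    ("genotyped", "n_dropped_no_genotype"),
    ("outcome_present", "n_dropped_no_outcome"),
)


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the sequential sample filters and log per-stage drop counts.

    Rows are dropped in order: failing ``ancestry_ok``, then (among
    survivors) failing ``genotyped``, then failing ``outcome_present``.
    The operation is idempotent.
    """
    for col, _ in _FLAG_ORDER:
        if col not in table.columns:
            raise ValueError(f"missing flag column: {col}")
    counts = {}
    current = table
    for col, key in _FLAG_ORDER:
        keep = current[col].astype(bool)
        counts[key] = int((~keep).sum())
        current = current.loc[keep]
    log = ExclusionLog(
        n_input=len(table),
        n_dropped_ancestry=counts["n_dropped_ancestry"],
        n_dropped_no_genotype=counts["n_dropped_no_genotype"],
        n_dropped_no_outcome=counts["n_dropped_no_outcome"],
        n_final=len(current),
    )
    return current.copy(), log
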