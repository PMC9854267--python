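"""Sensitivity specifications and binned visualization helpers.

The local linear fit assumes the outcome moves linearly in interview day
on each side of the cutoff; the quadratic specification relaxes that.
Because the depression score is skewed with a floor at zero, ln(Y+1) and
sqrt(Y) re-fits probe sensitivity to the outcome scale.  The binned
scatter summarizes the raw data for discontinuity plots: quantile-spaced
bins computed separately on each side of the cutoff, each bin contributing
its mean day and mean outcome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rdd import RDDSpec, RDDFit, _fit

__all__ = ["transform_outcome", "fit_quadratic_rdd", "binned_scatter", "plot_binned"]

TRANSFORMS = ("identity", "log1p", "sqrt")


def transform_outcome(
    table: pd.DataFrame,
    mode: str = "identity",
    outcome: str = "cesd_w3",
    out_column: str | None = None,
) -> pd.DataFrame:
    """Return a copy with the outcome transformed.

    ``log1p`` computes ln(Y + 1) (one is added because ln 0 is undefined at
    the floor of the scale); ``sqrt`` computes sqrt(Y); ``identity`` copies.
    Negative outcomes are rejected.
    """
    if mode not in TRANSFORMS:
        raise ValueError(f"unknown transform: {mode}")
    out = table.copy()
    y = out[outcome].astype(float)
    if (y.dropna() < 0).any():
        raise ValueError("outcome must be nonnegative for this transform")
    target = out_column or outcome
    if mode == "log1p":
        out[target] = np.log1p(y)
    elif mode == "sqrt":
        out[target] = np.sqrt(y)
    else:
        out[target] = y
    return out


def fit_quadratic_rdd(table: pd.DataFrame, spec: RDDSpec) -> RDDFit:
    """Order-2 sensitivity fit: adds r^2 and T:r^2 to the specification."""
    from dataclasses import replace

    return _fit(table, replace(spec, order=2))


def binned_scatter(
    table: pd.DataFrame,
    bins_per_side: int | None = None,
    target_count: int | None = None,
    outcome: str = "cesd_w3",
    running: str = "r",
    cutoff: float = 0.0,
) -> pd.DataFrame:
    """Quantile-spaced binned means, computed separately on each side.

    Exactly one of ``bins_per_side`` and ``target_count`` must be given;
    with ``target_count`` the number of bins per side is chosen so each
    bin holds approximately that many observations.  Bins partition each
    side, so per-side counts sum to the side's n.
    """
    if (bins_per_side is None) == (target_count is None):
        raise ValueError("give exactly one of bins_per_side or target_count")
    df = table[[running, outcome]].dropna()
    rows = []
    for side, mask in (
        ("pre", df[running] < cutoff),
        ("post", df[running] >= cutoff),
    ):
        sub = df.loc[mask].sort_values(running, kind="mergesort")
        n = len(sub)
        if n == 0:
            raise ValueError(f"no rows on the {side} side of the cutoff")
        k = bins_per_side if bins_per_side is not None else max(1, round(n / target_count))
        if k > n:
            raise ValueError(f"{k} bins requested but only {n} rows on the {side} side")
        for b, idx in enumerate(np.array_split(np.arange(n), k)):
            chunk = sub.iloc[idx]
            rows.append(
                {
                    "side": side,
                    "bin": b,
                    "r_mean": float(chunk[running].mean()),
                    "y_mean": float(chunk[outcome].mean()),
                    "n": len(chunk),
                }
            )
    return pd.DataFrame(rows)


def plot_binned(binned: pd.DataFrame, fit: RDDFit | None = None, ax=None):
    """Discontinuity plot: binned means plus (optionally) the fitted lines.

    Requires matplotlib; imported lazily so the package stays usable
    headless.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for side, marker in (("pre", "o"), ("post", "s")):
        sub = binned.loc[binned["side"] == side]
        ax.scatter(sub["r_mean"], sub["y_mean"], marker=marker, s=18, label=side)
    if fit is not None:
        h = fit.bandwidth
        lo = -h if h is not None else float(binned["r_mean"].min())
        hi = h if h is not None else float(binned["r_mean"].max())
        for t, (a, b) in (
            (0, (fit.params["const"], fit.params["r"])),
            (1, (fit.params["const"] + fit.params["T"],
                 fit.params["r"] + fit.params["T:r"])),
        ):
            xs = np.linspace(lo, 0.0, 50) if t == 0 else np.linspace(0.0, hi, 50)
            ax.plot(xs, a + b * xs, lw=1.5)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("days relative to cutoff")
    ax.set_ylabel("outcome (binned mean)")
    ax.legend()
    return ax
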