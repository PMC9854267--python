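#!/usr/bin/env python
"""Gene-environment moderation of the shock effect.

Re-fits the discontinuity model with a median-split moderator (mean PGS,
then variance PGS), the full interaction set (G, T*G, r*G, T*r*G), genetic
principal components, and the other standardized score as a covariate.
The T*G coefficient is the difference in the shock effect between the high
and low polygenic-score groups; with the variance (plasticity) score it is
the diathesis-stress contrast of interest.  Also reports the conditional
effect at half an SD below the mean of the continuous variance score.
"""

from dataclasses import replace
from pathlib import Path

from rdd_gxe.pipeline import MODEL_COVARIATES, PC_COLUMNS, pooled_sweep_table
from rdd_gxe.rdd import DEFAULT_BANDWIDTHS, RDDSpec, conditional_effect, fit_gxe_rdd

from importlib import import_module

sweep_mod = import_module("04_rdd_bandwidth_sweep")

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    imps = sweep_mod.load_imputations()
    base = RDDSpec(covariates=MODEL_COVARIATES, pcs=PC_COLUMNS)
    for prefix, other in (("meanPGS", "varPGS_z"), ("varPGS", "meanPGS_z")):
        spec = replace(
            base, moderator=f"{prefix}_group", moderator_coding="binary",
            other_pgs=other,
        )
        table = pooled_sweep_table(imps, spec, DEFAULT_BANDWIDTHS, fit_gxe_rdd)
        table.to_csv(OUT / f"rdd_gxe_{prefix}_sweep.csv", index=False)
        rows = table.loc[
            table["term"].isin(["T", "T:G"]),
            ["bandwidth", "term", "estimate", "se", "p", "sig"],
        ]
        print(f"\n{prefix} moderation (pooled):")
        print(rows.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    # conditional effect at G = -0.5 SD on the continuous variance score
    spec_c = replace(
        base, bandwidth=50, moderator="varPGS_z",
        moderator_coding="continuous", other_pgs="meanPGS_z",
    )
    fit = fit_gxe_rdd(imps.datasets[0], spec_c)
    ce = conditional_effect(fit, g=-0.5)
    print(
        f"\nshock effect at variance-PGS z=-0.5 (first imputation, h=50): "
        f"{ce['estimate']:.3f} (se {ce['se']:.3f}, p {ce['p']:.3f})"
    )


if __name__ == "__main__":
    main()
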