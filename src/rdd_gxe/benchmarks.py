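"""Published benchmark inputs for the study design this package emulates.

These constants come from a published quasi-experimental analysis of the
September 11, 2001 attacks and depressive symptoms in a U.S. young-adult
cohort (sharp regression discontinuity in interview date, CES-D outcome,
polygenic-score moderation).  They serve two roles:

* design inputs for the synthetic cohort generator (sample sizes, the
  treatment discontinuity, residual scale, covariate missingness rates);
* printed-table arithmetic that the analysis reproduces (sequential
  exclusion counts, standardized effect sizes).

They are inputs, never outputs: nothing in the package fits toward them.
"""

from __future__ import annotations

# --- Sample construction (sequential exclusions) -------------------------
#: Respondents completing the follow-up wave.
N_WAVE3_COMPLETED = 15_170
#: Dropped first: non-European genetic ancestry.
N_DROPPED_ANCESTRY = 10_318
#: Dropped second (among survivors): no genetic markers.
N_DROPPED_NO_GENOTYPE = 103
#: Dropped third: missing the depression outcome.
N_DROPPED_NO_OUTCOME = 23
#: Final analytical sample.
N_ANALYTICAL = 4_726

# --- Design around the cutoff --------------------------------------------
#: Interviews observed before / on-or-after the cutoff day.
N_PRE_CUTOFF = 1_098
N_POST_CUTOFF = 3_628
#: Subjects interviewed within 50 days of the cutoff (the h=50 model).
N_WITHIN_50_DAYS = 2_318
#: Running-variable support in days relative to the cutoff.
DATE_RANGE = (-50, 200)
#: Local-linear bandwidths swept in the published models (None = all data).
BANDWIDTHS = (10, 20, 30, 40, 50, None)

# --- Outcome scale --------------------------------------------------------
#: Pre-cutoff mean and SD of the 9-item CES-D score (0-27 scale).
PRE_CUTOFF_MEAN = 4.19
PRE_CUTOFF_SD = 3.87

#: Treatment (discontinuity) coefficient by bandwidth from the published
#: bandwidth sweep of the plain treatment model.
TREATMENT_COEF_BY_BANDWIDTH = {
    10: 1.45,
    20: 0.98,
    30: 0.96,
    40: 0.91,
    50: 0.89,
    None: 0.61,
}

#: Treatment x standardized-variance-PGS interaction at h=50 (binary split
#: scale in the published table; used as the generator's plasticity effect).
VARPGS_INTERACTION_H50 = 1.40

#: Level effect of the standardized mean PGS on the outcome (h=50 model).
MEANPGS_LEVEL_EFFECT = 0.20

#: High-vs-low mean-PGS group difference in the validity regression.
MEANPGS_GROUP_EFFECT = 0.53

#: The published effect-size floor: the discontinuity exceeds one-fifth of
#: the pre-cutoff SD in every local-bandwidth model.
EFFECT_SIZE_FLOOR = 0.20

# --- Covariate missingness (fraction of the analytical sample) ------------
#: Counts of imputed values per covariate, divided by the analytical n;
#: spans the published 0.2%..32% range.
MISSING_RATES = {
    "mother_edu": 746 / N_ANALYTICAL,       # 0.158
    "pvt": 207 / N_ANALYTICAL,              # 0.044
    "family_income": 831 / N_ANALYTICAL,    # 0.176
    "cesd_w1": 9 / N_ANALYTICAL,            # 0.002
    "neuroticism": 14 / N_ANALYTICAL,       # 0.003
    "extraversion": 1489 / N_ANALYTICAL,    # 0.315
    "conscientiousness": 44 / N_ANALYTICAL, # 0.009
}

#: Number of multiply imputed datasets used in the published analysis.
N_IMPUTATIONS = 20


def min_standardized_effect(
    coefficients: dict | None = None,
    sd: float = PRE_CUTOFF_SD,
    local_only: bool = True,
) -> float:
    """Smallest discontinuity, in pre-cutoff SD units, across the sweep.

    With ``local_only`` the full-sample model (bandwidth None) is excluded,
    matching the published statement that the jump exceeds one-fifth of a
    standard deviation in the local-bandwidth models.
    """
    coefs = dict(TREATMENT_COEF_BY_BANDWIDTH if coefficients is None else coefficients)
    if local_only:
        coefs.pop(None, None)
    if not coefs:
        raise ValueError("no coefficients to standardize")
    return min(c / sd for c in coefs.values())
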