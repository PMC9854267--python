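"""Synthetic cohort generator emulating the quasi-experimental study design.

The generator produces one row per subject with an integer interview day
``r`` relative to the cutoff, a sharp treatment indicator ``T = 1{r >= 0}``
(subjects interviewed on the cutoff day are treated), nine depression-screener
items whose reverse-coded sum is the outcome, baseline covariates with
realistic scales, ten genetic principal components, and two polygenic scores
drawn independently of treatment (no gene-environment correlation).

Ground truth.  The conditional mean of the *scored* outcome is, by
construction, exactly the working regression function

    E[Y | x] = alpha + tau*T + s_pre*r + (s_post - s_pre)*T*r
               + b_G * zG_mean + d_G * T * zG_var + covariate terms

so the generating parameters are the estimands the downstream discontinuity
fit targets.  The score is an integer in [0, 27]: a latent Gaussian with the
requested residual SD is discretized by round-and-clamp, and the latent
location is set by inverting the exact discretization-mean function

    g(m) = sum_{k=1..27} Phi((m - (k - 0.5)) / sigma)

so that clamping at the floor of the scale does not attenuate the
discontinuity.  Items are recovered from the score by even allocation (the
score fixes the item sum; only the sum is consumed downstream).

Randomness is a single global seed feeding a counter-based stream per
column, so any column is reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr, expit, logit
from scipy.optimize import brentq

from . import benchmarks as bm
from .phenotype import score_cesd, REVERSE_CODED_ITEMS, ITEM_COLUMNS

__all__ = [
    "SyntheticConfig",
    "generate_cohort",
    "inject_missingness",
    "true_params",
    "simulate_study_cohort",
    "make_exclusion_fixture",
    "write_cohort",
    "read_cohort",
]

SCALE_MAX = 27

#: Covariate effects on the outcome (points per unit of the *centered*
#: covariate).  Chosen once at realistic magnitudes: baseline depressive
#: symptoms and neuroticism raise follow-up symptoms, cognitive score,
#: income, maternal education, extraversion and conscientiousness lower
#: them slightly, men report fewer symptoms.
DEFAULT_COVARIATE_EFFECTS = {
    "cesd_w1": 0.20,
    "age": 0.0,
    "sex_male": -0.50,
    "mother_edu": -0.15,
    "family_income": -0.003,
    "pvt": -0.02,
    "neuroticism": 0.15,
    "extraversion": -0.05,
    "conscientiousness": -0.08,
}

#: State-of-residence labels and sampling weights; the two rare states
#: exercise the >=40-resident floor used by the balance tests.
_STATES = [f"state_{i:02d}" for i in range(1, 15)]
_STATE_P = np.array(
    [0.17, 0.14, 0.12, 0.10, 0.09, 0.08, 0.07, 0.06, 0.05, 0.045, 0.04, 0.035, 0.005, 0.005]
)
_STATE_P = _STATE_P / _STATE_P.sum()

MOTHER_EDU_LEVELS = ("below_hs", "high_school", "some_college", "college_grad")


@dataclass
class SyntheticConfig:
    """True parameter vector of the generating process.

    Defaults reproduce the emulated study's conditions: a 0.89-point jump
    at the cutoff on a 0-27 depression scale with residual SD 3.87, a flat
    pre-cutoff slope with a -0.006 points/day recovery slope after, a
    0.20-point level effect of the standardized mean PGS, a 1.40-point
    treatment interaction with the standardized variance PGS, interview
    days on [-50, 200] with the observed pre/post imbalance, and covariate
    missingness spanning 0.2%-32%.
    """

    n_subjects: int = bm.N_ANALYTICAL
    date_range: tuple[int, int] = bm.DATE_RANGE
    alpha: float = bm.PRE_CUTOFF_MEAN
    tau: float = bm.TREATMENT_COEF_BY_BANDWIDTH[50]
    slope_pre: float = 0.0
    slope_post: float = -0.006
    beta_meanG: float = bm.MEANPGS_LEVEL_EFFECT
    delta_varG: float = bm.VARPGS_INTERACTION_H50
    noise_sd: float = bm.PRE_CUTOFF_SD
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    missing_rates: dict = field(default_factory=lambda: dict(bm.MISSING_RATES))
    pre_fraction: float | None = bm.N_PRE_CUTOFF / bm.N_ANALYTICAL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        r_min, r_max = self.date_range
        if not (r_min < 0 < r_max):
            raise ValueError("date_range must satisfy r_min < 0 < r_max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, rate in self.missing_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"missing rate for {name} outside [0, 1]")
        scalars = [
            self.alpha, self.tau, self.slope_pre, self.slope_post,
            self.beta_meanG, self.delta_varG, self.noise_sd,
            *self.covariate_effects.values(),
        ]
        if self.pre_fraction is not None:
            if not (0.0 < self.pre_fraction < 1.0):
                raise ValueError("pre_fraction must lie in (0, 1)")
            scalars.append(self.pre_fraction)
        if not np.all(np.isfinite(scalars)):
            raise ValueError("non-finite value in configuration")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["date_range"] = list(self.date_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "date_range" in d:
            d["date_range"] = tuple(d["date_range"])
        return cls(**d)


def _rng(seed: int, label: str) -> np.random.Generator:
    """Counter-based per-column stream: one global seed, one CRC key per label."""
    key = zlib.crc32(label.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), key)))


# --- discretization ------------------------------------------------------

def _discretized_mean(m: np.ndarray, sigma: float) -> np.ndarray:
    """E[round(clamp(N(m, sigma), 0, 27))] = sum_k Phi((m - (k-1/2))/sigma)."""
    ks = np.arange(1, SCALE_MAX + 1) - 0.5
    return ndtr((np.asarray(m, dtype=float)[..., None] - ks) / sigma).sum(axis=-1)


def _latent_location(target: np.ndarray, sigma: float) -> np.ndarray:
    """Invert the discretization-mean function on a fine grid.

    Returns m such that the round/clamp of N(m, sigma) has mean ``target``.
    Targets are floored just inside (0, 27) -- a negative conditional mean
    is meaningless on a nonnegative scale.
    """
    target = np.clip(np.asarray(target, dtype=float), 0.02, SCALE_MAX - 0.02)
    lo = -8.0 * sigma
    hi = SCALE_MAX + 8.0 * sigma
    grid = np.linspace(lo, hi, 8192)
    g = _discretized_mean(grid, sigma)
    return np.interp(target, g, grid)


def _items_from_score(score: np.ndarray) -> np.ndarray:
    """Even allocation of an integer total in [0, 27] over nine 0-3 items.

    Item contributions (after reverse-coding) are base = s // 9 plus one for
    the first s % 9 items; reverse-coded items store 3 - contribution so the
    standard scoring rule reproduces the total exactly.
    """
    s = np.asarray(score, dtype=int)
    base = s // 9
    rem = s % 9
    contrib = base[:, None] + (np.arange(9)[None, :] < rem[:, None])
    items = contrib.copy()
    for i in REVERSE_CODED_ITEMS:
        items[:, i - 1] = 3 - contrib[:, i - 1]
    return items


# --- generation ----------------------------------------------------------

def generate_cohort(config: SyntheticConfig, r=None) -> pd.DataFrame:
    """Generate a complete (no-missingness) cohort table.

    Deterministic given ``config.seed``.  Use :func:`inject_missingness`
    (or :func:`simulate_study_cohort`) to add covariate missingness.

    Parameters
    ----------
    config : SyntheticConfig
    r : array-like of int, optional
        Explicit interview days (length ``n_subjects``); when omitted,
        days are drawn from ``date_range`` (uniform within each side,
        with the configured pre/post split).
    """
    n = config.n_subjects
    r_min, r_max = config.date_range
    seed = config.seed

    # interview day: integer days, optionally with a fixed pre/post split
    if r is not None:
        r = np.asarray(r, dtype=int)
        if r.shape != (n,):
            raise ValueError("explicit r must have length n_subjects")
    else:
        rng_r = _rng(seed, "running")
        if config.pre_fraction is None:
            r = rng_r.integers(r_min, r_max + 1, size=n)
        else:
            pre = rng_r.random(n) < config.pre_fraction
            r = np.where(
                pre,
                rng_r.integers(r_min, 0, size=n),
                rng_r.integers(0, r_max + 1, size=n),
            )
    T = (r >= 0).astype(int)

    age = 21.5 + (r - r.mean()) / 365.25 + _rng(seed, "age").normal(0.0, 1.75, n)
    sex = np.where(_rng(seed, "sex").random(n) < 0.45, "male", "female")
    mother_edu = _rng(seed, "mother_edu").choice(
        len(MOTHER_EDU_LEVELS), size=n, p=[0.09, 0.33, 0.33, 0.25]
    )
    family_income = np.round(
        np.exp(_rng(seed, "family_income").normal(3.6, 0.8, n)), 1
    )
    pvt = np.round(_rng(seed, "pvt").normal(105.2, 11.7, n), 0)
    cesd_w1 = np.clip(
        np.round(_rng(seed, "cesd_w1").normal(10.7, 7.4, n)), 0, 27
    )
    neuroticism = np.round(_rng(seed, "neuroticism").normal(11.5, 3.55, n), 0)
    extraversion = np.round(_rng(seed, "extraversion").normal(7.07, 2.76, n), 0)
    conscientiousness = np.round(
        _rng(seed, "conscientiousness").normal(9.0, 2.6, n), 0
    )
    state = np.array(_STATES)[
        _rng(seed, "state").choice(len(_STATES), size=n, p=_STATE_P)
    ]

    pcs = {
        f"pc{k}": _rng(seed, f"pc{k}").normal(0.0, 0.014, n) for k in range(1, 11)
    }

    mean_raw = _rng(seed, "meanPGS").normal(0.0, 1.0, n)
    var_raw = _rng(seed, "varPGS").normal(0.0, 1.0, n)

    def z(x):
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else x * 0.0

    mean_z = z(mean_raw)
    var_z = z(var_raw)

    cov_values = {
        "cesd_w1": cesd_w1,
        "age": age,
        "sex_male": (sex == "male").astype(float),
        "mother_edu": mother_edu.astype(float),
        "family_income": family_income,
        "pvt": pvt,
        "neuroticism": neuroticism,
        "extraversion": extraversion,
        "conscientiousness": conscientiousness,
    }
    cov_term = np.zeros(n)
    for name, beta in config.covariate_effects.items():
        if name not in cov_values:
            raise ValueError(f"unknown covariate effect: {name}")
        x = cov_values[name]
        cov_term += beta * (x - x.mean())

    target = (
        config.alpha
        + config.tau * T
        + config.slope_pre * r
        + (config.slope_post - config.slope_pre) * T * r
        + config.beta_meanG * mean_z
        + config.delta_varG * T * var_z
        + cov_term
    )

    if config.noise_sd > 0:
        m_star = _latent_location(target, config.noise_sd)
        latent = m_star + _rng(seed, "noise").normal(0.0, config.noise_sd, n)
    else:
        latent = target
    score = np.clip(np.floor(latent + 0.5), 0, SCALE_MAX).astype(int)
    items = _items_from_score(score)

    table = pd.DataFrame({"subject_id": np.arange(1, n + 1), "r": r, "T": T})
    for j, col in enumerate(ITEM_COLUMNS):
        table[col] = items[:, j]
    table["cesd_w3"] = score_cesd(items)
    table["cesd_w1"] = cesd_w1
    table["age"] = np.round(age, 2)
    table["sex"] = sex
    table["mother_edu"] = mother_edu
    table["family_income"] = family_income
    table["pvt"] = pvt
    table["neuroticism"] = neuroticism
    table["extraversion"] = extraversion
    table["conscientiousness"] = conscientiousness
    table["state"] = state
    for k in range(1, 11):
        table[f"pc{k}"] = pcs[f"pc{k}"]
    table["meanPGS_raw"] = mean_raw
    table["varPGS_raw"] = var_raw
    table["meanPGS_z"] = mean_z
    table["varPGS_z"] = var_z
    table["ancestry_ok"] = True
    table["genotyped"] = True
    table["outcome_present"] = True
    return table


#: Columns that may never be blanked by missingness injection.
PROTECTED_COLUMNS = frozenset(
    {"subject_id", "r", "T", "cesd_w3", "meanPGS_raw", "varPGS_raw",
     "meanPGS_z", "varPGS_z", "ancestry_ok", "genotyped", "outcome_present"}
    | set(ITEM_COLUMNS)
)


def inject_missingness(
    table: pd.DataFrame,
    rates: dict,
    seed: int = 0,
    mechanism: str = "mcar",
) -> pd.DataFrame:
    """Blank covariate cells at the given per-column rates.

    ``mechanism='mcar'`` blanks each targeted cell independently with its
    rate.  ``mechanism='mar'`` makes the missingness probability depend on
    observables (sex and baseline depressive symptoms) through a logistic
    model whose intercept is calibrated so the marginal rate still equals
    the requested rate.  Outcome and design columns are never blanked.
    """
    if mechanism not in ("mcar", "mar"):
        raise ValueError(f"unknown mechanism: {mechanism}")
    out = table.copy()
    for col, rate in rates.items():
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"missing rate for {col} outside [0, 1]")
        if col not in out.columns:
            raise ValueError(f"no such column: {col}")
        if col in PROTECTED_COLUMNS:
            raise ValueError(f"column {col} is protected from missingness")
        if rate == 0.0:
            continue
        rng = _rng(seed, f"miss:{col}")
        n = len(out)
        if rate == 1.0:
            mask = np.ones(n, dtype=bool)
        elif mechanism == "mcar":
            mask = rng.random(n) < rate
        else:
            male = (out["sex"] == "male").astype(float).to_numpy()
            w1 = out["cesd_w1"].to_numpy(dtype=float)
            w1 = np.where(np.isnan(w1), np.nanmean(w1), w1)
            lin = 0.5 * (w1 - w1.mean()) / max(w1.std(ddof=0), 1e-12) + 0.3 * male

            def marginal(c):
                return expit(c + lin).mean() - rate

            c0 = brentq(marginal, logit(rate) - 6, logit(rate) + 6)
            mask = rng.random(n) < expit(c0 + lin)
        if out[col].dtype.kind in "iub":
            out[col] = out[col].astype(float)
        out.loc[mask, col] = np.nan
    return out


def simulate_study_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a cohort and apply the configured covariate missingness."""
    table = generate_cohort(config)
    if config.missing_rates:
        table = inject_missingness(table, config.missing_rates, seed=config.seed)
    return table


def true_params(config: SyntheticConfig) -> dict:
    """Generating values keyed by the working-model coefficient names.

    beta1 is the discontinuity (treatment effect at the cutoff), beta2 the
    pre-cutoff slope, beta3 the treatment x day interaction (post minus pre
    slope), beta_G the standardized mean-PGS level effect, and beta5 the
    treatment x standardized variance-PGS interaction.
    """
    return {
        "alpha": config.alpha,
        "beta1": config.tau,
        "beta2": config.slope_pre,
        "beta3": config.slope_post - config.slope_pre,
        "beta_G": config.beta_meanG,
        "beta5": config.delta_varG,
        "noise_sd": config.noise_sd,
    }


def make_exclusion_fixture(
    n_input: int = bm.N_WAVE3_COMPLETED,
    n_ancestry: int = bm.N_DROPPED_ANCESTRY,
    n_no_genotype: int = bm.N_DROPPED_NO_GENOTYPE,
    n_no_outcome: int = bm.N_DROPPED_NO_OUTCOME,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag table with exact sequential exclusion counts.

    Among all ``n_input`` rows exactly ``n_ancestry`` fail the ancestry
    flag; among the survivors exactly ``n_no_genotype`` lack genotype data;
    among the remaining survivors exactly ``n_no_outcome`` lack the
    outcome.  Row order is shuffled deterministically.
    """
    if n_ancestry + n_no_genotype + n_no_outcome > n_input:
        raise ValueError("exclusion counts exceed n_input")
    ancestry_ok = np.ones(n_input, dtype=bool)
    genotyped = np.ones(n_input, dtype=bool)
    outcome_present = np.ones(n_input, dtype=bool)
    ancestry_ok[:n_ancestry] = False
    genotyped[n_ancestry : n_ancestry + n_no_genotype] = False
    outcome_present[
        n_ancestry + n_no_genotype : n_ancestry + n_no_genotype + n_no_outcome
    ] = False
    table = pd.DataFrame(
        {
            "subject_id": np.arange(1, n_input + 1),
            "ancestry_ok": ancestry_ok,
            "genotyped": genotyped,
            "outcome_present": outcome_present,
        }
    )
    order = _rng(seed, "exclusion_fixture").permutation(n_input)
    return table.iloc[order].reset_index(drop=True)


# --- IO -------------------------------------------------------------------

def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV with a fixed header (no index column)."""
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    return pd.read_csv(path)


def config_to_yaml(config: SyntheticConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def config_from_yaml(path) -> SyntheticConfig:
    import yaml

    with open(path) as fh:
        return SyntheticConfig.from_dict(yaml.safe_load(fh))
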