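"""Synthetic patient cohort generation.

Produces a cohort of patients with demographic/diagnostic covariates, a
binary mood-instability exposure, presentation dates spanning seven fiscal
years (so that nested 12-60-month follow-up windows have the configured
eligible counts exactly), and per-window hospitalisation and prescription
outcomes generated under known adjusted effect sizes.

The generative models are chosen so that each follow-up window's outcome has
*exactly* the marginal regression model a multivariable fit assumes:

* admission counts: per-year Poisson increments share a patient-level gamma
  frailty, so every cumulative window count is NB2 with the window's
  log-linear mean and common dispersion ``alpha``;
* binary outcomes: sequential conditional hazards reproduce each window's
  logistic marginal while keeping flags monotone across windows;
* inpatient days: per-year Gamma increments with an identity-link linear
  mean, so OLS is consistent for the exposure coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import defaults as D

__all__ = [
    "ConfigurationError",
    "CohortConfig",
    "sample_covariates",
    "calibrate_intercept",
    "covariate_linear_predictor",
    "assign_mood_instability",
    "sample_presentation_dates",
    "simulate_outcomes",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]


class ConfigurationError(ValueError):
    """Raised when generator configuration is internally inconsistent."""


@dataclass
class CohortConfig:
    """Configuration for the synthetic cohort generator.

    Parameters
    ----------
    n : cohort size (12-month window size; later windows scale down).
    mode : ``"model"`` draws exposure from a calibrated logistic model with
        the default adjusted odds ratios; ``"stratified"`` draws it from
        per-diagnosis prevalences.
    target_prevalence : marginal exposure prevalence the model-mode intercept
        is calibrated to.
    seed : master seed; per-stage child seeds are derived deterministically.
    """

    n: int = D.N_REFERENCE
    mode: str = "model"
    seed: int = 0
    target_prevalence: float = D.TARGET_PREVALENCE
    mi_log_odds: Mapping[tuple, float] = field(default_factory=lambda: dict(D.MI_LOG_ODDS))
    stratified_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(D.MI_PREVALENCE_BY_DIAGNOSIS)
    )
    covariate_counts: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in D.COVARIATE_COUNTS.items()}
    )
    presentation_counts: Mapping[int, int] | None = None
    dispersion: float = D.NB_DISPERSION
    days_shape: float = D.DAYS_GAMMA_SHAPE
    days_shape_mi: float = D.DAYS_GAMMA_SHAPE_MI

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError("cohort size must be >= 1")
        if self.mode not in ("model", "stratified"):
            raise ConfigurationError(f"unknown exposure mode {self.mode!r}")
        if self.dispersion <= 0:
            raise ConfigurationError("NB dispersion must be positive")
        if not 0 < self.target_prevalence < 1:
            raise ConfigurationError("target prevalence must lie in (0, 1)")

    def window_counts(self) -> dict[int, int]:
        counts = (
            dict(self.presentation_counts)
            if self.presentation_counts is not None
            else D.scaled_presentation_counts(self.n)
        )
        prev = None
        for w in D.WINDOWS:
            if w not in counts:
                raise ConfigurationError(f"missing presentation count for window {w}")
            if prev is not None and counts[w] > prev:
                raise ConfigurationError("presentation counts must be non-increasing")
            prev = counts[w]
        if counts[12] != self.n:
            raise ConfigurationError("12-month eligible count must equal cohort size")
        return counts


# ---------------------------------------------------------------------------
# Covariates and exposure
# ---------------------------------------------------------------------------


def _normalise(table: Mapping[str, float], name: str) -> tuple[list[str], np.ndarray]:
    levels = list(table)
    weights = np.asarray([table[l] for l in levels], dtype=float)
    if (weights < 0).any():
        raise ConfigurationError(f"negative weight in {name} distribution")
    total = weights.sum()
    if total <= 0:
        raise ConfigurationError(f"{name} distribution sums to zero")
    probs = weights / total
    # counts tables always renormalise cleanly; explicit probability tables
    # must sum to ~1 to catch typos
    if weights.max() <= 1.0 and abs(total - 1.0) > 1e-6:
        raise ConfigurationError(f"{name} probabilities sum to {total}, expected 1")
    return levels, probs


def sample_covariates(
    n: int,
    rng: np.random.Generator,
    covariate_counts: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Draw ``n`` covariate profiles with independent marginals."""
    tables = covariate_counts or D.COVARIATE_COUNTS
    data = {}
    for cov in D.COVARIATES:
        levels, probs = _normalise(tables[cov], cov)
        data[cov] = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(data)


def covariate_linear_predictor(
    profiles: pd.DataFrame,
    effects: Mapping[tuple, float],
    covariates: tuple = D.COVARIATES,
    references: Mapping[str, str] = D.REFERENCE_LEVELS,
) -> np.ndarray:
    """Sum per-level effects over covariate columns (reference levels = 0).

    A non-reference level present in the data but absent from ``effects`` is
    a configuration error, per the generator contract.
    """
    eta = np.zeros(len(profiles))
    for cov in covariates:
        col = profiles[cov].to_numpy()
        for level in np.unique(col):
            if level == references[cov]:
                continue
            if (cov, level) not in effects:
                raise ConfigurationError(f"missing effect for {cov}={level}")
            eta[col == level] += effects[(cov, level)]
    return eta


def calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept ``b0`` such that ``mean(expit(b0 + eta)) == target``.

    Solved by monotone root-finding; exact to 1e-10 in the mean probability.
    """
    if not 0 < target < 1:
        raise ConfigurationError("target prevalence must lie strictly in (0, 1)")
    eta = np.asarray(eta, dtype=float)

    def f(b0):
        return expit(b0 + eta).mean() - target

    return brentq(f, -50.0, 50.0, xtol=1e-12)


def assign_mood_instability(
    profiles: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw the binary exposure under the configured mode."""
    if config.mode == "model":
        eta = covariate_linear_predictor(profiles, config.mi_log_odds)
        b0 = calibrate_intercept(eta, config.target_prevalence)
        p = expit(b0 + eta)
    else:
        prev = config.stratified_prevalence
        missing = set(profiles["diagnosis"]) - set(prev)
        if missing:
            raise ConfigurationError(f"missing stratified prevalence for {sorted(missing)}")
        p = profiles["diagnosis"].map(prev).to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ConfigurationError("exposure probabilities outside [0, 1]")
    return (rng.random(len(profiles)) < p).astype(np.int8)


# ---------------------------------------------------------------------------
# Presentation dates
# ---------------------------------------------------------------------------


def sample_presentation_dates(
    config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Dates such that each window's eligible count is met exactly.

    Patients are assigned to fiscal-year strata (1 April - 31 March) whose
    sizes are the successive differences of the window counts; dates are
    uniform within each stratum. The earliest three fiscal years share the
    longest-window count as evenly as possible.
    """
    counts = config.window_counts()
    n = config.n
    # strata sizes, earliest fiscal year first
    diffs = [counts[48] - counts[60], counts[36] - counts[48],
             counts[24] - counts[36], counts[12] - counts[24]]
    oldest = counts[60]
    base, rem = divmod(oldest, 3)
    strata = [base + (1 if i < rem else 0) for i in range(3)] + diffs
    assert sum(strata) == n
    perm = rng.permutation(n)
    dates = np.empty(n, dtype="datetime64[D]")
    start_idx = 0
    for year_offset, size in enumerate(strata):
        fy_start = np.datetime64(f"{D.FIRST_FISCAL_YEAR + year_offset}-04-01")
        ndays = (
            np.datetime64(f"{D.FIRST_FISCAL_YEAR + year_offset + 1}-04-01") - fy_start
        ).astype(int)
        idx = perm[start_idx : start_idx + size]
        dates[idx] = fy_start + rng.integers(0, ndays, size=size).astype("timedelta64[D]")
        start_idx += size
    return dates


def window_cutoff(window: int) -> np.datetime64:
    """Last presentation date eligible for a follow-up window (in months)."""
    if window not in D.WINDOWS:
        raise ValueError(f"unknown follow-up window {window}")
    year = D.FIRST_FISCAL_YEAR + D.N_FISCAL_YEARS - window // 12
    return np.datetime64(f"{year + 1}-03-31")


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------


def _binary_outcome(
    mi: np.ndarray,
    cov_logit: np.ndarray,
    baselines: Mapping[int, float],
    ors: Mapping[int, float],
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Monotone binary flags whose window-w marginal is the logistic model.

    Sequential conditional hazards; where a patient's implied window
    probability dips (possible for anchor/OR combinations that cross), the
    hazard is floored at zero, freezing that patient's marginal at its
    running maximum.
    """
    n = len(mi)
    no_mi = mi == 0
    flag = np.zeros(n, dtype=bool)
    attained = np.zeros(n)
    out = {}
    for w in D.WINDOWS:
        target = baselines[w]
        b0 = brentq(
            lambda b: expit(b + cov_logit[no_mi]).mean() - target, -30.0, 30.0, xtol=1e-12
        )
        p = expit(b0 + np.log(ors[w]) * mi + cov_logit)
        hazard = np.clip((p - attained) / (1.0 - attained), 0.0, 1.0)
        flag |= rng.random(n) < hazard
        attained = np.maximum(attained, p)
        out[w] = flag.astype(np.int8)
    return out


def simulate_outcomes(
    cohort: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    days_beta: Mapping[int, float] | None = None,
    admissions_irr: Mapping[int, float] | None = None,
    compulsory_or: Mapping[int, float] | None = None,
    antipsychotic_or: Mapping[int, float] | None = None,
    mood_stabiliser_or: Mapping[int, float] | None = None,
    covariate_log_effects: Mapping[tuple, float] | None = None,
    days_covariate_effects: Mapping[tuple, float] | None = None,
) -> pd.DataFrame:
    """Attach per-window outcome columns to ``cohort`` (must carry mi_true)."""
    days_beta = days_beta or D.DAYS_BETA_MI
    admissions_irr = admissions_irr or D.ADMISSIONS_IRR_MI
    compulsory_or = compulsory_or or D.COMPULSORY_OR_MI
    antipsychotic_or = antipsychotic_or or D.ANTIPSYCHOTIC_OR_MI
    mood_stabiliser_or = mood_stabiliser_or or D.MOOD_STABILISER_OR_MI
    log_eff = (
        dict(D.OUTCOME_COVARIATE_LOG_EFFECTS)
        if covariate_log_effects is None
        else dict(covariate_log_effects)
    )
    days_eff = (
        dict(D.DAYS_COVARIATE_EFFECTS_60)
        if days_covariate_effects is None
        else dict(days_covariate_effects)
    )

    n = len(cohort)
    mi = cohort["mi_true"].to_numpy()
    no_mi = mi == 0
    if no_mi.all() or not no_mi.any():
        raise ConfigurationError("both exposure groups must be non-empty")

    # covariate predictors; levels without a stated effect default to 0 here
    # (the MI exposure model is strict; outcome covariate effects are a
    # sparse optional convention)
    def sparse_eta(effects):
        eta = np.zeros(n)
        for (cov, level), v in effects.items():
            eta[cohort[cov].to_numpy() == level] += v
        return eta

    cov_log = sparse_eta(log_eff)
    cov_days_60 = sparse_eta(days_eff)

    # --- admission counts: shared gamma frailty + per-year Poisson increments
    alpha = config.dispersion
    frailty = rng.gamma(1.0 / alpha, alpha, size=n)
    prev_mu = np.zeros(n)
    cum = np.zeros(n, dtype=np.int64)
    norm = np.exp(cov_log[no_mi]).mean()
    for w in D.WINDOWS:
        mu = (D.ADMISSIONS_BASELINE[w] / norm) * np.exp(
            np.log(admissions_irr[w]) * mi + cov_log
        )
        dmu = mu - prev_mu
        if (dmu < -1e-9).any():
            raise ConfigurationError("admission mean decreases across windows")
        cum = cum + rng.poisson(frailty * np.clip(dmu, 0.0, None))
        cohort[f"admissions_{w}"] = cum
        prev_mu = mu

    # --- binary outcomes
    for name, baselines, ors in (
        ("compulsory", D.COMPULSORY_BASELINE, compulsory_or),
        ("antipsychotic", D.ANTIPSYCHOTIC_BASELINE, antipsychotic_or),
        ("mood_stabiliser", D.MOOD_STABILISER_BASELINE, mood_stabiliser_or),
    ):
        flags = _binary_outcome(mi, cov_log, baselines, ors, rng)
        for w, v in flags.items():
            cohort[f"{name}_{w}"] = v

    # --- inpatient days: identity-link Gamma increments (group-specific
    # shape so both groups' day SDs match the descriptive anchors)
    shape = np.where(mi == 1, config.days_shape_mi, config.days_shape)
    prev_m = np.zeros(n)
    cum_days = np.zeros(n)
    for w in D.WINDOWS:
        scale_w = D.DAYS_BASELINE[w] / D.DAYS_BASELINE[60]
        cov_w = cov_days_60 * scale_w
        b0 = D.DAYS_BASELINE[w] - cov_w[no_mi].mean()
        m = b0 + days_beta[w] * mi + cov_w
        if (m <= 0).any():
            raise ConfigurationError(
                "identity-link days mean non-positive for some covariate combination"
            )
        dm = m - prev_m
        if (dm <= 0).any():
            raise ConfigurationError("days mean must increase across windows")
        cum_days = cum_days + rng.gamma(shape, dm / shape)
        cohort[f"inpatient_days_{w}"] = cum_days
        prev_m = m
    return cohort


# ---------------------------------------------------------------------------
# Orchestration and IO
# ---------------------------------------------------------------------------

_STAGES = ("covariates", "exposure", "dates", "outcomes", "notes", "annotation", "classifier")


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([master_seed, idx]).generate_state(1)[0] % (2**31))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, stage))


def generate_cohort(config: CohortConfig, outcomes: bool = True) -> pd.DataFrame:
    """Generate the full synthetic cohort as a DataFrame, one row per patient."""
    profiles = sample_covariates(
        config.n, stage_rng(config.seed, "covariates"), config.covariate_counts
    )
    cohort = profiles.copy()
    cohort.insert(0, "patient_id", np.arange(config.n))
    cohort["mi_true"] = assign_mood_instability(
        profiles, config, stage_rng(config.seed, "exposure")
    )
    cohort["presentation_date"] = sample_presentation_dates(
        config, stage_rng(config.seed, "dates")
    )
    if outcomes:
        simulate_outcomes(cohort, config, stage_rng(config.seed, "outcomes"))
    return cohort


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    out["presentation_date"] = pd.to_datetime(out["presentation_date"]).dt.strftime(
        "%Y-%m-%d"
    )
    out.to_csv(path, index=False)


REQUIRED_COLUMNS = ("patient_id", "presentation_date", "mi_true") + D.COVARIATES


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"cohort file missing column(s): {', '.join(missing)}")
    df["presentation_date"] = pd.to_datetime(df["presentation_date"]).to_numpy(
        dtype="datetime64[D]"
    )
    return df
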