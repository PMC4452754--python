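"""Default generator parameters.

The default configuration emulates a large urban secondary mental-healthcare
cohort: the covariate mix, exposure prevalences, adjusted odds ratios for
documented mood instability, and the 5-year hospitalisation and prescription
outcome anchors are all stated here explicitly so that every simulation
parameter is inspectable and overridable.

All odds ratios / rate ratios below are *adjusted* (direct) effects; the
generator draws covariates independently, so these are also the effects a
correctly specified multivariable fit should recover.
"""

from __future__ import annotations

import math

N_REFERENCE = 27_704

# ---------------------------------------------------------------------------
# Covariate marginals (counts at the reference cohort size)
# ---------------------------------------------------------------------------

AGE_COUNTS = {
    "16-25": 7133,
    "26-35": 7842,
    "36-45": 6611,
    "46-55": 4066,
    "56-65": 2052,
}
GENDER_COUNTS = {"male": 12_532, "female": 15_172}
ETHNICITY_COUNTS = {"White": 15_691, "Asian": 1511, "Black": 5203, "Other": 5299}
MARITAL_COUNTS = {
    "married_cohabiting": 5115,
    "divorced_separated": 2391,
    "single": 16_078,
    "not_recorded": 4120,
}
DIAGNOSIS_COUNTS = {
    "schizophrenia_related": 5860,
    "bipolar": 2691,
    "psychotic_depression": 767,
    "personality_disorder": 2311,
    "unipolar_depression": 14_192,
    "other_affective": 1883,
}

COVARIATE_COUNTS = {
    "age_band": AGE_COUNTS,
    "gender": GENDER_COUNTS,
    "ethnicity": ETHNICITY_COUNTS,
    "marital_status": MARITAL_COUNTS,
    "diagnosis": DIAGNOSIS_COUNTS,
}

COVARIATES = tuple(COVARIATE_COUNTS)

# Reference level per covariate = the most prevalent category.
REFERENCE_LEVELS = {
    "age_band": "26-35",
    "gender": "female",
    "ethnicity": "White",
    "marital_status": "single",
    "diagnosis": "unipolar_depression",
}

# ---------------------------------------------------------------------------
# Mood-instability exposure model
# ---------------------------------------------------------------------------

TARGET_PREVALENCE = 0.121  # marginal documented-MI prevalence within 1 month

# Adjusted odds ratios (reference levels omitted; they carry OR 1).
MI_ADJUSTED_OR = {
    ("age_band", "16-25"): 1.32,
    ("age_band", "36-45"): 0.73,
    ("age_band", "46-55"): 0.67,
    ("age_band", "56-65"): 0.50,
    ("gender", "male"): 0.75,
    ("ethnicity", "Asian"): 0.93,
    ("ethnicity", "Black"): 0.95,
    ("ethnicity", "Other"): 0.80,
    ("marital_status", "married_cohabiting"): 1.16,
    ("marital_status", "divorced_separated"): 1.18,
    ("marital_status", "not_recorded"): 0.82,
    ("diagnosis", "schizophrenia_related"): 2.23,
    ("diagnosis", "bipolar"): 3.42,
    ("diagnosis", "psychotic_depression"): 2.00,
    ("diagnosis", "personality_disorder"): 2.39,
    ("diagnosis", "other_affective"): 1.35,
}

MI_LOG_ODDS = {key: math.log(v) for key, v in MI_ADJUSTED_OR.items()}

# Per-diagnosis documented prevalence for the stratified generator mode.
MI_PREVALENCE_BY_DIAGNOSIS = {
    "schizophrenia_related": 0.155,
    "bipolar": 0.226,
    "psychotic_depression": 0.140,
    "personality_disorder": 0.178,
    "unipolar_depression": 0.080,
    "other_affective": 0.106,
}

# ---------------------------------------------------------------------------
# Follow-up windows and eligibility counts
# ---------------------------------------------------------------------------

WINDOWS = (12, 24, 36, 48, 60)

# Number of patients presenting early enough to be observed for each window,
# at the reference cohort size (presentation spans fiscal years 2006/07
# through 2012/13; the window-w cutoff is 31 March of 2014 - w/12).
PRESENTATION_COUNTS = {12: 27_704, 24: 24_848, 36: 21_188, 48: 17_130, 60: 13_032}

FIRST_FISCAL_YEAR = 2006
N_FISCAL_YEARS = 7

# ---------------------------------------------------------------------------
# Outcome generators (per follow-up window)
# ---------------------------------------------------------------------------
# Baselines are anchored to the no-exposure group mean/probability; exposure
# effects are the adjusted effect sizes the multivariable fits should recover.

DAYS_BASELINE = {12: 8.6, 24: 13.9, 36: 18.0, 48: 21.7, 60: 25.5}
DAYS_BETA_MI = {12: 13.4, 24: 13.9, 36: 13.5, 48: 15.9, 60: 18.5}

ADMISSIONS_BASELINE = {12: 0.21, 24: 0.26, 36: 0.31, 48: 0.37, 60: 0.43}
ADMISSIONS_IRR_MI = {12: 2.62, 24: 2.33, 36: 2.17, 48: 2.07, 60: 1.95}

COMPULSORY_BASELINE = {12: 0.074, 24: 0.090, 36: 0.099, 48: 0.109, 60: 0.120}
COMPULSORY_OR_MI = {12: 4.55, 24: 3.77, 36: 3.39, 48: 3.02, 60: 2.73}

ANTIPSYCHOTIC_BASELINE = {12: 0.278, 24: 0.307, 36: 0.325, 48: 0.343, 60: 0.358}
ANTIPSYCHOTIC_OR_MI = {12: 2.71, 24: 2.40, 36: 2.24, 48: 2.14, 60: 2.03}

MOOD_STABILISER_BASELINE = {12: 0.080, 24: 0.095, 36: 0.106, 48: 0.120, 60: 0.127}
MOOD_STABILISER_OR_MI = {12: 2.26, 24: 2.09, 36: 2.06, 48: 1.90, 60: 2.07}

# NB2 dispersion: solve var = mu + alpha*mu^2 at the 0-60 no-exposure
# anchors mu = 0.43, var = 1.19  ->  alpha = (1.19 - 0.43) / 0.43^2.
NB_DISPERSION = (1.19 - 0.43) / 0.43**2  # ~ 4.11

# Gamma shapes for per-year inpatient-day increments, per exposure group;
# chosen so the summed 0-60 SDs are ~105 days (unexposed) and ~139 days
# (exposed) - heavily right-skewed, most patients near zero days, as in
# routine inpatient data.
DAYS_GAMMA_SHAPE = 0.0134
DAYS_GAMMA_SHAPE_MI = 0.032

# Modest covariate effects on outcomes so that adjustment is consequential.
# Log (rate/odds) scale for count and binary outcomes; additive days at the
# 0-60 window for the identity-link days model (scaled to shorter windows in
# proportion to the baseline anchor).
OUTCOME_COVARIATE_LOG_EFFECTS = {
    ("diagnosis", "schizophrenia_related"): 0.45,
    ("diagnosis", "bipolar"): 0.35,
    ("diagnosis", "psychotic_depression"): 0.35,
    ("diagnosis", "personality_disorder"): 0.25,
    ("age_band", "16-25"): 0.15,
    ("age_band", "56-65"): -0.15,
}

DAYS_COVARIATE_EFFECTS_60 = {
    ("diagnosis", "schizophrenia_related"): 10.0,
    ("diagnosis", "bipolar"): 6.0,
    ("diagnosis", "psychotic_depression"): 6.0,
    ("diagnosis", "personality_disorder"): 4.0,
    ("age_band", "16-25"): 3.0,
    ("age_band", "56-65"): -3.0,
}


def scaled_presentation_counts(n: int) -> dict[int, int]:
    """Scale the default window eligibility counts to a cohort of size ``n``.

    The 12-month count is pinned to ``n``; later windows are rounded
    proportionally and forced non-increasing.
    """
    counts = {}
    prev = n
    for w in WINDOWS:
        c = n if w == 12 else round(PRESENTATION_COUNTS[w] * n / N_REFERENCE)
        c = min(c, prev)
        counts[w] = c
        prev = c
    return counts
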