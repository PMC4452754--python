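# Methods

This note documents the generative models, estimators and numerical choices
behind `moodmine`, and what the package's tests do and do not establish.

## Study design being emulated

A retrospective EHR cohort study: adults presenting to secondary mental
healthcare over seven fiscal years (1 April boundaries) with a psychotic,
affective or personality disorder; exposure = any documented instability of
mood, affect or emotion within 1 month of presentation, extracted from
free-text notes by three keyword-specific NLP applications; outcomes over
nested 12/24/36/48/60-month follow-up windows, with eligibility determined by
presentation date (only patients presenting early enough are observed for the
longer windows). Everything here is synthetic: no real patient data are used
or included.

## Cohort generator

**Covariates.** Age band, gender, ethnicity, marital status and diagnosis are
drawn independently with fixed marginals (stated as counts at the reference
size n = 27 704 in `defaults.py`). Independence is a deliberate
simplification: only the exposure depends on covariates, so the planted
adjusted effects are the recoverable direct effects and the fitted models
are correctly specified. Real cohorts have correlated covariates; tests on
this generator therefore say nothing about confounding structure beyond what
the adjustment set captures.

**Exposure.** Two modes.
*Model mode*: Bernoulli with logit = β₀ + Σ log-OR terms (defaults: the
adjusted odds ratios in `defaults.MI_ADJUSTED_OR`; reference levels are the
most prevalent categories). β₀ is calibrated by Brent root-finding so the
*mean predicted probability over the drawn profiles* equals the target
prevalence (default 12.1 %) to 1e-8 — prevalence is matched in expectation,
realisations vary binomially.
*Stratified mode*: Bernoulli with per-diagnosis probabilities (8.0 %–22.6 %);
the implied overall prevalence under the default diagnosis mix is ≈ 12.2 %.

**Presentation dates.** Window eligibility counts (27 704 / 24 848 / 21 188 /
17 130 / 13 032 at the reference size, scaled proportionally otherwise) are
met *exactly*: stratum sizes are the successive differences of the counts,
patients are assigned to fiscal-year strata by random permutation, and dates
are uniform within each stratum. The three earliest years share the
longest-window count as evenly as possible (the counts identify only their
sum).

**Admission counts.** Per-patient gamma frailty G ~ Gamma(1/α, α)
(mean 1, variance α) shared across years, with per-year Poisson increments
Poisson(G·Δμ). Mixing Poisson over the gamma frailty makes the cumulative
count at *every* window exactly NB2 with that window's log-linear mean
μ_w(x) = exp(b₀_w + log IRR_w·MI + covariate effects) and common dispersion
α, while cumulative sums are monotone by construction. α defaults to
(1.19 − 0.43)/0.43² ≈ 4.11, the value implied by the 0–60-month no-exposure
mean/variance anchors, and is shared across windows (one anchor available).
b₀_w is calibrated so the realised no-exposure group mean equals the window's
anchor.

**Binary outcomes** (compulsory admission, antipsychotic, mood stabiliser).
Each window's marginal is a logistic model with the window's anchor
(no-exposure probability) and exposure log-OR. Monotone "ever" flags are
generated by sequential conditional hazards
h_w = (p_w − p_{w−1})/(1 − p_{w−1}); where a patient's implied p_w dips
slightly below its running maximum (the published compulsory-admission
anchor/OR sequence implies a ≈ 2×10⁻⁴ dip around 36–48 months) the hazard is
floored at zero, freezing that marginal at its maximum — a distortion far
below sampling noise.

**Inpatient days.** Identity-link Gamma: per-year increments with mean
Δ(b₀_w + β_w·MI + covariate effects); any non-positive mean or increment is a
configuration error (rejected, never clipped). Days are deliberately
*decoupled* from the admission count so that OLS is consistent for β; real
inpatient days are the sum of lengths of stay over admissions, and this
coupling is not modelled. Gamma shapes (0.0134 unexposed, 0.032 exposed) are
set so the 0–60-month day SDs match the descriptive anchors (~105 and ~139
days): heavy right skew, most patients near zero.

**Covariate effects on outcomes** default to modest diagnosis and age effects
(log-scale 0.15–0.45; up to ±10 additional days at 0–60 months) so that
adjustment is consequential; all are overridable, and days effects scale with
the window baseline so increments stay positive.

**Seeds.** One master seed; per-stage child seeds derived via
`SeedSequence([master, stage_index])`. Identical config + seed gives
byte-identical CSV output.

## Note generator and corpus

Notes are dated sentences from authored template banks (the field's standard
instability lexicon: unstable, labile, fluctuating, erratic, volatile,
changeable, swings, plus the mandatory descriptors instability, dysfunction,
irregular, and fixed misspellings of each). Exposure-positive patients
receive ≥ 1 positive sentence dated within the 30-day documentation window
with probability `documentation_sensitivity` (default 1.0 — the true rate at
which clinicians document the symptom is unknown and is expressed as this
parameter); exposure-negative patients never receive a positive sentence.
Distractors include negated mentions ("no evidence of mood instability" —
candidates the gazetteer cannot reject), stable-mood statements and unrelated
filler. Keywords are never misspelled (only modifiers), so every positive
sentence remains a gazetteer candidate; this underpins the end-to-end oracle:
with documentation sensitivity 1 and a perfect classifier, extracted patient
flags equal the generator's truth exactly.

The standalone classifier corpus (default 3 000 sentences per construct)
additionally contains a *temporally ambiguous* family — "previously stable
mood now unstable" (positive) vs "previously unstable mood now stable"
(negative), identical bags of words, 60 % positive. A bag-of-words model
cannot separate these, so they form a single mid-probability cluster: baseline
(θ = 0.5) precision lands in the mid-80s, and raising the threshold to the
calibrated value excludes the cluster, pushing precision above 90 % at a real
recall cost (≈ 0.70–0.80). This realises the intended operating regime
(baseline precision > 80 %, thresholded ≥ 90 %, small recall reduction)
rather than a trivially separable corpus. The corpus is still far simpler
than clinical text — finite vocabulary, sentence-level independence, no
discourse context — so classifier results here demonstrate the calibration
machinery, not clinical NLP performance.

## Classifier

Token counts (lowercase, split on non-alphanumerics; no stemming) feed a
linear SVM (hinge loss, L2, fixed C = 1 — regularisation is not tuned per
run). Probabilities are Platt-scaled: a 1-D logistic fit of 5-fold
cross-validated decision scores on labels, giving a monotone score→probability
map (slope forced positive; the monotonicity is the tested contract, the
specific mapping is not). One active-learning round selects the k = 100 pool
sentences with probability nearest 0.5 (ties to the lower sentence id); the
generator's labels stand in for the human annotator. Splits are 60/20/20
train/validation/reference by MD5 hash of the sentence id; any train/eval id
overlap is a hard leakage error. Threshold calibration picks the smallest
observed validation probability whose prediction set reaches the target
precision (default 0.90), or fails loudly naming the best achievable value.

## Agreement

Two-rater, two-class Cohen's κ = (p_o − p_e)/(1 − p_e) with
p_e = Σ_c p₁(c)p₂(c); both-raters-constant-and-identical is a degenerate case
(κ undefined) and raises. A simulated second annotator with class-specific
flip rates (5 % / 3 %) exercises the machinery, since no human double
annotation exists for synthetic text.

## Outcome models

Logistic and NB2 fits by maximum likelihood (statsmodels; NB started from
Poisson estimates with a method-of-moments dispersion, BFGS, convergence
checked and non-convergence raised). Wald 95 % CIs on the coefficient scale,
exponentiated for ORs/IRRs. The days model is OLS with HC1
heteroskedasticity-robust standard errors: the identity-link Gamma outcome
has variance growing with the mean, and conventional OLS errors would
undercover the planted β — robust Wald CIs keep the coverage property honest.
ZINB (logit zero model: intercept + exposure; NB2 count model) is a
sensitivity analysis; the Vuong statistic √n·mean(d)/sd(d) over
per-observation log-likelihood differences (computed directly from the fitted
parameters) compares it with the plain NB, positive values favouring the
zero-inflated model; zero variance of the differences is a degenerate
comparison and raises. No multiple-testing correction is applied (raw
p-values are reported). The marital-status sensitivity refit drops patients
with unrecorded status; dummy columns for levels absent from a subset are
omitted from the design.

## Problem sizes and expected precision

Tests run the exposure-model and outcome recovery at the full reference sizes
(n = 27 704; 13 032 eligible at 0–60 months), where each planted effect is
expected inside its published 95 % CI — individually ~95 % probable per seed,
so the joint all-effects check is a strict, occasionally-failing criterion by
construction. The CI-coverage property uses 20 seeds at quarter scale
(n = 6 926), since Wald coverage is scale-free asymptotically; the Vuong
power check uses a purpose-built simulation (n = 8 000, structural-zero rate
0.2, baseline mean 1.5) because zero inflation is statistically invisible on
top of a count model whose baseline zero probability already exceeds 0.8.
The classifier suite uses the default 3 000-sentence corpora over 5 seeds.

## Known limitations

- Covariate independence and sparse outcome covariate effects are
  conventions, not estimates; only marginals and exposure/outcome effect
  sizes are anchored.
- Days and admissions are generated independently given covariates and
  exposure (a "linked" length-of-stay model is not the recovery surface).
- The documentation process (which patients' symptoms get written down, and
  when) is reduced to a single sensitivity parameter.
- Synthetic text has none of the ambiguity, ellipsis or cross-sentence
  negation of clinical prose; precision/recall numbers here validate the
  pipeline's calibration logic only.
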