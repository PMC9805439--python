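# Methods

## The score and its evaluation

The package implements a peri-operative composite risk score for
ovarian-cancer patients treated with primary debulking surgery (PDS).
Eight parameters — age, pre-treatment CA125, CRP and d-dimer,
post-PDS white blood cell count, CRP and albumin, and the WBC
difference (post − pre) — are each dichotomised; the score is the count
of abnormal parameters (0–8) and score ≥ 6 defines the high-risk class.
Abnormal means value ≥ cutoff for every component except albumin, where
low values (< 4.0 g/dL, hypo-albuminemia) are abnormal. The boundary is
inclusive on the abnormal side for ≥-type components and exclusive
(strictly below) for albumin, matching the inequality conventions of the
published definition.

Cutoffs are derived per marker from the empirical ROC curve against a
binary outcome (recurrence by default). Candidate thresholds are the
distinct observed values; test-positive means value ≥ t (or ≤ t for
low-abnormal markers). The AUC is the Mann–Whitney pairwise probability
P(case > control) + ½ P(tie), computed from ranks, which makes it
invariant under monotone transforms of the marker. The selected cutoff
maximises the Youden index J = sensitivity + specificity − 1; ties are
broken toward higher sensitivity, then the smaller threshold, on the
grounds that a prognostic screen should favour catching cases. PPV and
NPV are computed from reconstructed integer counts
(TP = round(sens·n₊), TN = round(spec·n₋), half-up rounding) so they are
exact count ratios rather than products of rounded rates.

The AUC p-value (H₀: AUC = 0.5) uses the tie-corrected normal
approximation to the Mann–Whitney U statistic; when the number of label
arrangements C(n, n₊) is at most 20 000 the exact permutation
distribution is enumerated instead. Below 3 observations per class the
p-value is refused rather than approximated.

## Statistical procedures

All procedures are implemented directly (scipy supplies only
distribution tail functions and ranking); the test suite cross-checks
each against an independent implementation (lifelines, statsmodels,
scipy.stats) or an enumeration oracle.

* **Mann–Whitney U** — tie-corrected normal approximation with a 0.5
  continuity correction, two-sided. The continuity correction keeps the
  approximation within 0.02 of exact enumeration even at n₁ = n₂ = 5.
* **Pearson χ²** — Σ(O−E)²/E without continuity correction,
  df = (r−1)(c−1). Applied to categorical group comparisons (e.g. the
  parity table).
* **Odds ratio** — cross-product ad/bc on a 2×2 exposure × outcome
  table; Wald 95% CI exp(ln OR ± 1.959964·√(1/a+1/b+1/c+1/d)) and Wald
  p. Zero cells are an error unless the Haldane–Anscombe +0.5 correction
  is explicitly requested. The univariate "risk ratios" of the score
  evaluation are these odds ratios — the published univariate values are
  reproduced exactly by the cross-product on the stage counts, which
  fixes the interpretation.
* **Logistic regression** — Newton/IRLS on the full likelihood,
  convergence at |Δℓ| < 1e−8, max 100 iterations; Wald CIs from the
  inverse observed information. Perfect separation is detected by
  coefficient divergence (|β| > 30) and reported as an error, as is a
  rank-deficient design. With a single binary predictor the fitted OR
  equals the closed-form 2×2 odds ratio (tested to 1e−6).
* **Cox proportional hazards** — partial-likelihood Newton–Raphson with
  Efron tie handling and step-halving, convergence at |Δℓ| < 1e−8.
  Covariates are centred internally for conditioning (hazard ratios are
  unaffected). The score test at β = 0 is reported; for one binary
  covariate on tie-free data it equals the log-rank χ² (identity tested
  to 1e−6). Efron was chosen over Breslow because it is more accurate
  under the moderate ties that rounded laboratory values produce.
* **Kaplan–Meier** — product-limit estimator; subjects censored exactly
  at an event time stay in the risk set for that time (events before
  censorings). Without censoring the curve equals the empirical survival
  function.
* **Log-rank** — observed-minus-expected event counts with the
  hypergeometric variance Σ d(n−d)/(n−1)·(nⱼ/n)(1−nⱼ/n), χ² on the
  first k−1 groups, df = k−1.

Wald intervals with z = 1.959964 are used everywhere; published CIs that
can be recomputed from integer counts are reproduced to ±0.01 on the
printed scale (published tables mix rounding and truncation at two
decimals, so no attempt is made to mimic the formatter).

## The synthetic cohort generator

The generator emulates the *structure* of the study cohort so that the
full pipeline can be exercised and validated: 235 patients, 28.9%
recurrent, group-wise marker distributions matching the published
per-stratum summaries, stage and parity frequencies per stratum, and
proportional-hazards event times. It is a testbed, not a patient
simulator.

**Distributions.** Right-skewed markers (CA125, CRP pre/post, d-dimer)
are log-normal, parameterised by the stratum median (location) with the
log-scale SD implied by the printed mean/median ratio,
σ = √(2·ln(mean/median)). Age, WBC (pre/post) and albumin are normal
truncated at zero with the printed stratum mean and SD. The WBC
difference is not drawn — it emerges as wbc_post − wbc_pre, each from
its own stratum distribution.

**Outcomes.** Recurrence is Bernoulli (default 0.289) per patient;
markers are then drawn from the assigned stratum. Recurrent patients
receive a progression time from a Weibull proportional-hazards model,
S(t) = exp(−(t/scale)^shape · e^η), with η the sum of configured log
hazard-ratios over covariates (continuous markers z-scored within the
cohort; the binary covariates `figo_advanced` and `parity_ge1` enter as
0/1 so a configured log-HR is the direct group contrast). Events beyond
the administrative horizon are censored and the recurrence flag is
flipped off. Overall survival adds an independent exponential
post-progression time for the fraction of recurrent patients who die
(default 0.6), capped at the horizon; censored patients have
os = pfs = their last follow-up, so pfs ≤ os holds by construction.
Death occurs only after recurrence in this generator.

**Invented parameters.** The source tables report no follow-up-time
distribution, so the survival side is this package's own choice:
Weibull shape 1.2 and scale 36 months (median progression ≈ 27 months
among recurrent patients, and only ~1.5% of event times beyond the
horizon, keeping the realised recurrence fraction close to the
configured one), administrative horizon 120 months, censored follow-up
uniform on (12, 120) months, post-progression survival exponential with
mean 18 months. Laboratory markers carry 3% missing-completely-at-random
missingness by default (age and stage are always complete), reflecting
that several published diagnostic rows cannot be reconstructed at the
full group sizes and therefore imply per-marker missingness of unstated
extent. Missingness is applied after event times are drawn, so it never
influences outcomes.

**Seeding.** One root seed spawns dedicated sub-streams (labels, one per
marker × stratum, survival, missingness), so a fixed seed yields
byte-identical cohorts and editing one marker's parameters does not
perturb the draws of the others.

**What the generator does not emulate.** Marker correlations beyond the
shared recurrence stratum (no latent severity factor), informative
censoring, the timing of the post-PDS blood draw (treated as a second
draw, not a time series), stage-dependent marker levels within a
stratum, and death without recurrence. Tests passing on these cohorts
therefore establish the correctness of the estimators and the pipeline
plumbing — not the clinical performance of the score on real patients.

## Missing-data policy

Scoring is complete-case: a patient missing any of the 8 components gets
a missing score and is excluded from score-based analyses, with the
exclusion count logged. This mirrors an analysis with no imputation. An
optional `partial=True` rescales the score over available components
(×8/k) for sensitivity analysis only. The published score cutoff (6) is
stored in the score definition rather than silently re-derived;
`derive_score_cutoff` remains available and applies the identical
ROC/Youden machinery to the integer scores of a new cohort.

## Pipeline composition

The pipeline never auto-selects covariates: multivariable logistic and
Cox models take an explicit covariate list (default: advanced FIGO
stage, the WBC-difference dichotomy, and the high-score class, the
factors retained in the published multivariable models). Univariate
blocks reuse the exact component inequalities (referent = normal side).
FIGO subgroup analyses (I/II vs III/IV) always run; strata with fewer
than 5 events are annotated with a warning rather than suppressed, since
low power is a finding in itself. All randomness lives in the generator;
given a cohort the pipeline is deterministic.

## Problem sizes

The validation suite uses cohorts of 235 (study-sized), 2 350 and 4 000
patients for calibration checks, 20 000 for distribution-median
recovery, and 5 000 with 200 replicates for parameter-recovery and
CI-coverage simulations — sizes at which binomial/Monte-Carlo error is
well inside the asserted bands. Exact-enumeration oracles run at ≤ 13
observations per class (≤ ~1 300 combinations), where enumeration is
instant.

## Known limitations

* The generator's survival side is structurally simple (one Weibull
  baseline, exponential post-progression time); it supports estimator
  validation, not prognostic-model benchmarking.
* The full-cohort published results (AUCs, multivariable ORs, Cox HRs
  on the real 235 patients) are not reproducible without the original
  dataset; only quantities determined by published integer counts are
  checked exactly.
* Logistic/Cox standard errors are Wald; no profile-likelihood or exact
  small-sample intervals.
* PFS treats recurrence as the only event; death without recurrence is
  censoring (and the generator never produces it).
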