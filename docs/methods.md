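# Methods and design notes

## The problem being modelled

A child presenting acutely to a general practitioner, outpatient
paediatrician or emergency department may have one of several serious
infections (SI) — most of them bacterial (SBI: pneumonia, complicated
UTI, sepsis/bacteraemia, meningitis, osteomyelitis, abscess/cellulitis,
appendicitis), two of them not (gastro-enteritis with dehydration, viral
respiratory infection with hypoxia) — or, far more often, nothing
serious. A clinical prediction model turns findings (symptoms,
temperature in °C, point-of-care CRP in mg/L, vital signs) into category
probabilities or an additive point score. This package implements the
external-validation and updating workflow for such models and the
synthetic cohorts needed to test it.

## Model representation

A `MultinomialCPM` stores, per non-reference category k, an intercept
α_k and coefficients β_k over a shared term list; the reference category
("absence of SBI") has η ≡ 0 and probabilities follow the softmax link.
Because files state categories explicitly and the reference is named,
file order never matters. Term transformations are deliberately limited
to identity, natural log (for right-skewed predictors like CRP),
categorical indicators and age-banded interval lookups; anything fancier
must be precomputed into the cohort, which keeps model files declarative
and round-trippable. Softmax evaluation subtracts the row maximum, so
linear predictors up to |η| ≈ 700 are safe.

The conditional risk r_k = P_k/(P_k + P_ref) is undefined when both
probabilities are exactly 0; such records are flagged NaN and dropped
from conditional statistics with a warning count rather than being given
an arbitrary 0.5 — the choice is visible in results (`n_dropped`).

Additive scores use half-open age bands `[lo, hi)` (last band closed)
that must tile the declared age range, and half-open value intervals
within each band; an unmatched value scores 0, which is what a
non-deviant (imputed-normal) finding should contribute. Ages are stored
in years with 1 month = 1/12 year; band tables may be declared in
months.

## Cohort handling

Eligibility mirrors the validation-study design: records missing any
*essential* field (outcome, age, sex, temperature) are excluded first,
then records outside 1 month–16 years (inclusive bounds). A record
failing both rules is counted once, under the first rule — the order
matters for reproducing flow accounting, and `FlowCounts` asserts
conservation on construction. Remaining missing findings get *single
non-deviant imputation*: the schema's declared normal value (0 for
symptoms, 37.0 °C, 5 mg/L CRP, ...), on the assumption that normal
findings are the ones least likely to be written down for a
well-appearing child. Multiple imputation is intentionally out of scope.
SBI analyses drop gastro-enteritis records, since viral and bacterial
gastro-enteritis cannot be told apart at outcome adjudication.
Prevalences carry Wilson 95% intervals, which behave at 0/1 boundaries
(Wilson on 498/8211 reproduces the 5.6–6.6% bracket at one-decimal
rounding).

## Discrimination

The C-statistic is the Mann–Whitney concordance probability (ties = ½),
computed by midranks. Its variance is DeLong's placement-value
estimator; the 95% CI is built on the logit scale and back-transformed,
keeping bounds inside [0,1] (at AUC = 1 the placement values are
degenerate, the variance is 0, and the interval collapses to the
estimate — so the upper bound is 1). The conditional variant restricts
controls to the *reference category*, not "all non-cases": that is what
the pairwise contrast "k vs. absence of SBI" means, and it is the
population on which the conditional risk is the correct score.

## Calibration

Binary calibration follows the classical two-fit definition: slope b
from the ML logistic fit of outcome on logit(risk), intercept a from a
second fit with logit(risk) as a fixed offset; Wald 95% CIs. Risks are
clipped to [1e−10, 1−1e−10] before the logit. Constant predictions make
the slope unidentifiable; it is reported NaN while calibration-in-the-
large remains defined.

Multinomial calibration is computed **per category on the conditional
contrasts** (category-k cases vs reference controls, scored by r_k)
rather than as one joint multinomial recalibration fit. Two reasons:
validation reports tabulate exactly one intercept and one slope per "k
vs. absence of SBI" contrast, which this formulation produces directly;
and it makes the update pipeline's zero-intercept guarantee exact (see
below). The joint variant would satisfy whole-cohort score equations
instead and is a possible extension; the choice is recorded in every
report's metadata.

Flexible calibration curves fit the outcome on a restricted cubic spline
of logit(risk) — truncated-power natural-spline basis, 5 knots at the
5/27.5/50/72.5/95th percentiles (knot count is a convention; the basis
is linear beyond the boundary knots) — evaluated by default on 100
points spanning the 1st–99th percentile of predicted risk, with
delta-method confidence bands and per-point extrapolation flags.

## Updating

Three stages, matching how an underperforming but structurally sound
model is rescued on new data:

1. **Recalibration** re-estimates only (a_k, s_k) in η′_k = a_k + s_k·η_k,
   by ML on each conditional contrast. Estimating these on the same
   contrasts used to *assess* calibration makes "recalibrate then
   re-assess" a fixed point: intercept 0, slope 1 to numerical
   tolerance, not approximately.
2. **Revision** refits every coefficient by joint multinomial ML. The
   solver (`mnlogit.py`) is a full Newton iteration with step-halving,
   tolerance 1e−8 on the relative log-likelihood change, 100 iterations
   maximum, supporting per-category design matrices and offsets — the
   shapes recalibration-style constraints need but off-the-shelf
   multinomial fitters do not expose. Complete separation is detected
   (diverging estimates or a log-likelihood at 0) and raised with the
   iteration trace. Rank-deficient designs are rejected naming the
   collinear terms.
3. **Shrinkage** pulls the revised coefficients towards the recalibrated
   ones with one uniform heuristic factor γ = (χ² − df)/χ², where χ² and
   df come from the *revised* fit — the overfitting-prone object being
   shrunk. γ is clamped to [0,1]; a non-positive χ² yields γ = 0 with a
   warning. Intercepts are then re-estimated per conditional contrast
   with the shrunken coefficients fixed as offsets (sequentially, not
   jointly — flagged in report metadata), which forces every post-update
   calibration intercept to 0 on the updating cohort by construction.
   That, not a numerical coincidence, is why updated calibration
   intercepts print as 0.00.

The binomial case (K = 2) runs through the identical machinery, where
conditional and joint formulations coincide. Penalised re-estimation and
bootstrap internal validation are out of scope.

## Diagnostic accuracy

Thresholding uses explicit direction operators. For point scores, a
"≤ c" cut-off names the *low-risk zone*; test-positivity means exceeding
it (this is the only reading consistent with low sensitivity / high
specificity at a low-risk cut-off). Sensitivity and specificity get
Wilson intervals; likelihood ratios get log-method intervals with a 0.5
continuity correction only when a cell is zero while the ratio is still
defined. Zero denominators produce an undefined flag rendered "NA" —
degeneracies are reported, never raised.

## Synthetic cohorts

The generator draws independent predictors by default (a Gaussian copula
over the marginals is available for stress tests), computes true
probabilities from a known `MultinomialCPM`, and draws one outcome per
child; the true probability matrix is returned so tests can compare any
downstream statistic against ground truth. Intercepts are calibrated to
target prevalences by damped 1-D Newton sweeps on a fixed 100 000-draw
Monte-Carlo predictor sample (internal seed, so the solve is
deterministic and memoised); joint convergence is judged *after* each
full sweep, because every one-dimensional solve perturbs the other
categories through the shared normalisation.

The ambulatory-care preset emulates the validation study's structure:
nine SI categories plus reference at the study's category prevalences
(the one structurally empty category, osteomyelitis, gets a small
positive rate of ~1/1000 so the category can be exercised; the
deterministic flow fixture keeps its exact zero), age 1 month–16 years
(log-normal, median ≈ 2 y), ~54% boys, three care settings, temperature
~N(38, 1) °C, log-normal CRP, and MCAR missingness at 5–25% per
non-essential variable. Coefficients of the preset truth model and of
the shipped model fixtures are *illustrative*: plausible in sign and
magnitude, not published values.

What the generator deliberately does not emulate: correlated predictors
(by default), informative (MNAR) missingness, setting-dependent case
mix, or the real joint covariate distribution. Passing tests therefore
demonstrate the *machinery* — estimators recover known truths, fixed
points hold, arithmetic identities balance — not that any fixture model
would perform at any particular level on real children.

The flow fixture is generated *exactly* (8962 rows of which precisely
730 miss an essential field and 21 are age-ineligible; outcome counts,
the 268/498 male split and per-setting counts are exact), so flow and
prevalence arithmetic are deterministic identities rather than sampling
outcomes.

## Problem sizes and numerical conventions

Estimator-recovery tests use n = 20 000 (revision, ±0.15 on
coefficients) and n = 50 000 (recalibration and calibration slopes,
±0.05; known-distortion slopes 1/c ± 0.05); the update fixed point is
checked at n ≈ 20 000 to 1e−6. Null behaviour of the revision χ² uses
200 replicates at n = 400. The acceptance script runs the update at
n = 20 000 and everything else on the 8962-row flow fixture. Reported
tables round to two decimals (one-decimal percent for prevalence);
manifests keep full precision. All randomness flows through a single
seeded generator per run; identical configurations reproduce outputs
byte-for-byte.

## Known limitations

- Calibration CIs are Wald; profile or bootstrap intervals may differ in
  small conditional subsets (rare categories).
- The conditional (dichotomised) calibration/recalibration variant is a
  modelling choice; a joint multinomial recalibration would give
  slightly different updated coefficients.
- Single non-deviant imputation understates uncertainty relative to
  multiple imputation.
- DeLong intervals assume independent records; clustering by practice or
  site is not modelled.
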