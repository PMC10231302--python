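# Methods

This note records the scientific and numerical choices behind `mpras`: how
raw measurements become band categories, how the score aggregates, how the
calibration statistics are computed, what the synthetic-cohort generator
does and does not emulate, and the known limitations.

## Categorisation

Each of the ten risk factors maps a raw measurement onto
LOW / INTERMEDIATE / HIGH using the boundary constants in
`ThresholdTable` (shipped defaults are the published protocol values; all
constants are editable through a per-factor YAML config block so the engine
can serve revised protocols).

Three boundary conventions are fixed in code rather than configurable,
because they are semantic rather than numeric:

* **Shared boundaries resolve to INTERMEDIATE.** The protocol's low band
  for SER change is "better than −0.50 D/yr" while the intermediate band is
  "−0.50 to −0.75"; at exactly −0.50 the inclusive intermediate reading
  wins. This is the conservative (higher-risk) assignment and is applied
  uniformly at every shared boundary.
* **Gaps resolve to INTERMEDIATE with a warning.** The accommodative-error
  bands leave (0.50, 0.75) D uncovered: the protocol assumes clinically
  quantised measurements (0.25 D steps), and mid-gap values are nearest the
  intermediate band. A `GapWarning` names the factor and value. Note that
  with a population mean lag near +0.53 D this gap covers a high-density
  region, so the warning is *common* on realistic data — a genuine property
  of the band definitions, not a bug.
* **The change factor takes the worse signal.** When both the SER change
  (D/yr) and axial-length change (mm/yr) are present and disagree, the more
  severe category is used: the factor is a single row of the protocol and
  either signal exceeding its threshold indicates progression. The protocol
  itself states no precedence rule; max-severity is this package's choice.
* **RPR uses the worse (more hyperopic) of the nasal/temporal meridians**
  at ±30° eccentricity, matching the "at least 0.25 D along either
  meridian" reading of the measurement protocol.

Two other readings worth recording: near-work at exactly 10 h/day is
INTERMEDIATE (the high band is strictly "> 10"), and any exophoria
(negative prism dioptres) satisfies the phoria low band ("≤ 2").

## Aggregation

A factor in band *c* contributes `weight × base_point(c) × multiplier(c)`
with base point and multiplier both 1/2/3 by band. This per-factor product
form and the two-step band-subtotal form (sum base points per band, then
multiply the three subtotals by 1/2/3 and add) are algebraically identical;
`ScoreBreakdown` exposes both so either can be audited. The product form —
contributions of 1/4/9 rather than 1/2/3 — is forced by the published
10–90 range of the ten-factor score and is deliberately documented
prominently, since the two-step prose admits a misreading that would give a
10–30 range.

The weighted variant applies three multiplicative rules: 2× on the change
factor (intermediate/high), and 0.5× on myopic parents and time outdoors
(intermediate/high) *conditional on age ≥ 18 years*. The rule set is an
open list (`WeightRule` supports any factor/band/condition combination) so
a fuller weighting scheme can be configured if one is published; only these
three rules are stated in the source protocol's methods.

Classification is strictly `total > cutoff`. On the integer unweighted
scale the shipped half-point cut-offs make strict-vs-non-strict immaterial;
on the fractional weighted scale it matters, and strict matches the
published "> 41.50 / > 41.75" phrasing. The random-eye option draws a
stable per-patient choice from SHA-256 of `(seed, patient_id)`, so results
are reproducible across runs and record orderings.

## Calibration statistics

* **ROC.** A subject is called positive when `score > threshold`. On an
  integer-valued score the candidate thresholds are the half-integers (one
  sentinel below the minimum, then each observed score + 0.5): every
  reported cut-off is an unattainable x.50 value, the convention behind
  published cut-offs like 41.50. On fractional scores (the weighted model
  moves in 0.25/0.5 steps) thresholds are midpoints between consecutive
  distinct observed scores plus two sentinels, which reproduces the x.75
  pattern of the published weighted cut-off. The AUC is the trapezoid over
  (1 − specificity, sensitivity), identical to the normalised Mann–Whitney
  statistic with half credit for ties (property-tested against exhaustive
  pair enumeration). An AUC below 0.5 triggers a warning, never a silent
  orientation flip.
* **AUC standard error** is the Hanley–McNeil closed form
  `SE² = [A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)]/(n₊n₋)` with
  `Q₁ = A/(2−A)`, `Q₂ = 2A²/(1+A)`. A sample-size utility
  (`auc_sample_size`) inverts the same variance family in a
  normal-approximation power calculation.
* **Cut-point selection** maximises Youden's *J*; among tied thresholds the
  lowest is reported, which maximises sensitivity — the natural preference
  in a screening context.
* **Cohen's kappa** is computed from the 2×2 marginals; the degenerate
  `p_e = 1` case (both raters constant and identical) returns 1.
* **Outcome validation** labels a subject as a progressor when the observed
  1-year SER change is ≤ −0.50 D/yr (a myopic change of at least 0.50 D in
  magnitude) and reports the confusion statistics of the score's decisions
  against that outcome, excluding missing follow-ups with a warning and
  reporting NaN (with a warning) for proportions undefined under a
  single-class outcome.

## Factor reduction

Permutation importance is classifier-agnostic: anything exposing `predict`
(and `predict_proba` for the AUC metric) can be ranked; the importance of a
feature is the drop in the baseline metric (accuracy by default) averaged
over independent permutations of that feature's column. The default demo
classifier is gradient-boosted trees (200 depth-3 trees, learning rate 0.1,
single-threaded) — plain, fixed settings chosen for reproducibility, fitted
on a stratified 70/30 holdout in the CLI demo. The canonical factor ranking
used by the shipped `1a`–`1g` presets is the published ordering, hard-coded:
the original classifier's hyperparameters are unreported, so a re-derived
ranking would not be reproducible and is not treated as canonical.

The Kaiser screen eigen-decomposes the correlation matrix of the *raw*
numeric factor values (not the 1/2/3 band scores) and retains components
with eigenvalue > 1. Raw values were chosen because the band scores are a
deterministic coarsening whose correlation structure is an artefact of the
band boundaries; the source protocol is ambiguous on this point.

## The synthetic cohort generator

The generator emulates a tertiary myopia-clinic population:

* **Marginals** are truncated normals with the clinic cohort's reported
  mean, SD and range: age at presentation 13.74 ± 4.89 y on [6, 29]; onset
  8.59 ± 3.74 y on [0.3, 18]; SER −5.02 ± 2.99 D on [−16.50, −0.50]
  (the myopia inclusion bound); SER change −0.73 ± 0.78 D/yr; near work
  7.85 ± 3.05 h/d on [0, 16]; outdoors 1.11 ± 1.14 h/d on [0, 8]; RPR
  +0.66 ± 0.71 D; accommodative error +0.53 ± 0.42 D; near phoria on
  [−25, +16] PD (mean −2, SD 7 — the source reports only the range; a
  slightly exophoric centre is typical of near phoria distributions).
  Parent counts follow the reported 61/59/29 frequencies. Sampling is by
  inverse-CDF through a Gaussian copula, so marginals are exact.
* **Structure.** Right/left eyes share copula correlation 0.95 (the
  reported per-eye means are near-identical; the exact correlation is
  unpublished). Nasal and temporal RPR share 0.7 within an eye. Age at
  presentation and onset share 0.9, and onset is clamped to presentation;
  at ρ = 0.9 the clamp binds for ≈1% of draws, preserving the onset
  marginal, while realistically making late presenters late-onset. Axial
  change is derived from SER change at −0.37 mm/D plus 0.03 mm noise.
  All other factors are conditionally independent — the true joint
  structure is unpublished.
* **Outcome.** A latent progression propensity is logistic in the
  risk-direction-aligned standardised factors with coefficients
  proportional to the published importance ranking (change in refraction
  strongest at 1.4, parents weakest at 0.2), scaled by `effect_scale`; the
  intercept is calibrated by bisection so the mean propensity equals the
  configured prevalence (default 16/36 ≈ 0.444, the prevalence implied by
  the published prospective validation subset). The gold 1-year SER change
  is then drawn from a progressor (−0.95 ± 0.35, ≤ −0.55) or
  non-progressor (−0.10 ± 0.20, ≥ −0.45) truncated normal; the small gap
  around the −0.50 decision boundary keeps measurement noise from churning
  labels. Observed follow-up adds 0.12 D of refraction noise (configurable;
  zero noise reproduces the gold outcome exactly).
* **Raters.** Clinician 1 thresholds the propensity at the quantile giving
  the reported at-risk prevalence (114/149); the other raters copy
  clinician 1 with a symmetric flip probability solved in closed form from
  the expected 2×2 table to hit a target kappa (default 0.95, the centre of
  the reported 0.90–1.00 agreement band).

**What passing tests show — and do not.** The generator reproduces the
reported univariate summaries, rater agreement and outcome prevalence, and
gives the score genuine discriminative signal. It does *not* claim the true
multivariate dependence among the factors, the real factor–outcome effect
sizes, or clinic-level artefacts (seasonal effects, measurement rounding,
referral bias). Results on synthetic cohorts validate the machinery, not
the epidemiology. One structural consequence worth knowing: because the
outcome couples to the *continuous* factors while the score sees only three
bands per factor (1/4/9 points, equally weighted), score–outcome agreement
saturates (≈0.75 accuracy, AUC ≈0.83 at defaults) no matter how strong the
configured effect — a categorical score cannot reproduce a continuous
decision boundary exactly.

## Numerical choices and problem sizes

Deterministic seeding throughout (`numpy.random.default_rng`, SHA-256 eye
picks, brentq for the two calibration solves at 1e-10/1e-12 tolerance).
Default test problem sizes: 10 000 patients for marginal-fidelity checks
(Monte-Carlo tolerance 5 SE on means, 5% on SDs), 5 000 for the kappa
band, 1 000 for the signal-restricted sub-model comparison and the
weighted-identity sweep, 300 for the shared end-to-end fixture — sizes at
which the Monte-Carlo tolerances above are comfortably resolvable. The
score-range enumeration is exhaustive (3¹⁰ assignments).

## Limitations

* The weighted model implements only the three published weight rules; the
  full weight table was not published in the available text.
* The published data-dependent numbers (cut-offs 41.50/43.50/22.00, AUCs
  0.88–0.96) depend on a 149-patient clinic cohort that is not deposited;
  they are carried as shipped preset cut-offs and pattern-level properties
  (half-point cut-offs, 1g ≥ 1a on signal-restricted cohorts), not
  re-derived.
* No measurement-error model for the clinical instruments: inputs are
  taken at face value.
* Single follow-up horizon (1 year); no longitudinal trajectories, no
  treatment-response modelling, no slow/fast progressor grading.
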