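# Methods

## The screening problem

A short self-report scale administered in the first weeks after a traumatic
event is evaluated as a screener for PTSD assessed months later.  Three
screener variants are considered: the categorical DSM-5 acute stress
disorder (ASD) diagnosis, the continuous acute-stress intensity score, and
the two combined (diagnosis within low/high-intensity strata, or diagnosis
plus score in a regression).  Outcomes are full-threshold DSM-5 PTSD and
two subthreshold caseness definitions.  All evaluation reduces to integer
2×2 tables — screener against outcome — from which sensitivity,
specificity, PPV and NPV are computed, and to probit models that trace
predictive values continuously across the score.

## Instrument scoring

**ASDS.** Nineteen symptom items on a 1–5 ordinal scale (1 = not at all,
5 = very much); the item sum is the intensity score (19–95).  A binary
peritraumatic-fear item is carried but plays no role in scoring.  Probable
DSM-5 ASD requires endorsement of at least 9 of 14 DSM-5 symptoms.  Because
19 items probe 14 symptoms, an item→symptom map is needed; the published
instrument's mapping is not freely reproducible, so the package ships a
documented default (symptoms 1–9 fed one-to-one by items 1–9; symptoms
10–14 fed by consecutive item pairs, endorsed by the pair maximum) and
loads any substitute mapping from a plain-text config file.  The 9-of-14
rule itself is fixed.  An item counts toward symptom endorsement at rating
≥ 3, the scale midpoint ("moderate"); this level is configurable because
instrument conventions differ.

**PCL-5.** Twenty items on a 0–4 scale, one per DSM-5 PTSD symptom, in the
standard criterion order B = items 1–5 (intrusion), C = 6–7 (avoidance),
D = 8–14 (negative cognitions/mood), E = 15–20 (arousal).  An item is an
endorsed symptom at rating ≥ 2 ("moderately"), the standard convention.
Full threshold requires endorsed counts ≥ (1, 1, 2, 2) over (B, C, D, E);
*Majority* requires at least 3 of those 4 componentwise conditions;
*Six Plus* requires ≥ 6 endorsed symptoms with no distribution requirement.
Full threshold logically implies both subthreshold definitions (its
(1, 1, 2, 2) pattern already contains 6 endorsed symptoms); the test suite
verifies this exhaustively over the criterion-count grid.

**Missing data.** Scoring is complete-case per instrument.  An optional
prorated intensity total (mean of answered items × 19, rounded half-up) is
available when ≥ 80% of items are answered; prorating is never used for
symptom counting, where a missing item simply cannot endorse.

## Predictive-value evaluation

For a confusion matrix (tp, fp, fn, tn): sens = tp/(tp+fn),
spec = tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn).  Each estimate
carries a 95% Wilson score interval — chosen over Wald for its behaviour at
boundary proportions (small strata routinely produce proportions of 0 or
1).  A metric with a zero denominator is returned as an explicit undefined
marker, never 0 or NaN.  Intensity stratification splits subjects at a
score cut-off (default 58, inclusive: high ⇔ total ≥ 58; a strict-inequality
variant is configurable) and evaluates the diagnosis screener within each
stratum; per-stratum tables sum componentwise to the marginal table by
construction.

**Reconstruction of printed tables.**  Published screening tables usually
print group sizes and percentages, not the underlying integer cells.
`reconstruct_counts` inverts this: given n screener-positives, n
screener-negatives and PPV/NPV printed at a known precision, it scans every
tp ≤ n_pos and tn ≤ n_neg whose half-up-rounded percentage reproduces the
printed values, returning *all* consistent tables with a uniqueness
verdict.  `reconstruct_stratified` extends the search to every split of the
two screener groups into low/high strata consistent with stratified *and*
marginal printed values simultaneously.  Matching uses decimal half-up
rounding at the printed number of decimals (2 for tables, 1 for running
text), since binary floating rounding can disagree at ties.  When printed
cells admit no integer table the operation raises an explicit inconsistency
error rather than forcing a fit; when several tables qualify, a helper
reports whether the sensitivities/specificities they induce agree at the
printed precision.  One known reference case behaves exactly this way: the
later acute wave's stratified cells reconstruct to a table whose induced
sensitivities contradict the separately printed ones (most plausibly
because of per-cell missing scores in the source data), and the package
surfaces the contradiction instead of resolving it.

## ROC, Youden selection, probit curves

The ROC is evaluated at every integer threshold in [19, 95] (positive test:
score ≥ threshold), a reproducible grid independent of which scores happen
to be observed.  The AUC uses the rank (Mann–Whitney) definition with ties
counted half; its standard error is Hanley–McNeil and the p-value is a
two-sided normal test against 0.5.  The Youden index J = sens + spec − 1 is
maximised over the grid; ties break toward the smaller threshold, which
favours sensitivity — the natural choice for a screener intended to catch
prospective cases.  A comparison report returns J at any user-named
candidate cut-offs (e.g. 56 vs 58).

Two probit models are fitted per wave and outcome: (1) outcome on the ASD
diagnosis alone, and (2) outcome on diagnosis plus the intensity score.
The likelihood is maximised by Newton–Raphson with step-halving;
convergence requires relative log-likelihood change < 1e-10 or gradient
norm < 1e-8 within 100 iterations.  Complete separation is detected two
ways — coefficients diverging past 10⁴, or a log-likelihood within 1e-6 of
its supremum of zero — and raises an error naming the separating predictor.
The covariance is the inverse observed information, symmetrised.

From model (2) with coefficients (β₀, β₁, β₂), the model-based predictive
curves are PPV(s) = Φ(β₀ + β₁ + β₂ s), the predicted outcome probability
for a diagnosis-positive subject at score s, and NPV(s) = 1 − Φ(β₀ + β₂ s)
for a diagnosis-negative subject.  This model-based construction is a
design choice: a binned empirical alternative
(`empirical_predictive_curve`) is provided for comparison, and on large
cohorts generated under the probit model the two agree within 0.05.  Curve
endpoints default to the observed score range of the cohort (configurable
to the theoretical [19, 95]); with β₂ > 0 the PPV curve is strictly
increasing and the NPV curve strictly decreasing, which the tests assert.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any particular real dataset:

* **Latent structure.**  One standard-normal trauma-severity trait T per
  subject; acute-wave liabilities L_w = λ_w T + √(1−λ_w²) ε_w, so the
  cross-wave liability correlation λ₁λ₂ is induced by the shared trait
  rather than being a free parameter (the minimal structure yielding both
  cross-wave stability and wave-specific prevalence decline).  The PTSD
  liability is driven by the standardised mean of the acute liabilities
  with slope b: P = b·M + √(1−b²) ε, so subthreshold outcome gradations
  arise naturally rather than from the diagnosis flag.
* **Items.**  Item propensity a·L + noise, cut at per-level thresholds
  (graded-response form).  Defaults: discrimination a = 1.0 for all items,
  chosen once so the 19-item ordinal scale reaches Cronbach α ≈ 0.94, the
  internal consistency reported for the instrument; baseline cutpoints at
  normal quantiles giving a right-skewed response distribution.
* **Calibration.**  A single global threshold shift per instrument/wave is
  found by bisection (common random numbers, 100 000-subject panel) so the
  expected diagnosis prevalence hits the configured targets — defaults
  45.8% (wave 1) and 31.3% (wave 2) for ASD and 29.6% for full-threshold
  PTSD — to within 0.1 percentage points on the panel, well inside the
  0.5-point contract.  Because every liability is marginally standard
  normal, calibration is independent of the loadings.  An unreachable
  target raises a diagnostic error.
* **Participation.**  The default 426-subject cohort reproduces a realistic
  longitudinal pattern exactly: 50 wave-1-only, 209 wave-2-only, 167 at
  both acute waves, all with the follow-up outcome.  Demographics (age
  36.31 ± 12.03 truncated to [20, 73], 76.06% female, 74.65% clinical
  profession) are decorative — not linked to liabilities — by default.
* **Determinism.**  All draws come from one seeded stream in a fixed,
  documented order (demographics, latent block, wave-1 items, wave-2
  items, follow-up items); item matrices are drawn for all subjects and
  masked afterwards, so changing the participation pattern cannot shift
  other draws.  Regeneration from the same (config, seed) is
  byte-identical, which the tests check on serialised CSV bytes.

**What passing tests do and do not show.**  The generator produces
unidimensional, high-reliability, monotone item responses with
whole-wave-only missingness.  Real questionnaire data add item-level
missingness, multidimensionality, response styles, floor effects and
attrition correlated with severity; pipeline correctness on synthetic
cohorts therefore demonstrates the *computations*, not robustness to those
real-data features.  Reference-table reconstruction, by contrast, is exact
integer arithmetic and transfers directly.

## Numerical choices

* Printed-value matching: decimal half-up at the stated precision;
  percentages in emitted tables at 2 dp alongside full-precision
  proportions.
* Wilson intervals clamped to contain the point estimate and stay in
  [0, 1] (guards float fuzz at proportions of exactly 0 or 1).
* Youden ties → smallest cut-off; ROC grid fixed at the theoretical score
  range.
* Probit: zero start, observed-information Newton steps with step-halving;
  tolerances as above.
* Calibration bisection: bracket ±8 liability units, 60 iterations, target
  tolerance 0.001.
* The default analysis fixes the cut-off at 58; `--select-cutoff` re-runs
  Youden selection per wave instead.

## Problem sizes

Default test and acceptance runs use the 426-subject default cohort for
end-to-end checks, 5 000-subject cohorts for null and qualitative-ordering
checks, 50 000 subjects for latent-correlation recovery, 100 000–200 000
subject panels for prevalence calibration and its verification, and 200
replicates at n = 5 000 for probit coverage — sizes at which Monte-Carlo
error is comfortably below the asserted tolerances while the full suite
runs in well under a minute of compute.

## Known limitations

* The default item→symptom map is a documented placeholder, not the
  published instrument's mapping; substitute the real mapping via the
  config file for substantive use.
* The cross-wave liability correlation is tied to the wave loadings
  (λ₁λ₂); cohorts needing a correlation outside [0, λ₁λ₂] bounds require a
  different latent structure.
* No item-level missingness model; missingness is whole-wave only.
* Screening evaluation is descriptive: no between-wave inferential
  comparisons (McNemar, DeLong) are implemented.
* The probit models use no covariates beyond the screener; demographic
  columns are carried through but unused by design.
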