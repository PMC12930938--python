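# Methods

## Analysis units and set construction

The analysis unit is one lymph node measured by one reader; there is no
within-patient clustering correction anywhere in the pipeline. This matches
per-node reporting conventions in diagnostic-accuracy studies of nodal
imaging, but it means confidence intervals are computed as if nodes were
independent — a known limitation, most relevant for patients contributing
many nodes.

Two node-level sets are built from a cohort containing a sentinel (SLN)
group and an advanced-stage metastatic (MLN) group:

* **Sentinel set** — all sentinel nodes, minus every *benign* node of a
  patient who also has at least one metastatic node. Benign nodes of such
  patients are plausibly not exchangeable with benign nodes of node-negative
  patients (tracer binding and drainage effects), so they are excluded and
  each exclusion is logged.
* **Pooled set** — every metastatic node of the MLN group plus every benign
  sentinel node, *including* those the sentinel set excluded. Benign MLN
  nodes (if present) are excluded from this set and logged.

Missingness rule: a metric that is absent for a record is excluded from
that metric's computation only, and every performance row reports its
effective n. Reader 2 re-measures the ROI-based sequences, short-axis
diameter and Node-RADS but not the volumetric sequence, so reader-2
analyses of volumetric metrics are structurally empty. No imputation is
performed anywhere.

## Ratio normalization

`cADC` divides the target node's ADC by the arithmetic mean of up to three
contralateral benign nodes' ADCs; `mADC` divides it by the ADC of a fixed
muscle region. The design case uses exactly three contralateral references;
one or two are accepted (real tables are imperfect) with the count recorded
and a diagnostic emitted. Ratios are stored unrounded; rounding happens only
in the print-precision report copies (half-up, 2 decimals). One muscle value
is attached per patient × reader × sequence; whether a muscle reference
should instead be drawn per nodal basin is an open question of the design,
and the data model would need one extra key to support it.

## ROC, AUC and the Youden cut-off

Candidate thresholds are the observed unique metric values with inclusive
comparison: for ADC-like metrics (lower = malignant) a node is positive
when `value <= t`; for short-axis diameter and Node-RADS when `value >= t`.
Midpoint threshold conventions cannot be distinguished from observed-value
conventions without raw data; observed values are the default and the
classification rule is explicit in `classify_at_cutoff`. Node-RADS is
treated as an ordinal score with thresholds at the observed categories.

The AUC is the trapezoid over the resulting operating points, which for
this threshold set equals the pairwise concordance probability with ties
counted half (tested against a brute-force pairwise count on random
fixtures). The default 95% CI is DeLong's nonparametric interval, truncated
at 1.0; a class-stratified bootstrap (default 2000 resamples, seeded) is
available where the per-class counts are too small for DeLong (fewer than
two per class) or as a sensitivity check.

The Youden-optimal cut-off maximizes `J = sens + spec − 1` over the
candidate thresholds. Ties are broken toward higher sensitivity (the
screening emphasis: a missed metastasis is costlier than a false alarm),
then toward the threshold with the larger margin to the next observed
value, then toward the smaller threshold. The reported J always equals
`sens + spec − 1` at the returned cut-off exactly.

## Logistic regression

The regression arm fits a single-predictor Bernoulli model with logit link
by maximum likelihood (Newton iteration, 100-iteration cap) and reports
McFadden's pseudo-R² `1 − ll/ll0` against the intercept-only model.
Complete separation is detected directly from the data (disjoint class
supports of the predictor) and flagged rather than letting coefficients
diverge silently; the capped-iteration coefficients are still returned.

## Agreement statistics

* **Gwet's AC1** for two binary ratings: chance agreement `2π(1−π)` with π
  the mean of the raters' positive marginals, so the coefficient stays
  interpretable under the skewed prevalence typical of sentinel cohorts
  (unlike Cohen's kappa). The variance is the unconditional subject-level
  estimator without finite-population correction; the CI uses the t
  distribution with n−1 degrees of freedom, upper bound truncated at 1.
* **ICC(2,1)**: two-way random effects, absolute agreement, single
  measures, computed from the ANOVA mean squares; CI by the
  McGraw–Wong F-based interval (cross-checked against pingouin in tests).
  Incomplete pairs are excluded and counted. When both error mean squares
  are exactly zero (numerically identical readers) the CI degenerates to
  the point estimate and is flagged.
* **Bland–Altman**: bias = mean(R1 − R2) — the sign convention is
  reader 1 minus reader 2 throughout and is documented on the result —
  with 95% limits of agreement `bias ± 1.96·SD` (n−1 denominator).
* **Spearman's ρ**: Pearson correlation of mid-ranks; two-sided p by the
  t-approximation, replaced by exact enumeration over all rank permutations
  for n ≤ 8; constant inputs yield a flagged undefined result.

In the agreement report the metastatic-vs-benign Mann-Whitney p is computed
per reader; classification-vs-truth AC1 is computed per reader at the
supplied (derivation-set) cut-offs.

## Cohort statistics

Quartiles use linear interpolation between order statistics — the common
statistical-software default; printed IQRs cannot adjudicate the convention,
so it is configurable (`quartile_method`). Mann-Whitney U uses exact
enumeration when the pooled sample is ≤ 12 without ties, otherwise the tie-
and continuity-corrected normal approximation. Fisher's exact test is
two-sided by probability-mass summation. The chi-square test is Pearson's,
(r−1)(c−1) df, no continuity correction, warning when any expected count is
below 5; the summary-table builder selects Fisher for sparse 2×2 tables and
chi-square otherwise, and labels the choice.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
images:

* **Marginals.** Per-group, per-sequence nodal ADC distributions are
  lognormal, calibrated in closed form to target medians and IQRs
  (location = ln median, scale = ln(q3/q1)/(2·z₀.₇₅)). The median is
  reproduced exactly; the IQR exactly iff the target is multiplicatively
  symmetric, with any asymmetry reported as a calibration residual.
  Lognormal is the default because ADC values are positive and reported
  IQRs are right-skewed; a truncated-normal family is available for
  sensitivity checks. Defaults are calibrated to published per-group
  summaries of a melanoma lymph-node DWI study (benign EPI ADC 943
  (866–1066) ×10⁻⁶ mm²/s; advanced-stage metastatic 616 (566–681); sentinel
  metastatic 695 (644–781.5); analogous values for the RESOLVE and
  volumetric sequences, short-axis diameter and ROI/VOI sizes; Node-RADS
  category frequencies chosen to match the published per-group
  median/IQR).
* **Muscle references.** Muscle ADC summaries are not published; defaults
  (EPI 1520, RESOLVE 1620, volumetric 1500 ×10⁻⁶ mm²/s, log-symmetric IQR
  ≈ ±9%) are chosen once so the implied muscle-ratio medians match the
  published ratio medians given the nodal ADC medians, with spread
  comparable to benign nodal spread. Skeletal muscle is among the most
  homogeneous reference tissues, hence the somewhat tighter IQR.
* **Within-patient correlation.** One standard-normal patient effect z is
  shared by all of a patient's draws; a measurement with calibrated
  log-scale σ is drawn as `exp(μ + σ(√f·z + √(1−f)·ε))` with
  `f = intra_patient_sd_fraction` (default 0.3). This keeps every marginal
  at its calibrated target while correlating a patient's nodal,
  contralateral and muscle values. The fraction is not estimable from
  published summaries; recovery tests exercise 0 and 0.3–0.5 style settings
  and the ratio analysis is insensitive to it by construction (the effect
  largely cancels in the ratios; exactly so for a literal patient-wide
  multiplicative shift).
* **Two readers.** Reader-2 values are reader-1 values minus a bias plus
  independent Gaussian noise per raw measurement, with SDs set to published
  limits-of-agreement half-widths divided by 1.96 (EPI ADC ≈ 107, RESOLVE
  ADC ≈ 137 ×10⁻⁶ mm²/s, SAD ≈ 2.2 mm, Node-RADS ≈ 0.97 categories,
  discretized and clipped to 1–5) and biases to the published values
  (R1 − R2 convention). Noise is injected only on raw measurements; the
  limits of agreement of downstream *ratios* are emergent, not separately
  calibrated.
* **Micrometastasis mimic.** A configurable fraction of metastatic nodes
  draws its ADCs from the benign distribution while keeping metastatic
  truth and morphology — the mechanism behind false negatives at ratio
  cut-offs. Default 2/7 for sentinel-group positives (matching the
  published false-negative pattern), 0 for confirmed advanced-stage nodes.
* **Structure.** Defaults: 52 sentinel patients (1–3 nodes each, node-level
  metastasis probability 7/71) and 12 advanced-stage patients (1 + Poisson
  nodes, mean ≈ 6.25, all metastatic). `recovery_config` reshapes this to
  ~150 nodes per group for parameter-recovery runs — sizes chosen so the
  sampling error of a recovered cut-off is well inside the ±0.05 assessment
  band while the whole 20-seed suite runs in seconds.
* **What it does not emulate:** joint dependence between ADC, short-axis
  diameter and Node-RADS within group (sampled independently — published
  summaries give no joint law), per-row missingness patterns of real
  two-reader tables (only the structural absence of reader-2 volumetry),
  voxel-level effects (partial volume, b-value physics), or inflammation
  and other benign ADC-lowering confounders. Passing recovery tests
  therefore show the *estimators* recover generator truth under the assumed
  structure, not that the published effect sizes are correct.

`implied_optimal_cutoff` maximizes `J(t) = F_met(t) − F_ben(t)` (for
lower-is-malignant metrics) over the closed-form CDFs with a 2001-point
grid bracketing plus bounded scalar minimization; identical specs are
flagged degenerate (J = 0), essentially disjoint supports are flagged as
boundary solutions (J → 1). `implied_ratio_spec` gives the exact lognormal
law of target/reference under the shared patient effect: location
μ_t − μ_r, variance `f(σ_t − σ_r)² + (1−f)(σ_t² + σ_r²)`.

## Numerical conventions

* Report rounding: decimal half-up at 2 decimals, applied only to the
  `*_rounded.csv` copies and printed summaries; raw tables keep full
  precision. Published-style Youden indices are computed from unrounded
  sensitivity and specificity, then rounded.
* Logistic convergence: Newton, 100 iterations; non-convergence without
  separation raises with the last parameter state.
* Degenerate inputs are errors or flags, never silent values: all-zero
  confusion matrices, single-class ROC labels, zero-margin Fisher tables,
  constant Spearman inputs, sub-minimum pair counts.
* End-to-end determinism: one `numpy` Generator seeded from the config
  drives the cohort generator; identical config + seed produce byte-identical
  output files.

## Interfaces

The cohort table is a long-format CSV (one row per node × reader; UTF-8,
comma-separated, decimal point, empty string = absent) whose column list is
the importable constant `nodemetric.data.SCHEMA_COLUMNS`; per-patient
reference panels ride on the node rows as wide columns and are
de-duplicated on read, with conflicting duplicates rejected. `nodemetric
validate <file>` checks conformance. The CLI (`validate`, `simulate`,
`derive`, `transfer`, `agreement`, `report`, `run-all`) is a thin layer
over the library; all outputs are CSV plus a JSON run manifest carrying
seed, stage logs and exclusion counts.

## Known limitations

* Node-level CIs ignore within-patient correlation of multiple nodes.
* The AC1 variance formula is one of several published choices
  (unconditional, no finite-population correction).
* The generator's independence of ADC and morphology within group
  understates real correlations (larger metastases are likely both larger
  in SAD and more diffusion-restricted).
* Real two-reader tables have idiosyncratic per-metric missingness that the
  per-metric-presence rule accommodates but the generator does not imitate.
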