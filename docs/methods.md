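# Methods

This note documents the statistical models implemented in `folscan`,
the synthetic-data model used to validate them, the parameter defaults
and why they were chosen, and the numerical conventions that matter for
reproducibility.

## Data model

A cycle is a `SizeHistogram` (counts per integer mm bin, 8–25) plus
five outcome counts. Binning rounds measured diameters half away from
zero; diameters under 8 mm are excluded because they are not aspirated
at retrieval, and diameters over 25 mm are pooled into the 25 mm bin.
The rounding convention is a package choice — clinical reports quote
whole millimetres without stating one — and is applied identically
everywhere, so it cannot bias comparisons between stages. Window
arithmetic (`count_in_window`, `proportion_in_window`, `oocyte_yield`)
is exact integer arithmetic over the bins; an oocyte yield may exceed 1
(oocytes can come from follicles outside the denominator window) and is
deliberately not clamped.

## Stage 1: exhaustive window scan

All 171 contiguous windows over the 18 bins are fitted by simple least
squares of the outcome on the window count. The implementation computes
all windows at once from prefix sums; a scalar routine
(`fit_simple_ols`) with identical conventions is kept for direct use
and as a cross-check. Conventions for degenerate cases:

* constant window count across the cohort → the window is retained with
  r² = 0 and a `degenerate` flag (so every scan reports all 171
  windows, comparable across cohorts);
* constant outcome → r² = 0, p = 1;
* the best window is the argmax of r², ties broken toward the narrower
  window, then the lower `lo` (ties are essentially impossible with
  float r² except among degenerate windows; the rule makes the result
  deterministic anyway);
* if *every* window is degenerate (all patients share one histogram)
  the scan raises rather than reporting noise.

No multiple-testing adjustment is applied across the 171 windows. The
scan is a screening device — overlapping windows share follicles and
their fits are strongly dependent — and the caveat is repeated in the
API documentation. Inference about individual diameters belongs to
stage 2.

## Stage 2: per-diameter regression

One model with all 18 per-bin counts as predictors. The default family
is Gaussian with identity link, fitted by OLS (statsmodels), reporting
per-coefficient two-sided t tests and the conventional r². The count
nature of the outcomes suggests Poisson with log link, which is
available (`family="poisson_log"`, IRLS to relative deviance change
< 1e-8, max 100 iterations, Wald z tests, deviance pseudo-r²); the
Gaussian default was chosen because it is the family whose model-level
r² matches what clinical reports print alongside such tables, and, on
the synthetic cohorts, the two families agree on the sign of every
strong coefficient (asserted in the tests). The model is
intercept-plus-diameters only — no age or reserve covariates, which the
per-cycle CSV does not carry.

Zero-variance columns (e.g. nobody with a 25 mm follicle) cannot be
tested; they are dropped from the design and reported with coefficient
0, p = 1 and a degenerate flag rather than failing the fit. A design
that is singular *after* those drops raises an error naming the
collinear columns. Significance stars follow the three printed tiers
(\* p<0.05, \*\* p<0.01, \*\*\* p<0.0001).

## Stage 3: regression forest

CART regression trees, written from first principles:

* split criterion: maximise SSE(parent) − SSE(left) − SSE(right),
  computed per node from cumulative sums over each candidate feature's
  sort order; thresholds at midpoints of consecutive distinct values;
* at each node `mtry` features (default 6 ≈ 18/3, the usual regression
  default) are sampled without replacement; both children must have at
  least `min_leaf` rows (default 5);
* growth stops when a node has fewer than 2·`min_leaf` rows or the best
  decrease is not positive (absolute tolerance 1e-12, which also makes
  constant-outcome nodes leaves);
* each tree trains on an n-sized bootstrap resample; the forest seed is
  expanded into independent per-tree streams with `SeedSequence.spawn`,
  so a (seed, config) pair fully determines the forest, independent of
  evaluation order.

The **model importance factor** of a diameter is the summed SSE
decrease of all splits on it across the forest, divided by the number
of trees (impurity importance). This matches the semantics of a
non-negative score with exact zeros for never-split features. No
normalisation is applied: the absolute scale depends on the outcome
variance and cohort size, so comparisons should be rank-based or
relative (in-window vs out-of-window means), which is how the tests and
the acceptance script use it. Out-of-bag permutation importance (mean
OOB MSE increase after permuting one column, averaged over trees) is
provided as an independent cross-check with different bias properties;
on the synthetic cohorts both methods rank the planted window's
diameters above the rest.

Prediction is the mean of per-tree predictions. Two 95% interval
notions are reported where relevant: per-tree quantiles of the tree
predictions for a single profile (`predict_interval`), and
across-patient quantiles of per-patient predictions for a simulated
population (counterfactual results carry both; the across-patient
limits are clamped to bracket the mean, which empirical quantiles of a
heavily skewed sample need not do). The default tree count for tests
and desk-scale runs is 200; 5,000 is the fidelity setting and is the
CLI default for standalone forest fits.

## Proportion contrasts

Patients are ranked by proportion-in-window and cut into k = 2 or 3
near-equal groups (rank r of n goes to group ⌊rk/n⌋; ties at a
boundary resolve by stable file order, so the split is deterministic
and seed-free). A cohort in which every patient has the same proportion
(e.g. the full window 8–25) is a degenerate split and raises.

Kruskal–Wallis uses the standard tie-corrected H with a chi-square
reference (scipy), with one added convention: if all pooled
observations are identical, H = 0 and p = 1 rather than an error. Dunn
post hoc z statistics use the rank-mean formula with the pooled tie
correction; the default multiple-comparison adjustment is Holm (the
usual "Dunn's correction" is ambiguous between software defaults;
Bonferroni and none are exposed). Top-vs-bottom deltas are reported on
means, with median deltas alongside, since clinical reports rarely say
which they quote. The confounder check compares total follicle counts
between the extreme groups (KW, k = 2): a significant difference warns
that an outcome contrast partly reflects follicle number, not profile.

## Counterfactual simulation

Scenario patients carry a fixed number of follicles (default 20, a
typical stimulated cohort size) allocated uniformly at random over the
window bins (`all_in_window`) or over the complement within 8–25 mm
(`all_out_window`); the allocator is pluggable since no canonical
choice exists. The two scenario prediction samples are compared with a
two-sided Mann–Whitney U test (Welch's t optional). A coverage
diagnostic reports the fraction of scenario profiles with any bin count
outside the training range; out-of-window scenarios are usually far
outside the training support (the trigger rule guarantees real patients
in-window follicles), so their predictions are extrapolations and
should be read as such.

A structural property worth knowing: trees condition on per-bin counts,
and a uniform 20-follicle in-window profile has only ~2.5 follicles per
bin — middling values unlike any high-yield training patient — so the
forest's all-in prediction sits well below the analytic per-follicle
rate times 20. The comparison between scenarios (direction, gap,
significance) is robust; the absolute all-in level is shrunk toward the
training mean.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes,
with known ground truth:

* **Follicle count** N per patient: negative binomial (mean m,
  size k, variance m + m²/k), truncated below at the lead-rule count.
  Presets: `hcg_like` (m = 14, k = 50), `gnrha_like` (m = 17, k = 6),
  `kisspeptin_like` (m = 27, k = 5) — means matching the three study
  arms' reported medians of trigger-day follicle counts (14/17/27),
  dispersions set so the interquartile ranges are of the reported
  order.
* **Diameters**: skew-normal, location 14 mm, scale 3 mm, shape −2 (a
  left tail of small follicles trailing the leads). Each patient's
  scale is multiplied by a log-normal factor (σ = 0.35), modelling
  between-patient differences in follicular synchronization; this is
  what makes the proportion-in-window vary across patients (roughly
  0.6–1.0 for a 12–19 mm window), the variation the contrast stage
  needs. Per-bin diameter distributions are not reported for real
  cohorts; the skew-normal family and these values are package choices.
* **Trigger conditioning**: all diameters are rigidly shifted so the
  n-th largest equals the lead threshold (n = 2 at 17 mm for
  hCG/GnRHa-like, n = 3 at 18 mm for kisspeptin-like), emulating a scan
  taken on the morning the clinical trigger rule fires, without a
  growth model. Shifted diameters at or below zero are dropped (they
  are far below the 8 mm aspiration floor). This conditioning induces a
  mild negative coupling between total count and post-shift diameter
  level (more draws → larger n-th order statistic → smaller shift); with
  the spread heterogeneity above, the net proportion/total correlation
  is near zero.
* **Outcomes**: each binned follicle yields an oocyte with probability
  given by the yield curve (step or double-logistic plateau over
  [lo_true, hi_true], defaults 12–19 mm, p_in = 0.8, p_out = 0.1);
  downstream counts are nested binomial thinnings with default rates
  0.8 (mature | oocyte), 0.7 (zygote | mature), 0.5 (embryo | zygote),
  0.4 (grade 1 | embryo) — typical laboratory maturity/fertilisation/
  usable-embryo/top-grade rates. The latent per-follicle draws are kept
  in `GroundTruth`, so tests can compare analytic expectations
  (E[oocytes | h] = Σ_d c_d p(d)) with observed counts.

One seeded generator is threaded through all draws in fixed patient
order: a config is a complete, byte-reproducible specification of a
cohort.

**What passing the synthetic validation shows — and does not.** The
recovery tests establish that each stage finds a planted
diameter-dependent yield structure under realistic cohort shapes, at
realistic sample sizes, and that the stages agree with independent
oracles where closed forms exist. They do not establish clinical
validity on real cohorts: the generator has no measurement error in
follicle sizing, no inter-observer variation, no per-patient frailty in
the cascade rates, no relation between oocyte competence and diameter
beyond the yield curve, and its per-follicle independence assumption is
a simplification. Real effect sizes (the published tertile deltas of
~5 oocytes) are larger than the generator's defaults produce, because
real cohorts are more heterogeneous than the calibrated synthetic ones.

## Pipeline and reproducibility

`run_pipeline` executes scan → GLM → forest → contrasts →
counterfactual; the contrast/counterfactual window defaults to the
scan's best window for the first requested outcome, with
`window_override` available to pin the consensus 12–19 mm window (the
published choice triangulated across methods by inspection — no
automated fusion rule is invented). All intermediates are written as
CSV/TSV/JSON; the report (JSON + Markdown) contains no timestamps and
is a pure function of the config, so identical configs give
byte-identical reports; stage timings go to the log only. Forests
serialize to a versioned JSON schema (structure and parameters;
training data are not serialized, so permutation importance requires
the in-memory model).

Problem sizes used by the test suite and `scripts/acceptance.py`
(n = 300–500 patients, 100–200 trees, 50-seed recovery batches,
10,000-patient invariant sweeps) are desk-scale choices that keep a
full run in the low minutes while leaving all Monte-Carlo margins
wide; the fidelity tree count (5,000) changes importance scales but
not rankings.

## Known limitations

* The generator's trigger-rule conditioning is a rigid shift, not a
  growth model; day-before-trigger scans and growth-rate questions are
  out of scope.
* Per-follicle outcome linkage (which follicle gave which oocyte) is
  available only in the synthetic ground truth — real per-cycle data do
  not contain it, so per-follicle claims can only be validated
  synthetically.
* The window scan's 171 fits are mutually dependent; its p values are
  unadjusted and should not be read as confirmatory.
* Impurity importance inherits CART's bias toward features with more
  distinct values; with small integer counts this is mild, and the
  permutation cross-check guards the rankings.
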