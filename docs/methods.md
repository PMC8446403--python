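# Methods

This note documents the statistical procedures, the conventions chosen where
the methodology literature leaves room, the synthetic-data model and its
limits, and the numerical choices that matter for reproducing results.

## Standardized regression-based change

For each cognitive measure, follow-up scores of the *control* group are
regressed by ordinary least squares on baseline score, premorbid IQ
(an information-subtest scale score), and age, with intercept. The intercept
absorbs the mean practice effect, the baseline slope absorbs
regression-to-the-mean, and the covariates absorb demographic drift. Every
participant — patient or control — is then scored as
`z = (observed follow-up − predicted follow-up) / SEE`.

Conventions:

- **SEE denominator** is n − 4 (n minus all fitted parameters including the
  intercept), the standard OLS residual-standard-deviation convention.
- **Direction harmonization**: timed tests (trail-making, in seconds) and
  error counts are lower-is-better; their z is negated before
  classification so that positive harmonized z always means improvement.
  This makes the global composite well-defined when averaging time-scored
  and accuracy-scored tests.
- **Classification** uses inclusive bounds: z ≤ −1.64 declines, z ≥ +1.64
  improves. 1.64 is the two-tailed 10% normal quantile, i.e. the extreme 5%
  at each end.
- **Global composite (GCS-z)** is the unweighted arithmetic mean of all
  harmonized per-measure z (no domain-level pre-averaging), classified with
  the same ±1.64 rule. Because averaging 15 z-scores shrinks the variance of
  the composite well below 1, composite-level change is much rarer than
  per-measure change; a cohort with per-measure rates of 10–30% can easily
  show 0% composite change.
- **No shrinkage** is applied to the control regression despite the small
  reference group (n ≈ 21, 3 predictors); this mirrors standard practice for
  SRB norms and keeps z interpretable as a standardized residual.
- **Sensitivity re-analysis** (excluding metastatic patients) refilters the
  classified subjects only; SRB models depend only on controls and are not
  refitted.

A caveat worth stating precisely: with a reference fit of n controls and
p = 4 parameters, the null distribution of z for a *new* subject is not
exactly standard normal — prediction error inflates its SD by roughly
√(1 + p/n) (≈ 1.09 at n = 21), so the realized null decline rate at 1.64 is
closer to 6.5% than 5%. The calibration checks therefore use a large
reference fit (n = 2000), for which z is N(0,1) to high accuracy and the
lower-tail mass is Φ(−1.64) = 5.05%. At the study's n = 21 the inflation is
a property of the method itself, not of this implementation.

## Exact-test comparison and odds ratios

Rates are compared with the two-sided Fisher exact test in the
point-probability convention: the p-value sums the hypergeometric
probabilities of all tables with the observed margins whose point
probability does not exceed the observed table's. The test is validated
against exhaustive integer-arithmetic enumeration for every table with row
margins ≤ 25.

Odds ratios are oriented as event odds in patients over controls. When any
cell of the 2×2 table is zero, the Woolf–Haldane correction adds 0.5 to
**all four** cells before forming both the OR and its CI — this variant (as
opposed to correcting only zero cells) is the one that reproduces published
zero-cell ORs such as 2.95, 7.06, 11.98, and 15.84 exactly. Confidence
intervals are Woolf logit intervals on the (possibly corrected) cells. The
critical value defaults to the conventional two-decimal quantile (1.96 at
95%), which is what published tables use; the exact quantile differs in the
second decimal of extreme bounds (e.g. 68.37 vs 68.38) and can be requested
via `z_value`.

BCa bootstrap intervals for mean differences use 10,000 resamples and
jackknife acceleration (scipy's implementation); degenerate samples fall
back to the percentile interval with a warning. The group × time interaction
for paired two-timepoint data is computed as the between-group one-way ANOVA
on per-subject Δ, which is algebraically identical to the mixed-ANOVA
interaction F with two within-levels (unit-tested against an independent
mixed-ANOVA implementation); a standardized-coefficient regression of Δ on
(baseline, group, group × baseline) is reported alongside.

## Connectome analysis

Inputs are symmetric nonnegative weighted matrices over a 90-region atlas
ordering in which nodes 77/78 (1-based) are the left/right thalamus. Edge
weights are taken as supplied by upstream tractography; the pipeline is
agnostic to their definition (streamline count, density, ...).

- **Strength normalization** divides all weights by the mean off-diagonal
  upper-triangle weight (zeros included), making the analysis invariant to
  global weight rescaling.
- **Density thresholding** keeps the k = round(d·n(n−1)/2) strongest edges
  and binarizes. Ties at the cutoff are broken by node-index lexicographic
  order for reproducibility. Graph metrics are computed on binary graphs —
  consistent with density-grid analysis, where the weighted information has
  already been consumed by edge selection.
- **Density grid**: 0.06–0.12 in steps of 0.01 (7 points). Metrics are
  summarized as the trapezoidal AUC over the grid, ×100.
- **Clustering** is the mean local clustering coefficient with degree < 2
  nodes contributing 0. **Path length** averages shortest-path lengths over
  reachable ordered pairs only; disconnected pairs are excluded and counted
  in the log (fragmentation is possible at the low end of the grid).
- **Null models**: each thresholded graph is compared against 20
  degree-preserving randomizations produced by double edge swaps (10·|E|
  accepted swaps per null; swaps creating self-loops or multi-edges are
  rejected), seeded and fully reproducible. The swap loop is numba-compiled
  for throughput. SW = (C/C_rand)/(L/L_rand).
- **Normalized node degree** is degree divided by mean network degree — a
  convention choice, stated prominently because "normalized degree" is
  ambiguous in the literature; absolute node-degree AUC values are therefore
  not comparable across normalization conventions.
- **Group × time tests** per metric/node use the Δ ANOVA above;
  Benjamini–Hochberg FDR is applied across the 90 nodes within each nodal
  metric.

## Endocrine quantities and predictor models

Calculated free testosterone solves the two-protein mass-action equilibrium
with association constants K_SHBG = 1.0×10⁹ L/mol and
K_albumin = 3.6×10⁴ L/mol — the canonical published values — and albumin
defaulted to 43 g/L when not assayed (molar mass 66,500 g/mol). The
closed-form positive quadratic root is used; an independent fixed-point
iteration of the mass balance agrees to < 10⁻⁶ nmol/L across the
physiological range. Because the albumin concentration is defaulted rather
than measured, cohort free-T means are plausibility anchors (±0.02 nmol/L),
not exact targets.

Δ-scores are follow-up minus baseline throughout. Predictor models are
within-group simple regressions of cognitive change (continuous harmonized z
primarily; binary category available) on each candidate predictor, with a
pooled group × predictor interaction model fitted as follow-up when a
within-group test is significant. The testosterone models can adjust for
matching SHBG and CAG repeat length. Multiple testing across predictor
models is deliberately *not* corrected — these are exploratory, dependent
analyses — but a BH flag is available downstream.

## Synthetic cohort generator

The generator's defaults are the study conditions: 38 patients vs 21
controls; group-specific age (37.7 ± 12.0 vs 36.3 ± 12.1 years), premorbid
IQ (9.3 ± 3.2 vs 11.6 ± 2.3), genotype carrier frequencies, CAG repeat
distributions, and hormone baseline/Δ trajectories taken from the published
group summaries (patient SHBG rising by ~9 nmol/L while controls stay flat;
patient neutrophils falling); 5 of 38 patients flagged metastatic.

Cognitive scores: control follow-up is linear in baseline, IQ, and age plus
Gaussian residual, with per-measure practice effects; baseline means/SDs and
residual SDs are chosen at realistic raw-score scales for each test (e.g.
trail-making ~25 ± 8 s, delayed recall ~9 ± 2.5 items). Patients follow the
same model plus configured effects: Bernoulli decline subgroups on
processing-speed/visuospatial measures and improvement subgroups on delayed
recall and visuospatial learning, each shifting the follow-up score by
≈ 2–2.2 residual SDs in the relevant direction. These defaults reproduce the
qualitative published pattern (patient excess decline on speed/visuospatial
tests, excess improvement on recall measures) without matching exact counts,
which are facts of the real data.

Connectomes are Watts–Strogatz ring lattices (90 nodes, k = 12 neighbours,
rewiring 0.1) with lognormal edge weights (σ = 0.5) and lognormal edge-level
t1→t2 jitter (σ = 0.1); at follow-up, designated thalamic nodes of the
control group receive a degree shift (−4 left, +4 right) implemented by
suppressing the node's strongest edges or adding top-weight edges. All draws
derive from a single seed; the generative ground truth (coefficients,
subgroup memberships, designed shifts) is returned for recovery tests.

What the generator does **not** emulate: measurement floors/ceilings and
integer score granularity (scores are continuous and may stray outside
instrument ranges); item-level response processes; correlated residuals
across measures; hormone assay detection limits (values are truncated at 0);
anatomically realistic connectome geometry beyond small-worldness.
Passing tests therefore demonstrate correctness of the statistical machinery
under the stated generative model, not robustness to the idiosyncrasies of
real neuropsychological data.

## Numerical and scale choices

- Problem sizes: calibration uses a 2,000-control reference fit and 10,000
  scored null subjects; subgroup recovery uses 500 patients; coefficient
  recovery averages 500 replicate fits at n = 21; graph-metric oracles use
  200 random graphs of ≤ 30 nodes (betweenness enumeration on ≤ 20 nodes);
  the exact-test sweep enumerates all tables with row margins ≤ 25.
- Connectivity matrices are symmetrized as (M + Mᵀ)/2 when asymmetry is
  ≤ 10⁻⁶ and rejected otherwise; diagonals are forced to zero; a fit with
  numerically zero residual variance (SEE² ≤ 10⁻¹⁶·var(y)) is rejected as
  degenerate rather than producing infinite z.
- Result tables are written at full precision with fixed column order; the
  run manifest records seed and a config hash (excluding the output path),
  so identical config+seed reruns are byte-identical.
- Display rounding follows the published-table conventions: percentages to
  1 d.p., ORs/CIs to 2 d.p.

## Known limitations

- The SRB null-rate inflation at small reference samples (above) means
  per-measure "5% tail" rates are nominal, not exact, at n = 21.
- Absolute node-degree AUC values depend on the degree-normalization and
  null-model conventions; only within-pipeline contrasts are meaningful.
- The exact-test p and the printed values of historical tables can disagree
  in the second decimal where those tables' own rounding chains differ from
  full-precision computation.
- Fragmented graphs at low densities silently shorten the path-length
  average (reachable-pairs convention); heavy fragmentation makes L/L_rand
  unstable.
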