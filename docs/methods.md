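# Methods

This note documents the statistical procedures, the synthetic data model,
the numerical conventions, and the design choices where more than one
reasonable reading existed. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Normalization (log2 TMM-TPM)

Stages run in a fixed order: low-count filter → gene-length scaling →
TMM factors → TPM → log2 → sample QC.

* **Low-count filter.** A gene is removed when its total raw count across
  all samples is ≤ `low_count_max` (default 10, strictly "≤"). Removing
  every gene is an error, and the operation is idempotent.
* **Length scaling.** With per-sample effective lengths L[g,s], each
  length is divided by its per-gene geometric mean across samples and the
  counts divided by that normalized length. With per-gene constant
  lengths the step is exactly a no-op; length differences between genes
  then enter nowhere, which is intentional — the quantity being
  normalized between samples is the within-gene length variation that
  transcript-abundance estimators produce.
* **TMM.** The reference library is the sample whose upper-quartile count
  fraction is closest to the mean of those fractions. For each library
  against the reference, genes zero in either library are dropped;
  M-values (log2 ratio of count fractions) are trimmed 30% from each tail
  and A-values 5% from each tail, both by rank with average ties; the
  factor is 2 to the inverse-variance-weighted mean of surviving
  M-values, with the asymptotic binomial (delta-method) variance
  1/x − 1/N per library as the variance. Factors are rescaled to
  geometric mean 1 (asserted to 1e-9 in tests). The implementation is
  checked against an independently written plain-loop reference
  evaluation at 1e-6, and was verified during development to agree with
  the edgeR implementation to ten decimals on random matrices.
* **TPM.** Effective library size = length-scaled column sum × TMM
  factor; TPM = scaled counts / effective size × 1e6, so TPM columns sum
  to 1e6/factor. Expression = log2(TPM + 1). The pseudocount of 1 keeps
  the transform bounded below by 0 and is the common choice for TPM; it
  is configurable. One consequence worth knowing: log2-TPM is *exactly*
  invariant to uniform rescaling of a sample's counts only at fixed TMM
  factor — the inverse-variance trim weights depend weakly on absolute
  depth, so the factor itself (and hence the column) can move at the
  third decimal. The tests assert the exact decomposition rather than
  pretending to exact invariance.
* **Sample QC.** Pairwise Euclidean distances over all retained genes on
  the log2 scale; per-sample median distance to the others; threshold
  P75 + 3·IQR of those medians; flagged strictly above the threshold
  ("exceeding" read as strict). At least 4 samples are required. A
  separate pass-through helper applies the upstream alignment-QC rule
  (< 75% uniquely mapped reads) to an externally supplied metadata table;
  alignment metrics are never computed here.

All quantiles everywhere in the package (P25/median/P75, dichotomization
thresholds, the TMM reference choice) use linear interpolation between
order statistics — numpy's default, matching R's type 7 — fixed once so
results are reproducible across stages.

## Metagene scoring and the CDKPredX classifier

A metagene score is the unweighted arithmetic mean of log2 expression over
the set's genes present in the matrix. If fewer than
`min_fraction_present` (default 0.5) of a set's genes are found, scoring
fails with an error naming the missing genes; the 0.5 default reflects
that cross-platform validation cohorts rarely contain every gene.

Dichotomization is at a cohort quantile — median, or lower quartile for
the proliferation module — with ties resolved as score ≥ threshold →
high. This tie rule makes a median split deterministically at least 50%
high. "Lower quartile for Pr" is read as *Pr high when at or above Q1*
(≈75% of samples pass), i.e. a permissive proliferation gate; the
opposite reading (top quartile) would radically change prevalence and is
not what a permissive gate implies. CDKPredX+ = Pr high ∧ Er high ∧ Im
low. Under mutually independent module scores the expected positive
fraction is 0.75 × 0.5 × 0.5 = 18.75%, which the tests verify at n = 2000.

The three module gene lists are not hard-coded: they ship as ordinary GMT
files (the synthetic generator writes placeholder lists) and users
substitute published lists. Application to an external cohort re-derives
the same quantile *levels* (Q1, median, median) within that cohort by
default, which is the reading of "same cutoffs" that survives platform
shifts — a global +3 log2 shift of an external cohort leaves labels
unchanged. Transferring the derivation cohort's absolute thresholds is
supported as a non-default mode because the phrase is genuinely ambiguous.
Single-sample (cohort-free) prediction is out of scope.

## Association statistics

* 2×2 tables are oriented rows = treatment (CDK4/6i-containing arm
  first), columns = responder/non-responder; OR = ad/bc with Wald CI and
  two-sided Wald p. The z quantile is computed (Φ⁻¹(0.975)), not a
  hard-coded 1.96. Zero cells are an error unless Haldane's +0.5 is
  requested.
* Fisher's exact test (two-sided, hypergeometric summation) comes from
  scipy and tolerates zero cells.
* The interaction model is endpoint ~ arm + biomarker + arm×biomarker on
  complete cases. The default test is the likelihood-ratio test of the
  interaction term. Because the four-parameter model saturates the four
  arm×biomarker cells, its sup-log-likelihood is computed in closed form
  from the cell response rates (with 0·log 0 = 0); this keeps the LRT
  defined even when a pure cell (all responders or none) pushes the
  iterative MLE to infinity. The Wald variant genuinely requires a finite
  MLE and raises an explicit error naming the degenerate cells; an empty
  cell makes the interaction unidentifiable and is always an error. The
  additive (reduced) model is fitted by maximum likelihood via
  statsmodels. Per-stratum odds ratios with Wald CIs are reported
  alongside (Haldane fallback on zero cells). No multiplicity adjustment
  is applied to association p-values.
* Count reconstruction inverts one-decimal printed percentages: r is
  accepted when |100·r/n − rate| < 0.05. For two rates with a
  constrained total, the split is exhaustively searched; no solution and
  multiple solutions are distinct, explicit errors (ambiguities list all
  candidates). ORR denominators are treated as explicit inputs
  throughout — evaluable-population sizes are not derivable from rates
  alone.
* Clinical formulas: complete cell cycle arrest is Ki67 ≤ 2.7% (boundary
  inclusive); easTILs% = 100 × TIL cell area / stroma area (unit
  invariant); SUVmax response is the week-12/baseline ratio with
  relative decrease 100 × (1 − ratio).

## Differential ranking and enrichment

The negative-binomial count model of dedicated DE packages is not
re-implemented; a Welch (unequal-variance) two-sample t-test on log2
expression provides the per-gene p-value and the difference of group
means the log2 fold change. The artifacts that matter downstream — the
signed significance ranking −log10(p)·sign(LFC), the BH threshold 0.05
with |LFC| > 0.5 for DEG selection (both strict), and the GSEA settings —
are implemented exactly. Zero p-values are floored at the smallest
positive double before the log. Externally computed per-gene p/LFC tables
(e.g. from an interaction DE design) can be fed directly into the ranking
and enrichment stages.

Pre-ranked GSEA: enrichment score = signed maximal deviation of the
running sum with hit increments proportional to |rank score| (weighting
exponent 1, the cited tool's default) and uniform miss increments. The
null is gene-label permutation — the only permutation scheme available
from a pre-ranked list — with the null distribution shared across sets of
equal effective size. Null ES values are evaluated only at hit positions
(an O(k) identity of the running sum), making 200 sets × 1000
permutations a few seconds of work. NES = ES / mean |null ES| of the
matching sign; the permutation p is sign-matched with a +1 numerator and
denominator correction; BH across sets. Set sizes outside [10, 500] after
intersection with the ranking are dropped. Everything is deterministic
given the seed.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not real
transcriptomes:

* Three disjoint gene modules (default sizes 16/4/11, total 31 — the
  per-module split of the published 31-gene predictor is not public, so
  the split is an explicit, documented placeholder) against a background
  gene universe (default 2000 genes).
* Per sample, binary latent module states drawn independently at rates
  (0.75, 0.5, 0.5) — chosen to mirror the classifier's quantile gates so
  latent truth and cohort-quantile calls agree in expectation.
* Latent log2 expression = per-gene baseline N(5, 1.5²) + state shift
  (±`module_mean_shift`/2, default 1.5 log2 units between states) +
  shared within-module factor (variance fraction
  `within_module_correlation`, default 0.5) + independent noise, total
  noise SD `noise_sd` = 0.6 log2 units.
* Counts: Poisson around rates proportional to 2^latent × gene length,
  scaled to a lognormal per-sample depth (mean 1e6). Poisson suffices to
  exercise normalization; negative-binomial overdispersion was considered
  and left out as it adds a parameter no downstream stage is sensitive
  to.
* The true biomarker label applies the classifier rule to the *noise-free*
  module means (equivalently the latent states), not to post-hoc cohort
  quantiles, so truth is independent of cohort composition and gives an
  unambiguous recovery target.
* Treatment arm is Bernoulli (default 0.5, arm B = CDK4/6i first);
  response is Bernoulli with log-odds c₀ + c₁·arm + c₂·label +
  c₃·arm·label. The default coefficients anchor the chemotherapy-arm
  response rates at the reconstructed trial tables (40/61
  biomarker-negative, 6/19 biomarker-positive) and set the within-stratum
  odds ratios to exactly 0.40 and 1.99. Secondary endpoints (ORR24, pCR,
  RCB class, Ki67 and SUVmax trajectories, including deeper Ki67
  suppression under CDK4/6i and deeper SUVmax suppression under
  chemotherapy) are generated with plausible marginals for
  schema-completeness; no analysis in this package calibrates against
  them.
* Expression outliers: `outlier_count` samples receive a latent shift of
  uniform magnitude `outlier_shift` with a random sign per gene. A
  same-sign shift on every gene would cancel exactly in the
  depth-normalized count link and again in TPM, so the sign flip is what
  makes an injected outlier geometrically detectable; a shift of ≥5 log2
  units on a 100-sample cohort is reliably the only flagged sample.
* All randomness flows from one integer seed through independent
  substreams (gene parameters, latent expression, clinical, outlier
  choice, count noise), so identical seeds give bit-identical cohorts and
  changing only the outlier settings perturbs nothing else.

What passing tests on these cohorts do *not* show: robustness to real
full-transcriptome covariance, batch effects, library-preparation
artifacts, or any property of the actual trial data, which are controlled
access. Trial-scale observed quantities (e.g. the 25.8% positive
prevalence among 163 patients, or signature correlations) are therefore
reconstructed from printed summary numbers where possible and otherwise
replaced by property checks at desk scale.

## Problem sizes and numerical conventions

The simulation-based checks use 500 replicate cohorts of n = 180 (the
trial's scale) for CI coverage and interaction type-I error, n = 2000
score-level cohorts for prevalence, 200 random sets × 1000 permutations
for enrichment calibration, and an n = 50,000 cohort in the acceptance
script where a few-percent Monte-Carlo SE on a refitted odds ratio is
wanted. Ties in dichotomization go high; boundary comparisons are strict
where the source formulation says "exceeding"/"below" (outlier threshold,
DEG cutoffs) and inclusive where it says "≤" (low-count filter, CCCA).
Degenerate inputs have defined behavior: all-identical scores dichotomize
to all-high with a warning; an all-zero count matrix, an all-zero sample,
empty gene sets and sub-minimum module coverage are errors.

## Known limitations

* The shipped module gene lists are synthetic placeholders; scientific
  use requires the published Pr/Er/Im lists.
* The Wald CI convention reproduces published lower bounds; published
  upper bounds appear to follow a different (unstated) convention and are
  not targeted.
* The DE substitute (Welch test on log2 expression) will not reproduce
  count-model shrinkage behavior for low-count genes; rankings feeding
  GSEA are comparable, per-gene inference near the detection limit is
  not.
* Single-sample classification, survival analysis, intrinsic subtyping
  and copy-number integration are out of scope.
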