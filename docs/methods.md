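# Methods

## Conformal machinery

**p-values.** For a test nonconformity score α against calibration scores
α_1…α_n, the counting rule is p = (#{α_i ≥ α} + 1)/(n + 1), with ties
counted as ≥ (the conservative choice that preserves the validity
guarantee). Linear interpolation between the counting-rule values at the
sorted calibration scores is available for small calibration sets and is
the default for classification: the interpolated p equals 1 below the
smallest score, 1/(n+1) above the largest, and between adjacent scores
lies within 1/(n+1) of — and never below — the step function, so
interpolation cannot destroy class-conditional validity while removing
the coarse discretization of tiny Mondrian calibration sets.

**Intervals.** The interval at confidence c is ŷ ± α*·(exp(μ̂) + β) with
α* the ⌈c·(n+1)⌉-th order statistic of the calibration scores. If that
index exceeds n the interval is unbounded; it is returned with an
infinite half-width and flagged, and the median aggregation across a CCP
keeps the final interval finite as long as most members are. An
interpolated quantile (linear between adjacent order statistics at the
fractional index c·(n+1)) is available behind a flag but is *off* by
default: the ceiling order statistic is the form with the exact
finite-sample guarantee, and the interpolated variant trades a little
coverage for narrower intervals.

**Nonconformity.** Classification uses the negative signed distance to
the linear SVM decision surface toward the hypothesised class, with the
active class mapped to the positive side. Regression uses the normalized
measure α = |y − ŷ|/(exp(μ̂) + β): the error model predicting μ̂ is a
second linear SVR trained on ln(|y − ŷ| + δ) of the proper-training
residuals, δ = 10⁻⁶ guarding exact fits, and β = 0.01 smooths the
denominator. In-sample residuals understate out-of-sample error, but any
systematic understatement is absorbed by the calibration quantile; what
the error model contributes is the *relative* per-compound scaling of
interval widths.

**Learners.** L2-regularized L2-loss linear SVMs (LIBLINEAR via
scikit-learn), cost 0.25, SVR tube ε = 0.01, termination tolerance
0.001 — sensible defaults for high-dimensional sparse count descriptors,
kept fixed across all strategies so that comparisons reflect data
composition rather than tuning. The scoring model is pluggable through
`LearnerConfig`/`fit_icp_*`'s `model` argument.

**Aggregation.** Cross-conformal predictors use k = 10 shuffled
contiguous-block folds; per-class p-values and interval bounds are
aggregated componentwise by the median. With even k the midpoint of the
two central order statistics is used (a `median_rule="lower"` dialect is
provided since the convention is not universal). Median aggregation of
ICP p-values carries no strict finite-sample guarantee; empirically it is
mildly conservative here, which the validity tests confirm.

**Minimum calibration.** Every Mondrian calibration fold must contain at
least one example of each class, and every calibration set at least one
row; strategies refuse the cell otherwise, and the study harness records
such cells as "skipped" rather than dropping them.

## Preparation rules

Records above 100 μM are outside the typical experimental range and
dropped; an optional exact-value filter removes a known over-represented
artifact concentration (33.3 μM in Na_V-like data). Duplicated
(compound, assay) measurements keep the most recent record by default —
recent measurements are the most relevant to ongoing chemistry — with
"median" and "keep_all" policies available. Classification labels use
the 10 μM threshold (active iff IC50 ≤ 10 μM; ">" qualifiers can only
certify nonactivity, "<" only activity, anything else is undetermined
and dropped). Regression keeps qualifier-free records only and targets
pIC50 = 6 − log10(IC50/μM). Every dropped record is attributed to exactly
one rule in a plain-text audit log, and the filter pipeline is
idempotent.

## The synthetic two-assay generator

The generator emulates the structure of a real assay transition without
any proprietary data:

* **Descriptors.** Sparse non-negative integer counts (signature-like),
  d = 500 by default with ~30 nonzeros per record and counts
  1 + Poisson(1). Real signature spaces exceed 10⁴–10⁵ dimensions; d is
  a desk-scale choice and configurable.
* **Chemical-space shift.** Each assay draws descriptor positions from
  its own support: the old assay from the first 80% of the dimensions,
  the new assay from the last 40% (20% overlap by default). This encodes
  the empirical observation that a legacy assay has covered a broader
  and partly different region of chemistry, and it is what makes a model
  trained purely on old data genuinely less informative about new-assay
  compounds.
* **Potency.** Latent pIC50 = 5 + z(x) + e with z the standardized
  descriptor score and e ~ N(0, 0.3) compound-level noise; per-assay
  class balance (45% actives new, 30% old by default, matching the
  historical datasets) is met by stratified sampling on the latent
  potency at the 10 μM threshold — a population difference, not a
  measurement artifact.
* **Measurement shift.** The new assay reports potency + ν,
  ν ~ N(0, 0.2); the old assay reports 5 + a·(potency − 5) − b + ν with
  slope a = 0.9 and offset b = 0.1 pIC50 by default (old assay reads
  less potent). Setting a = 1, b = 0, full supports and equal fractions
  (`GeneratorConfig.no_shift`) makes the assays statistically identical —
  the exchangeable limit in which every strategy must be valid.
* **Augmentation.** To simulate a much less concordant transition,
  old-assay measurements can be disturbed on the IC50 scale:
  IC50' = IC50 + c·IC50² + G(5, 0.5) μM with c = 0.01/μM — a quadratic
  term growing with concentration plus a fixed shift with noise;
  descriptors are unchanged. Non-positive results are clipped to
  0.001 μM with the count reported.
* **Qualifiers.** A configurable censoring rate turns the highest-IC50
  records into ">" measurements at the 100 μM assay ceiling, exercising
  the preparation filters.

What the generator does *not* emulate: real chemistry (no structures,
scaffolds or cliff behavior), assay-specific error structure beyond
Gaussian noise, or temporal drift within an assay. Passing validity and
trend tests on this generator shows the conformal machinery and the
strategy logic are correct under controlled shift; it does not certify
performance on any particular real assay pair.

## Study harness

Per replicate r the base seed expands deterministically (via
`numpy.random.SeedSequence` over (base_seed, r, fold, …) tuples, all
derived seeds < 2³¹) into shuffling, CV-splitting, sampling and learner
seeds. The full new-assay set is split into 10 CV folds; the held-out
fold is the test set (testing is always on new-assay data), n_new is
drawn per fold from the remaining split and n_old from the full old
dataset, and all strategies in a cell share the identical samples and
test fold, so efficiency differences across strategies are paired.
Sampling is without replacement; with n_old near |A_old| the replicate
variance shrinks because replicates overlap — aggregated confidence
intervals then describe the fixed available dataset, not fresh compound
draws. Aggregation averages folds within replicate, then reports the
mean and a t-based 95% CI over replicate means.

## Validity assessment

Calibration curves use a 0.05…0.95 step 0.05 confidence grid. The
validity flag is one-sided with tolerance 0.025: a model is invalid iff
empirical accuracy falls below confidence − 0.025 at any gridpoint;
overconservative models are valid. Empty classification prediction sets
count as errors (the truth cannot be in an empty set); a lenient flag is
provided. Tests of the conformal guarantee compare mean coverage over 20
seeded replicates against the confidence level minus a two-standard-error
Monte Carlo allowance computed from the seed spread, since the guarantee
is "≥ c in expectation" and any finite-seed mean fluctuates around the
conformal expectation ⌈c(n+1)⌉/(n+1).

## Desk-scale study conditions

The bundled evaluations use n_train = 2000–3000 with d = 500 for the
classification validity checks, n_old = 3000 / n_new = 500 for validity
under shift (slope 0.6, offset 0.5 pIC50 — a deliberately strong
disagreement), n_old = 2000 / n_new = 200 for the pooling-invalidity
demonstration, and n_old = 6000 = 10·n_new for the efficiency-trend
comparison (10 replicates), chosen so the new-assay model is neither
hopeless nor saturated at the default descriptor dimension. All are far
below the historical dataset sizes; the qualitative conclusions (which
strategies stay valid under shift, pooling's failure mode, the
efficiency ordering CCP_AT ≤ CCP_new ≤ ICP_old_new) are the reproducible
content, not the absolute efficiency numbers.

## Known limitations

* Median-aggregated CCPs are not formally guaranteed valid; monitor the
  calibration curves, which is the package's central recommendation
  anyway.
* The interpolated p-value/quantile dialects follow one reasonable
  formula each; other implementations interpolate differently, hence the
  flags.
* `concordance_summary`'s paired t-test is an informational readout, not
  a decision procedure.
* Linear models only are exercised; the ICP contract accepts any
  fit/predict scoring model, but nonlinear learners are untested.
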