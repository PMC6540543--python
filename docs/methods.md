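# Methods

## The statistical model

The package treats a biomarker screen as K independent two-class expression
studies per comparison. Study k measures G genes on n₁ case and n₀ control
samples; values are log2-scale intensities assumed approximately Gaussian
within a class (the convention for RMA-normalized arrays). The analysis
asks, per gene, whether the case class is consistently shifted across
studies, by two deliberately different routes:

1. **Evidence combination.** Within each study a moderated t statistic is
   computed with a SAM-style fudge constant s₀ in the denominator,
   t = (x̄₁ − x̄₀)/(s_p·√(1/n₁+1/n₀) + s₀). Significance comes from a
   label-permutation null: B permutations of the class labels, with the
   null t statistics of all genes pooled into one reference of size B·G,
   giving one-sided p-values with resolution 1/(1+B·G) and an add-one
   correction so p > 0. Across studies the one-sided p-values are combined
   per side by Fisher (−2Σ ln p, χ²(2K)), maxP (m^K), roP (Beta(r, K−r+1)
   at the r-th order statistic) or the adaptively-weighted statistic
   (below), then wrapped two-sidedly as p = min(1, 2·min(p_right, p_left))
   with the winning side defining the direction.
2. **Effect-size pooling.** Hedges' g (bias-corrected standardized mean
   difference) with its analytic sampling variance is pooled by the
   DerSimonian–Laird random-effects moment estimator; significance is the
   two-sided normal tail of z = μ̂/se(μ̂).

A gene is *selected* only when both routes pass an FDR threshold with the
same direction, in the training *and* the validation cohort, and is
*GBM-specific* only if additionally differential (same direction) versus
both other glioma subtypes. The multi-stage intersection — not any single
threshold — is what controls false discoveries; this mirrors the logic of
published multi-cohort screens whose specific gene counts depend on their
own data and are not reproduced here.

### The AW statistic

For 0/1 study weights the Fisher statistic on any subset of fixed size j is
maximized by taking the j smallest p-values, so only the K sorted prefixes
need to be searched (verified in the tests by brute force over all 2^K−1
subsets at K=4). The statistic is the minimum over j of the χ²(2j) tail
value of the prefix-Fisher statistic; the minimizing prefix is reported as
the weight vector. A minimum of dependent tail probabilities is not
uniform, so its p-value is read off an empirical null of B_aw simulated
uniform p-matrices. Consequence: AW p-values are floored at 1/(1+B_aw) —
with the default B_aw = 1000 the two-sided AW p cannot go below ≈ 0.002,
which is visible in the detection-competency table at stringent
thresholds. Raise B_aw when stringent AW selection is needed.

### Two-sided wrap-up

The combination operates on one-sided branches because direction matters.
The two-sided wrap p = min(1, 2·min) is exactly uniform under the null for
K = 1 and conservative in the bulk for K > 1 (mass accumulates at 1), but
its tails — the only region used for selection — are calibrated: the
fraction of null genes below α matches α within Monte-Carlo error at
α ≤ 0.05 (asserted in the test suite). The one-sided branches themselves
are exactly uniform under the null and are exposed as `p_right_comb` /
`p_left_comb`.

## Synthetic cohorts

`gbmeta.simulate` generates, per study, baseline + class effect + noise on
the log2 scale:

* **gene baselines** ~ N(7, 1.5²), shared across cohorts of the same run
  (baseline expression is a property of the gene); a per-study gene-wise
  shift ~ N(0, 0.3²) emulates platform/batch effects;
* **planted genes**: `gbm_up`/`gbm_down` shift only GBM samples,
  `pan_glioma` genes shift GBM, A and OD equally — the confound the
  specificity filter must remove. Per-study realized effects are drawn
  ~ N(±δ, τ²) (defaults δ = 1.5, τ = 0.2 log2 units, i.e. a strong marker
  with moderate between-study heterogeneity at residual SD σ = 1.0);
* planted genes are resampled into the top 60% of the baseline
  distribution: biomarkers are expressed transcripts, and a transcript
  below the detection floor is undiscoverable by construction — the
  low-signal filter exists precisely to remove such probes;
* optional per-study gene dropout emulates platform coverage differences
  and exercises the gene-intersection rule; optional Student-t noise
  (5 df) provides a heavier-tailed variant, default off;
* **survival**: event times exponential with hazard
  h₀·exp(β·(x − x̄)) given an expression score x, independent exponential
  censoring. Defaults h₀ = 0.02/month, β = 0.5 per log2 unit,
  censor rate 0.01/month for a 400-patient cohort.

What the generator does *not* emulate: probe-level effects, intensity-
dependent variance, correlated gene modules, non-exponential hazards,
class imbalance between studies of a cohort. Passing end-to-end tests
therefore demonstrates that the cascade's bookkeeping and statistics are
correct under the stated model, not that any particular real-data gene
list would be reproduced.

## The QC filter

The low-signal filter removes the bottom 10% of genes by mean and then the
bottom 10% of survivors by SD (sequential, matching the mean-then-SD
convention; quantiles with linear interpolation; ties at the cut survive,
so the filter never exceeds its nominal fraction). Two forms exist:

* `filter_low_signal` — per study, the literal contract, including its
  error when everything would be removed;
* `filter_low_signal_consensus` — the cohort-level form used by the
  pipeline: genes are ranked within each study and the bottom fractions by
  *average rank across studies* are removed. This is the convention of
  multi-study DE packages; filtering each study independently lets
  borderline genes flicker in and out of the bottom decile study by study,
  and the cross-study gene intersection then compounds rare removals into
  a substantial loss of genuinely expressed genes.

Note the per-study filter is *not* idempotent: re-applying it removes
another bottom decile of the surviving genes, by construction of the
sequential-quantile contract.

## Default parameters of the demo screen

| parameter | default | why |
|---|---|---|
| studies (train / val / A / OD) | 6 / 4 / 4 / 4 | larger cohort trains, smaller validates |
| genes | 2000 | desk-scale; large enough for stable FDR |
| samples/class/study | 15 | typical single-study glioma cohort size |
| δ, τ, σ | 1.5, 0.2, 1.0 log2 | strong marker, moderate heterogeneity |
| planted GBM-specific / pan-glioma | 80 / 60 | enough to score recovery rates |
| B (permutations) | 200 | p resolution 1/(1+200·G) ≈ 3·10⁻⁶ |
| B_aw | 1000 | AW calibration; floor ≈ 10⁻³ |
| roP order r | ⌈K/2⌉ | majority-of-studies evidence |
| stringent FDR (GBM-vs-NG) | 0.01 | see below |
| subtype FDR | 0.05 | conventional level |

**On the stringent threshold.** Published screens at full scale (9+ cohorts,
hundreds of samples each) can apply extreme thresholds such as 10⁻¹⁹. At
this package's demo scale the pooled z of a true δ = 1.5σ marker in the
4-study validation arm is ≈ 6.5 with spread ≈ 1.3, so its 5th percentile
sits near z ≈ 3.8; a threshold implying z > 4 discards >10% of genuine
markers while a threshold of 0.01 retains them. The dual-method,
train/validate and two-subtype intersections — four approximately
independent filters — carry the specificity burden: the expected number of
null genes surviving all of them at 0.01/0.05 is ≪ 1. The 0.01 vs 0.05 gap
preserves the stringent-versus-conventional distinction of the original
design at a scale where it is meaningful.

## Numerical conventions and degenerate inputs

* s₀ = "auto" is the median across genes of s_p·√(1/n₁+1/n₀), computed on
  the observed data and held fixed across permutations.
* Genes with zero pooled variance: moderated t stays finite via s₀;
  Hedges' g is undefined and the gene is dropped from that study's result
  (and, via the intersection universe, from the comparison).
* Median dichotomization sends values ≤ median to "low"; all-identical
  expression raises (one empty group).
* roP with r = K is exactly maxP (Beta(K,1) CDF = m^K); asserted in tests.
* BH is computed within each comparison's gene universe, never across
  comparisons.
* IRS extent bins: percentages are rounded to whole percent; exactly 5%
  falls to the higher bin (score 1). Products 11 cannot occur (no factor
  pair in range); the printed bin edges are applied as stated.
* All randomness flows from one seed through named substreams
  (`numpy.random.SeedSequence`); identical config + seed ⇒ byte-identical
  `report.json`.

## Known limitations

* Between-gene correlation is not modeled, so genome-wide FDR behaves
  ideally here; on real arrays, correlated modules make BH more variable.
* The permutation null is pooled across genes; with strong planted signal
  the null is slightly contaminated by permuted planted genes
  (conservative, negligible at the default planting fraction of 7%).
* The Fisher "permutation" reference is an empirical null of uniform
  draws, useful for checking the analytic χ² reference at the demo scale,
  not a replacement for study-level permutation at extreme tails.
* Survival uses the two-group log-rank only; no Cox modeling, stratified
  or trend variants.
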