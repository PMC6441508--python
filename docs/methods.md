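# Methods

This note documents the models, default parameters and numerical
choices behind `msisig`, and what the synthetic-cohort experiments do
and do not demonstrate.

## Problem setting

The pipeline performs binary MSI-vs-MSS classification from bulk gene
expression, where cohorts may be measured on different platforms
(RNA-seq counts or microarray log2 intensities). MSI grades are pooled
before any analysis: MSI-H → MSI, MSI-L and MSS → MSS, reflecting the
shared clinicopathology of MSI-L and stable tumours. Gene identity is
kept as Entrez IDs stored as strings; symbols are metadata only.

## Preprocessing

**Low-count filter.** Genes with CPM ≥ `min_cpm` (default 1) in at
least `min_samples` (default 10) libraries are kept; thresholds are
exposed because published analyses rarely state them.

**TMM.** Between-sample scaling follows the trimmed-mean-of-M-values
algorithm: the reference library is the one whose 75th count percentile
(scaled by library size) is closest to the mean; for every other
library, per-gene log2 ratios M and average log2 abundances A are
computed over genes positive in both; the M values are trimmed at 30%
and the A values at 5% (the method's published defaults); the scaling
factor is 2 to the precision-weighted mean of the surviving M values
(weights = inverse asymptotic binomial variance), and factors are
rescaled to geometric mean 1. The implementation reproduces the
reference Bioconductor implementation to ~1e-13 on frozen fixtures.

**log-CPM.** log2((count + p̃) / (L̃ + 2·p̃) · 10⁶), where L̃ is the
TMM-effective library size and p̃ is the pseudo-count (default 0.5)
scaled proportionally to effective library size. The transform is
finite at zero and strictly monotone in the count.

**Quantile normalization** (microarray harmonization): every column is
mapped onto the across-sample mean of order statistics; ties receive
the mean of their target quantiles (average-rank convention). Exact
multiset equality of columns therefore holds only for tie-free input —
with ties, tied entries share an averaged target value.

**Probe collapsing.** When probe-level arrays are supplied with a
probe→gene map, the probe with the highest mean expression represents
the gene — a deterministic rule chosen for reproducibility.

## Differential expression

Each gene follows a negative-binomial log-linear model at a single
common dispersion φ: log μ = offset + β₀ + β₁·MSI (+ batch indicators),
offset = ln(library size × TMM factor). φ is estimated by pooled
method-of-moments: counts are rescaled to a common effective library
size, and within-class (variance − mean) is regressed on mean² through
the origin, floored at 0. Models are fit by iteratively reweighted
least squares, vectorized across genes (batched 2–4-parameter weighted
normal equations), to a 1e-10 step tolerance with at most 100
iterations; non-converged genes get p = NaN and are excluded from the
multiple-testing denominator. Significance of the class effect comes
from the likelihood-ratio χ²₁ test; log2 FC = β₁/ln 2; BH adjustment is
applied across genes. DEGs require |log2 FC| > 1 **and** adjusted
p < 0.05, both strict.

This is deliberately simpler than full empirical-Bayes count
frameworks: one pooled dispersion, no tagwise shrinkage, no
quasi-likelihood. In the strong-signal regimes the pipeline targets
(|log2 FC| ≥ 2 at 35-vs-140 samples) the power loss is negligible, and
the per-gene test is pluggable where finer control is needed. At φ = 0
the test reduces to Poisson regression and matches an independent GLM
implementation to 1e-6.

## Signature construction

The core MSI list combines published signatures restricted to the
cross-platform gene universe; the combination rule is a support
threshold with default `min_support = 1` (union) — the weakest
assumption, since published work rarely states how source lists were
merged. The candidate signature is core ∩ DEGs (DEG order preserved).

Redundancy pruning: a gene pair is redundant when |Pearson r| > 0.75
(log-scale expression) in **any** training cohort. Pairs are processed
in descending order of their maximum |r| across cohorts, ties broken by
the gene-ID pair, and for each pair still fully present a seeded coin
decides which member is dropped. The deterministic ordering plus the
seeded coin make the greedy procedure exactly reproducible, and every
decision is logged (gene pair, r, kept, dropped). After the sweep, no
surviving pair exceeds the threshold in any supplied cohort — verified
exhaustively in tests.

## Classifier

Per-class centroids are arithmetic means over training samples of the
signature-gene expression vectors. The score is the difference of
cosine distances, oriented so MSI scores high; it lies in [−2, 2] and
is invariant to positive rescaling of the sample vector.

Raw log units of two platforms are not comparable, so per-gene
z-scoring precedes the cosine computation by default. Where the
statistics come from is explicit at scoring time: `"cohort"`
(recomputed from the scored matrix — the default for cross-platform
transfer, and the mechanism that removes platform-specific location and
scale), or `"training"` (the statistics stored in the fitted model —
used within-cohort and in cross-validation, where test-fold information
must not leak). The decision threshold maximizes Youden's J over
midpoints of consecutive sorted unique training scores, ties broken
toward the larger threshold (higher specificity); classification uses
strict exceedance. When signature genes are missing from a target
matrix (older array designs), an explicit flag reduces the model to the
available gene subset; the reduction is logged.

## Evaluation

AUC is the Mann–Whitney statistic (ties ½). DeLong variance comes from
placement values: V10ᵢ (fraction of negatives each positive outscores)
and V01ⱼ (fraction of positives each negative is below);
var = S10/m + S01/n with unbiased sample (co)variances. Confidence
intervals use the normal approximation, clipped to [0, 1]; perfect
separation yields zero variance and is flagged degenerate rather than
silently reported. The paired test uses the placement-value covariance
of two score vectors on the same samples, z = ΔAUC/√(var_a + var_b −
2 cov); identical score vectors return z = 0, p = 1 exactly, and total
separation of a reversed pair makes the paired variance 0 (z = ±∞).
Both CI and paired test reproduce the reference ROC implementation
exactly on frozen fixtures, CI coverage is 92–97% in the Gaussian score
model, and the paired test holds its 5% size on null replicates.

Cross-validation is stratified 10-fold on the binary label; centroids,
standardization statistics and thresholds are fit per training fold and
held-out scores are pooled into a single ROC — one AUC and one CI, the
form in which cross-validated performance is conventionally reported
for this classifier. Signature comparisons share one fold plan, use
paired DeLong tests against the first (reference) signature and BH
across comparisons; signatures with no usable genes become failed rows,
not fatal errors.

## Enrichment

One-sided hypergeometric over-representation: p = P(X ≥ k) for a set
with K of N universe genes catching k of the n signature genes, BH
across sets. The universe defaults to the genes of the analyzed
(post-filter) expression matrix and is configurable, since published
enrichment universes are rarely stated. Signature genes outside the
universe are dropped with a warning; only over-representation is
tested.

## Synthetic cohort generator

The generator exists so every stage — including cross-platform
transfer — can be exercised without external data. Per gene, a latent
baseline log2 abundance comes from a two-component mixture (25% low
expressors at N(−3, 1), 75% expressed at N(6, 1.5)), so the low-count
filter removes a predictable stratum. Defaults mirror the development
regime the pipeline targets: 140 MSS + 35 MSI samples per platform
(20% MSI prevalence), 2 000 genes, 50 signal genes shifted by
±2 log2 units in the MSI class (sign randomized per gene), NB
dispersion 0.1, five 5-gene correlated blocks at latent ρ = 0.9, two
batches with per-batch-per-gene N(0, 0.3²) offsets, 90% of genes shared
between platforms, and library sizes log-uniform on [5×10⁵, 2×10⁶].
RNA-seq counts are NB around library-scaled relative abundances;
microarray values are the latent log2 abundances plus N(0, 0.3²) noise,
on the shared-gene subset. The two cohorts contain distinct simulated
patients drawn from the same law.

Two internal scales deserve explanation:

- **Per-gene biological SD = 0.8 (log2).** Planted signal genes are
  correlated with each other *through the phenotype*: two genes shifted
  by ±2 across a 20% minority class share covariance Δ²·p(1−p) ≈ 0.64.
  Unstructured per-gene variation must be large enough that this
  induced correlation stays clearly below the 0.75 pruning threshold,
  otherwise redundancy pruning removes genuinely informative genes and
  recovery metrics become ambiguous — signal and block genes are kept
  disjoint for the same reason. An SD of 0.8 (≈1.7-fold typical
  inter-tumour swing, realistic for cancer cohorts) puts the induced
  correlation near 0.4.
- **Block module SD = 2.0 (log2).** Block genes load on a shared
  Gaussian factor with loading √ρ of the module SD, so the *latent*
  within-block correlation equals ρ exactly; measurement noise (NB or
  array) attenuates the empirical correlation. At module SD 2.0 the
  attenuated value for ρ = 0.9 sits near 0.85, which still exercises
  the pruning stage as intended.

Signal and block genes are drawn from the expressed stratum so planted
effects are measurable after filtering. Everything is deterministic
under the spec's seed.

**What passing tests show — and do not.** The synthetic regime is a
strong-signal sanity check: with 50 genes at |log2 FC| = 2 the classes
are essentially separable, so AUCs of ~1.0 confirm correctness of the
machinery, not clinical performance. Real MSI cohorts have weaker and
heterogeneous effects, probe-level artefacts, annotation errors and
platform idiosyncrasies (probe affinity, saturation) that the generator
does not model; performance on real data must be established on real
data. The generator also simulates expression matrices only — no reads,
no probes.

## Problem sizes used in validation

Monte-Carlo checks default to sizes that keep the full suite fast while
leaving comfortable statistical margins: 1 000 simulated datasets
(30+30 samples) for CI coverage, 2 000 null replicates for the paired
test's size, 20 null simulations for the FDR check, 10 end-to-end
builds for recovery, and 5 seeds for cross-platform transfer.

## Known limitations

- The NB test does not replicate any specific count-model package
  numerically; it implements the defined computation (NB GLM + LRT +
  BH + thresholds) with one common dispersion.
- Microarray processing starts from normalized log2 intensities;
  CEL-file handling (RMA, NUSE-based QC) is out of scope.
- The hypergeometric test treats genes as exchangeable; no length or
  expression-level bias correction.
- The threshold criterion (Youden's J) and the score's sign convention
  are package conventions; alternatives can be layered on the exposed
  scores.
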