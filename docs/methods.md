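# Methods

## The classification model

Intrinsic subtyping by single-sample prediction is a nearest-centroid rule:
each tumor's expression over the classifier genes (50 in the standard
configuration) is correlated with a fixed per-subtype prototype vector, and
the sample takes the subtype of the best-correlated centroid. We use
Spearman's rank correlation (Pearson on average-tie ranks), which makes
calls invariant to any strictly increasing per-sample transform of
expression — the property that allows a rank-based rule to travel across
assay chemistries at all. A sample is left **unclassified** when its maximum
correlation over the active centroids is strictly below 0.1; a correlation
that is undefined because a rank vector is constant is treated as −∞ and can
never win the argmax. Exact correlation ties are broken in the canonical
subtype order (Basal-like, HER2-enriched, LuminalA, LuminalB, Normal-like) so
results are deterministic; ties are measure-zero on real data.

Two modes are exposed: SSP5 (all five centroids) and SSP2 (the
Normal-like centroid removed). The Normal-like subtype largely reflects
normal-tissue contamination, so tumor cohorts are conventionally called with
SSP2 while matched normal tissues are assessed with SSP5.

Key classifier parameters: `unclassified_threshold` (default 0.1, strict
comparison), `min_genes` (default 40 of 50 — the minimum sample/centroid
gene overlap before a sample is refused; the threshold is our choice, the
sources of centroid tables being silent on tolerated dropout), and `mode`.

## Preprocessing

Digital-count route (nCounter-style): per sample, subtract the mean of the
negative-control counts from every gene row (an optional mean + 2 SD
estimator is exposed; mean is the default), clamp at `count_floor`
(default 1.0), divide all counts by the geometric mean of six housekeeper
genes (ACTB, G6PD, RPLP0, TBP, TFRC, UBB), and take log2. Division happens
on the count scale, then logs are taken; the ratio form makes the output
exactly invariant to per-sample global scaling. Housekeeper rows are kept in
the output (they become near-constant) so gene matching downstream is
unaffected; they are never classifier genes.

Microarray route: matrices arrive probe-indexed and already summarized to
log2. Where several probes map to one gene we keep the probe with the
largest interquartile range across samples (Q3 − Q1, linear-interpolation
quantiles; ties keep the earlier row). IQR is the standard robust
variability filter for this step.

Both routes end with per-gene centering (mean by default, median available)
computed **within each platform**, because the centroid values are relative
expressions; this makes the method sensitive to cohort subtype composition,
a known property of centroid classifiers.

## Centroid completion

Published centroid tables occasionally have missing cells. We complete them
with gene-wise K-nearest-neighbor imputation (default k = 10): for a missing
cell, candidate donor genes observed at that column are ranked by Euclidean
distance over co-observed columns, scaled by the number of shared columns so
rows with different missingness are comparable, and the k nearest donate an
inverse-distance-weighted mean. Distance ties break by row order; a
zero-distance donor set (exact duplicate rows) is averaged with equal
weights; fewer than k eligible donors are all used, with a warning. Imputed
values are convex combinations of donor values, and imputation is
permutation-equivariant and the identity on complete matrices — all three
properties are asserted in the test suite.

## DWD batch adjustment

Systematic between-dataset bias is removed with distance-weighted
discrimination. With y = +1 for the reference batch and −1 for the new one,
DWD solves

minimize Σᵢ 1/rᵢ + C Σᵢ ξᵢ  subject to  rᵢ = yᵢ(w·xᵢ + b) + ξᵢ > 0, ξᵢ ≥ 0, ‖w‖ ≤ 1.

Every sample's distance to the hyperplane contributes (unlike the SVM hinge),
which makes w a stable estimate of the systematic batch offset even when the
batches overlap. We solve the slack-eliminated reduced problem: the inner
minimum over ξ gives the convex C¹ loss φ(m) = 1/m for m ≥ 1/√C and
2√C − Cm otherwise, and the resulting smooth program over the unit ball is
solved with SLSQP from the mean-difference initialization to a 1e-12
function tolerance. The test suite checks the reduced solution against an
independent multistart solve of the full slack formulation (agreement to
1e-5 relative on small instances).

Numerical choices:

* **Standardization.** Genes are scaled to unit pooled SD before the fit
  ("standardized DWD"); zero-variance genes are excluded and get zero
  weight. The fitted direction is mapped back to the original gene space as
  a **displacement**: an adjustment along w in standardized coordinates is
  an adjustment along sd ∘ w in raw coordinates (the direction transforms
  with the data, not as a hyperplane normal, because its role here is to
  shift samples). The mapped direction is renormalized to unit length.
* **Penalty.** `C = 100 / median(pairwise inter-batch distance)²` by
  default, the customary heuristic; configurable.
* **Mean adjustment.** "Center at the first mean": each new-batch sample
  becomes x − ((μ_new − μ_ref)·w) w. After the shift the two batch means
  project identically on w (to 1e-8) and components orthogonal to w are
  untouched; the reference batch is returned unchanged. Re-applying the
  same model's adjustment is exactly the identity. A full *re-fit* on
  adjusted data, by contrast, will generally find a small residual
  direction: two finite samples always differ in mean somewhere, and DWD
  will align with whatever sampling separation remains. Exact idempotence
  under re-fitting is therefore not a property of the method and is not
  asserted; idempotence along the fitted direction is.
* **Diagnostics.** Samples can be projected on PC1–3 of the pooled
  gene-centered data plus the DWD direction as a fourth axis, the standard
  before/after visual check for batch adjustment.

## Concordance statistics

Paired calls from two platforms are tallied into a confusion matrix with the
reference platform on the columns. Pairs where either platform left the
sample unclassified are excluded from the matrix body but counted, so
`body + excluded = total pairs` always holds and printed totals can be
checked. Per-class accuracy is the diagonal cell over the reference column
total (classified pairs only); overall agreement is the diagonal sum over
the body; chance-corrected agreement is unweighted Cohen's kappa,
κ = (p_o − p_e)/(1 − p_e) with p_e from the marginals. Subtypes are nominal,
so no weighted variant is offered.

The package ships transcriptions of the four count tables from the study
cohort it was built around (109 microarray tumors × IHC, 24 matched normals,
144 digital-count tumors × IHC, and the 64-sample paired-platform table) as
reviewable TSV fixtures, validated against their printed totals at load.
Running the concordance machinery on the paired-platform fixture reproduces
the published agreement (41 of 63 classified pairs, 65%) and per-class
accuracies (3/7, 13/16, 5/20, 20/20). The standard unweighted kappa on that
body is ≈ 0.506; the source publication prints 0.60 without stating a
variant or software, and we deliberately do not reproduce that figure — the
formula value is the one reported and tested. Similarly, the matched-normal
fraction 16/24 equals 66.7% although it is printed elsewhere as 67.8%; the
counts are treated as authoritative.

IHC crosstabs pair calls with HR/HER2 phenotypes; per-subtype fractions are
computed over non-missing IHC only, with missing statuses carried explicitly
rather than dropped.

## Survival

Overall survival uses all-cause death as the event; a breast-cancer
composite event (recurrence/metastasis/BC death) travels in the clinical
record and is analyzed on request. Kaplan–Meier estimation and the k-group
log-rank test delegate to lifelines; censored subjects at a tied time remain
at risk for events at that time. The test suite checks the product-limit
estimate against an explicit hand-rolled oracle, the chi-square against an
independent O−E/covariance implementation, small-sample p-values against a
10,000-permutation reference, and type-I error calibration (rejection rate
in [0.03, 0.07] at α = 0.05 over 1,000 null replicates, n = 200).

## Synthetic cohorts

The generator emulates the paired-platform study design so every stage has
ground truth. Platform A samples are their subtype centroid plus iid
N(0, noise_sd) per gene (log2 scale); platform B applies a per-gene affine
distortion a_g x + b_g, a_g ~ U(scale_range), b_g ~ N(0, shift_sd), plus
independent noise. Optional pieces: uniform random missingness; probe-level
expansion in which one faithful probe per gene carries the full signal and
the others are attenuated and noisier (so IQR collapse should recover the
gene matrix, and does for ≥ 95% of genes at the default noise);
digital-count emulation with per-sample content factors, constant-signal
housekeeper rows and additive negative-control background (the count
pipeline then recovers the log2 input up to a per-gene constant, removed by
centering); matched normal tissues drawn around the Normal-like centroid;
and exponential survival per subtype with uniform censoring.

Defaults are the study's conditions: tumor mix 23/28/55/37 across
basal-like/HER2-enriched/luminal A/luminal B (the 144-sample cohort's
composition), 24 matched normals, an 11.6-year censoring window, hazards
(0.085/0.065/0.013/0.040 per year) chosen so per-subtype censoring
fractions resemble the reported ones, noise_sd 0.5, and an IHC probability
table mirroring the study's subtype-by-phenotype composition. All
randomness flows through one `numpy.random.default_rng(seed)` stream;
identical seeds give bit-identical cohorts on any platform.

What the generator does **not** emulate: nonlinear cross-platform response,
probe-sequence affinity effects, FFPE degradation, tumor-cellularity
differences between fresh-frozen and archival input, and cohort-composition
effects beyond the configured mix. Passing the synthetic recovery tests
therefore shows the pipeline is correct under additive/affine distortion
with rank-preserved signal; it does not certify concordance on real
cross-platform data, where the study this package models found only
fair-to-substantial agreement.

For the end-to-end batch-adjustment demonstration we use a pure per-gene
mean shift (scale range (1,1), shift SD 5 — large enough to visibly break
rank correlation to the centroids) and classify without re-centering, since
per-gene centering would itself absorb any constant shift and leave the
adjustment nothing to demonstrate. DWD then restores accuracy on the
shifted platform to within 2 percentage points of the bias-free condition
(in practice, exactly to it).

## Problem sizes

Tests and the acceptance script run cohorts of 60–200 samples × 50 genes,
1,000-replicate null calibrations and 10,000-permutation references —
sizes at which every check completes in seconds to a couple of minutes on
one core while keeping Monte-Carlo error well below the asserted margins.

## Known limitations

* Only two-batch DWD is implemented; multi-batch harmonization is out of
  scope.
* No risk-of-recurrence (ROR) or proliferation scoring; subtyping only.
* The published centroid files are not bundled; users supply a centroid TSV
  (synthetic centroids are provided for testing and demonstration).
* Cohort-dependent published figures (the survival curves' p-value, the
  censoring percentages, the normal-tissue fractions from raw arrays)
  require the original cohort's raw data and are not recomputed here; the
  synthetic property suites stand in for them.
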