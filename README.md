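# ssp50

Cross-platform molecular subtyping of breast cancer by nearest-centroid
single-sample prediction (SSP), for researchers who classify tumors with the
PAM50-style intrinsic taxonomy on heterogeneous expression platforms
(digital RNA counting and oligonucleotide microarrays) and need to know how
well the calls agree.

## What it computes

A sample with expression vector *x* over the classifier genes is assigned to
the intrinsic subtype whose centroid it ranks most like:

    label(x) = argmax_k  rho(x, c_k),    rho = Spearman rank correlation

over centroids *c_k* for Basal-like, HER2-enriched, Luminal A, Luminal B and
Normal-like (SSP5), or the first four only (SSP2). If max_k rho < 0.1 the
sample is **unclassified**. Around this core the package provides:

* **Preprocessing** — digital counts: negative-control background
  subtraction, division by the geometric mean of six housekeepers (ACTB,
  G6PD, RPLP0, TBP, TFRC, UBB), log2; microarrays: collapse of multiple
  probes per gene to the most variable probe (largest IQR); per-gene
  mean/median centering within each platform.
* **Centroid completion** — gene-wise K-nearest-neighbor imputation
  (k = 10, inverse-distance weights) for incomplete centroid tables.
* **Batch adjustment** — standardized distance-weighted discrimination
  (DWD): fit the convex DWD program separating two batches, then shift the
  non-reference batch along the fitted direction until both batch means
  project identically ("center at the first mean"), with PC1–3 + DWD-axis
  diagnostics.
* **Concordance** — paired confusion matrix with explicit unclassified
  bookkeeping, per-class accuracy against a reference platform, overall
  agreement, unweighted Cohen's kappa, IHC (HR/HER2) crosstabs, and
  matched normal-tissue summaries.
* **Survival** — Kaplan–Meier curves and the k-group log-rank test
  stratified by subtype (via lifelines).
* **Synthetic cohorts** — seeded paired two-platform cohorts with known
  subtype truth, per-gene affine platform distortion, probe-level
  expansion, digital-count emulation, matched normals and exponential
  survival, so the whole pipeline runs and is tested with no external data.

## Worked example

```python
import ssp50 as s
from ssp50.classifier import ClassifierConfig

centroids = s.make_centroids(n_genes=50, seed=11)
spec = s.SyntheticCohortSpec(platform_shift_sd=5.0,
                             platform_scale_range=(1.0, 1.0), seed=11)
cohort = s.generate_cohort(spec, centroids)

cfg = ClassifierConfig(mode="SSP2")
calls_A = s.classify_cohort(cohort.expr_platform_A, centroids, cfg)
calls_B = s.classify_cohort(cohort.expr_platform_B, centroids, cfg)

truth = cohort.true_labels
acc = lambda calls: sum(c.label == truth[c.sample_id] for c in calls) / len(calls)
print(f"platform A accuracy: {acc(calls_A):.3f}")      # 1.000
print(f"platform B accuracy: {acc(calls_B):.3f}")      # 0.818  (batch bias)

model = s.fit_dwd(cohort.expr_platform_A, cohort.expr_platform_B)
_, B_adj = s.adjust_batches(cohort.expr_platform_A, cohort.expr_platform_B, model)
calls_B2 = s.classify_cohort(B_adj, centroids, cfg)
print(f"after DWD adjustment: {acc(calls_B2):.3f}")    # 1.000

res = s.concordance_report(calls_A, calls_B2)
print(f"cross-platform agreement: {res.agreement[1]:.3f}, kappa: {res.kappa:.3f}")
# cross-platform agreement: 1.000, kappa: 1.000
```

The 143-sample cohort mirrors a realistic subtype mix (23/28/55/37). The
per-gene mean shift between the platforms drops nearest-centroid accuracy
to 0.818; fitting the DWD direction between the two batches and centering
the shifted batch at the reference mean restores it to 1.000, and the two
platforms then agree on every call (kappa 1.0).

A shell workflow over the same machinery:

```sh
ssp50 simulate --seed 3 --out-dir sim/
ssp50 subtype --expr sim/expr_platform_A.tsv --centroids sim/centroids.tsv \
      --mode ssp2 --out calls_A.csv
ssp50 concord --ref calls_A.csv --test calls_B.csv --out report.json
```

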