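"""Synthetic paired two-platform cohorts with known subtype ground truth.

Emulates the study design every pipeline stage needs: tumors drawn around
subtype centroids with per-gene Gaussian noise on the log2 scale, a second
platform related to the first by a per-gene affine distortion (scale and
shift) plus independent noise, optional missing values, probe-level
expansion for the microarray collapse step, matched normal-tissue samples,
digital-count emulation (negative-control and housekeeper rows) for the
count-normalization steps, and subtype-dependent exponential survival with
uniform censoring.

Defaults mirror the study's conditions: the tumor subtype mix of the
144-sample digital-count cohort (23/28/55/37 across basal-like,
HER2-enriched, luminal A, luminal B), 24 matched normals, an 11.6-year
follow-up window, and hazards calibrated so per-subtype censoring fractions
resemble the reported ones. All randomness flows through a single
``numpy.random.default_rng`` seed; identical seeds give bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .centroid_model import CentroidSet
from .core import (
    IHC_MISSING,
    IHC_PHENOTYPES,
    SSP50Error,
    SUBTYPES_5,
    ClinicalRecord,
    ExpressionMatrix,
)
from .preprocess import DEFAULT_HOUSEKEEPERS, ProbeAnnotation

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "make_centroids",
    "generate_cohort",
    "expand_to_probes",
    "generate_normal_pairs",
    "emulate_digital_counts",
]

#: Default subtype -> IHC phenotype probabilities (rows: HR+/HER2+, HR+/HER2-,
#: HR-/HER2+, HR-/HER2-, missing). Loosely mirrors the composition of the
#: study cohort: basal-like mostly HR-, luminal mostly HR+/HER2-.
DEFAULT_IHC_TABLE: dict[str, tuple[float, ...]] = {
    "Basal-like": (0.22, 0.17, 0.22, 0.30, 0.09),
    "HER2-enriched": (0.28, 0.07, 0.50, 0.11, 0.04),
    "LuminalA": (0.13, 0.74, 0.07, 0.00, 0.06),
    "LuminalB": (0.16, 0.81, 0.03, 0.00, 0.00),
    "Normal-like": (0.13, 0.74, 0.07, 0.00, 0.06),
}

#: Exponential event rates (per year) giving censoring fractions resembling
#: the reported per-subtype percentages over an 11.6-year window.
DEFAULT_HAZARDS: dict[str, float] = {
    "Basal-like": 0.085,
    "HER2-enriched": 0.065,
    "LuminalA": 0.013,
    "LuminalB": 0.040,
    "Normal-like": 0.013,
}

#: Tumor counts per subtype in the digital-count study cohort.
DEFAULT_N_PER_SUBTYPE: dict[str, int] = {
    "Basal-like": 23,
    "HER2-enriched": 28,
    "LuminalA": 55,
    "LuminalB": 37,
    "Normal-like": 0,
}


@dataclass
class SyntheticCohortSpec:
    """All generator knobs; identical seed -> bit-identical cohort."""

    n_per_subtype: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_SUBTYPE))
    n_genes: int = 50
    noise_sd: float = 0.5
    platform_shift_sd: float = 0.5
    platform_scale_range: tuple[float, float] = (0.8, 1.2)
    missing_rate: float = 0.0
    probes_per_gene: int = 3
    n_normal_pairs: int = 24
    hazard: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HAZARDS))
    censor_time_max: float = 11.6
    ihc_table: dict[str, tuple[float, ...]] = field(default_factory=lambda: dict(DEFAULT_IHC_TABLE))
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_subtype.values()):
            raise SSP50Error("subtype counts must be >= 0")
        if self.noise_sd < 0 or self.platform_shift_sd < 0:
            raise SSP50Error("noise SDs must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SSP50Error("missing_rate must be in [0, 1)")
        if self.probes_per_gene < 1:
            raise SSP50Error("probes_per_gene must be >= 1")
        if self.censor_time_max <= 0:
            raise SSP50Error("censor_time_max must be positive")
        for s, p in self.ihc_table.items():
            if len(p) != 5 or abs(sum(p) - 1.0) > 1e-8:
                raise SSP50Error(f"IHC probability row for {s!r} must have 5 entries summing to 1")


@dataclass
class SyntheticCohort:
    expr_platform_A: ExpressionMatrix
    expr_platform_B: ExpressionMatrix
    true_labels: pd.Series  # sample -> subtype
    clinical: list[ClinicalRecord]
    centroids_used: CentroidSet
    probe_level_B: tuple[ExpressionMatrix, ProbeAnnotation] | None = None
    normals_A: ExpressionMatrix | None = None
    normal_pairing: dict[str, str] | None = None  # normal ID -> matched tumor ID


def make_centroids(
    n_genes: int = 50,
    n_subtypes: int = 5,
    separation: float = 1.0,
    seed: int = 0,
    max_retries: int = 50,
) -> CentroidSet:
    """Draw well-separated synthetic centroids (pairwise Spearman rho < 0.3).

    Columns are iid Gaussian with SD ``separation``; draws are retried a
    bounded number of times until every distinct-centroid pair correlates
    below 0.3 (always satisfied quickly for n_genes >= ~20).
    """
    if n_genes < 2:
        raise SSP50Error("need at least 2 genes")
    if separation <= 0:
        raise SSP50Error("separation must be positive")
    from .classifier import spearman_rho

    names = list(SUBTYPES_5[:n_subtypes]) + [f"Subtype{i+1}" for i in range(5, n_subtypes)]
    genes = [f"G{i+1:03d}" for i in range(n_genes)]
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        vals = rng.normal(0.0, separation, size=(n_genes, n_subtypes))
        if n_subtypes == 1:
            break
        rhos = [
            spearman_rho(vals[:, i], vals[:, j])
            for i in range(n_subtypes)
            for j in range(i + 1, n_subtypes)
        ]
        if max(rhos) < 0.3:
            break
    else:
        raise SSP50Error(
            f"could not draw centroids with pairwise rho < 0.3 in {max_retries} tries"
        )
    return CentroidSet(pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=names))


def generate_cohort(spec: SyntheticCohortSpec, centroids: CentroidSet) -> SyntheticCohort:
    """Draw a paired two-platform tumor cohort with clinical annotations.

    Platform A samples are their subtype centroid plus N(0, noise_sd) per
    gene; platform B applies a per-gene affine distortion a_g * x + b_g with
    a_g ~ U(platform_scale_range) and b_g ~ N(0, platform_shift_sd), plus
    independent noise. Survival times are exponential per subtype hazard
    with uniform censoring on [0, censor_time_max]; IHC phenotypes follow
    the configured subtype-conditional probability table.
    """
    spec.validate()
    if not centroids.is_complete:
        raise SSP50Error("centroids must be complete (no missing values)")
    unknown = [s for s in spec.n_per_subtype if s not in centroids.subtypes]
    if unknown:
        raise SSP50Error(f"n_per_subtype references unknown subtype(s): {unknown}")
    rng = np.random.default_rng(spec.seed)
    genes = centroids.genes
    n_genes = len(genes)
    if spec.n_genes != n_genes:
        raise SSP50Error(f"spec.n_genes={spec.n_genes} but centroid set has {n_genes} genes")

    labels: list[str] = []
    for s in SUBTYPES_5:
        labels += [s] * spec.n_per_subtype.get(s, 0)
    for s in spec.n_per_subtype:  # any non-canonical subtype names, in insertion order
        if s not in SUBTYPES_5:
            labels += [s] * spec.n_per_subtype[s]
    if not labels:
        raise SSP50Error("empty cohort: all subtype counts are zero")
    sample_ids = [f"S{i+1:04d}" for i in range(len(labels))]

    C = centroids.values
    A = np.column_stack(
        [C[lab].to_numpy() + rng.normal(0.0, spec.noise_sd, n_genes) for lab in labels]
    )
    a_g = rng.uniform(*spec.platform_scale_range, size=n_genes)
    b_g = rng.normal(0.0, spec.platform_shift_sd, size=n_genes)
    B = a_g[:, None] * A + b_g[:, None] + rng.normal(0.0, spec.noise_sd, A.shape)

    if spec.missing_rate > 0:
        A = np.where(rng.random(A.shape) < spec.missing_rate, np.nan, A)
        B = np.where(rng.random(B.shape) < spec.missing_rate, np.nan, B)

    idx = pd.Index(genes, name="gene")
    cols = pd.Index(sample_ids, name="sample")
    expr_A = ExpressionMatrix(pd.DataFrame(A, index=idx, columns=cols), "ncounter", "log2")
    expr_B = ExpressionMatrix(pd.DataFrame(B, index=idx, columns=cols), "microarray", "log2")

    clinical = _draw_clinical(spec, labels, sample_ids, rng)
    return SyntheticCohort(
        expr_platform_A=expr_A,
        expr_platform_B=expr_B,
        true_labels=pd.Series(labels, index=cols, name="subtype"),
        clinical=clinical,
        centroids_used=centroids,
    )


def _draw_clinical(
    spec: SyntheticCohortSpec, labels: list[str], sample_ids: list[str], rng
) -> list[ClinicalRecord]:
    categories = list(IHC_PHENOTYPES) + [IHC_MISSING]
    records = []
    for sid, lab in zip(sample_ids, labels):
        probs = spec.ihc_table.get(lab, spec.ihc_table.get("LuminalA"))
        pheno = categories[rng.choice(5, p=np.asarray(probs, dtype=float))]
        if pheno == IHC_MISSING:
            hr = her2 = IHC_MISSING
        else:
            hr = "positive" if pheno.startswith("HR+") else "negative"
            her2 = "positive" if pheno.endswith("HER2+") else "negative"
        rate = spec.hazard.get(lab, np.mean(list(spec.hazard.values())))
        t_event = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        t_censor = rng.uniform(0.0, spec.censor_time_max)
        event = bool(t_event <= t_censor)
        records.append(
            ClinicalRecord(
                sample_id=sid,
                hr_status=hr,
                her2_status=her2,
                followup_time=float(min(t_event, t_censor)),
                event_death=event,
                event_bc=event and bool(rng.random() < 0.7),
            )
        )
    return records


def expand_to_probes(
    expr_B: ExpressionMatrix,
    probes_per_gene: int = 3,
    extra_noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ProbeAnnotation]:
    """Emit a probe-level matrix: one faithful probe per gene, the rest
    signal-attenuated and noisier, so IQR-based collapse recovers the gene
    matrix. With probes_per_gene = 1 the round trip is exact."""
    if probes_per_gene < 1:
        raise SSP50Error("probes_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    probe_ids = []
    mapping: dict[str, str] = {}
    arr = expr_B.values
    for gene in arr.index:
        x = arr.loc[gene].to_numpy(dtype=float)
        faithful = int(rng.integers(probes_per_gene))
        for j in range(probes_per_gene):
            pid = f"{gene}_p{j+1}"
            if j == faithful:
                rows.append(x)
            else:
                atten = rng.uniform(0.3, 0.7)
                offset = rng.normal(0.0, 1.0)
                rows.append(atten * x + offset + rng.normal(0.0, extra_noise_sd, x.size))
            probe_ids.append(pid)
            mapping[pid] = str(gene)
    probe_df = pd.DataFrame(
        np.vstack(rows), index=pd.Index(probe_ids, name="id"), columns=arr.columns
    )
    return (
        ExpressionMatrix(probe_df, platform=expr_B.platform, scale="log2"),
        ProbeAnnotation(mapping),
    )


def generate_normal_pairs(
    spec: SyntheticCohortSpec, centroids: CentroidSet, cohort: SyntheticCohort
) -> SyntheticCohort:
    """Append matched normal-tissue samples drawn near the Normal-like centroid.

    Each normal sample links to one tumor sample ID (the first
    ``n_normal_pairs`` tumors). The noise model matches the tumor draw.
    """
    if "Normal-like" not in centroids.subtypes:
        raise SSP50Error("Normal-like centroid required to generate normal pairs")
    n = spec.n_normal_pairs
    tumors = cohort.expr_platform_A.samples
    if n > len(tumors):
        raise SSP50Error(f"n_normal_pairs={n} exceeds tumor count {len(tumors)}")
    rng = np.random.default_rng(spec.seed + 1)
    genes = centroids.genes
    base = centroids.values["Normal-like"].to_numpy()
    vals = np.column_stack([base + rng.normal(0.0, spec.noise_sd, len(genes)) for _ in range(n)])
    ids = [f"N{i+1:04d}" for i in range(n)]
    normals = ExpressionMatrix(
        pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=pd.Index(ids, name="sample")),
        platform=cohort.expr_platform_A.platform,
        scale="log2",
    )
    cohort.normals_A = normals
    cohort.normal_pairing = dict(zip(ids, tumors[:n]))
    return cohort


def emulate_digital_counts(
    expr: ExpressionMatrix,
    seed: int = 0,
    n_negative_controls: int = 8,
    background_mean: float = 10.0,
    base_log2: float = 8.0,
    housekeeper_log2: float = 10.0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Turn a log2 matrix into raw digital counts with control rows.

    Gene counts are s_j * 2^(x + base_log2) for a per-sample content factor
    s_j, housekeepers carry a constant true signal scaled by the same s_j,
    and every row gains additive negative-control-level background — so the
    background-subtract / housekeeper-normalize / log2 pipeline recovers the
    input up to a per-gene constant (removed downstream by gene centering).
    Returns the counts matrix and the negative-control row IDs.
    """
    rng = np.random.default_rng(seed)
    arr = expr.values.to_numpy(dtype=float)
    n_genes, n_samples = arr.shape
    s_j = rng.uniform(0.5, 2.0, size=n_samples)
    gene_counts = s_j[None, :] * np.exp2(arr + base_log2)
    hk_counts = np.tile(s_j * np.exp2(housekeeper_log2), (len(DEFAULT_HOUSEKEEPERS), 1))
    neg_ids = [f"NEG_{i+1}" for i in range(n_negative_controls)]
    neg_counts = np.abs(rng.normal(background_mean, 2.0, size=(n_negative_controls, n_samples)))
    background = neg_counts.mean(axis=0)
    stacked = np.vstack([neg_counts, hk_counts + background, gene_counts + background])
    index = pd.Index(
        neg_ids + list(DEFAULT_HOUSEKEEPERS) + list(expr.values.index), name="id"
    )
    counts = pd.DataFrame(stacked, index=index, columns=expr.values.columns)
    return ExpressionMatrix(counts, platform="ncounter", scale="counts"), neg_ids
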