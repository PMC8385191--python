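"""Platform-specific preprocessing into comparable log2 gene-by-sample matrices.

Digital-count (nCounter-style) route: background subtraction using negative
controls, division by the per-sample geometric mean of housekeeper genes,
log2 transform. Microarray route: collapse of multiple probes per gene to the
single most variable probe (largest interquartile range). Both routes end in
per-gene centering so relative expression is comparable to centroid values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, SSP50Error

__all__ = [
    "NormalizationConfig",
    "ProbeAnnotation",
    "background_subtract",
    "housekeeping_normalize",
    "collapse_probes",
    "center_genes",
]

logger = logging.getLogger(__name__)

#: The six housekeeper controls used for digital-count content normalization.
DEFAULT_HOUSEKEEPERS: tuple[str, ...] = ("ACTB", "G6PD", "RPLP0", "TBP", "TFRC", "UBB")


@dataclass
class NormalizationConfig:
    housekeepers: tuple[str, ...] = DEFAULT_HOUSEKEEPERS
    count_floor: float = 1.0
    #: background estimator: "mean" of negative controls, or "mean_2sd"
    background: str = "mean"

    def __post_init__(self) -> None:
        if not self.housekeepers:
            raise SSP50Error("housekeeper list must be non-empty")
        if self.count_floor <= 0:
            raise SSP50Error("count_floor must be positive")
        if self.background not in ("mean", "mean_2sd"):
            raise SSP50Error(f"unknown background estimator {self.background!r}")


@dataclass
class ProbeAnnotation:
    """Many-to-one probe -> gene symbol map."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise SSP50Error("probe annotation is empty")
        self.mapping = {p: g.upper() for p, g in self.mapping.items()}

    @classmethod
    def from_tsv(cls, path) -> "ProbeAnnotation":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"probe_id", "gene"}.issubset(df.columns):
            raise SSP50Error(f"{path}: annotation needs columns 'probe_id' and 'gene'")
        return cls(dict(zip(df["probe_id"], df["gene"])))


def background_subtract(
    counts: ExpressionMatrix,
    negative_control_rows: list[str],
    cfg: NormalizationConfig | None = None,
) -> ExpressionMatrix:
    """Subtract each sample's negative-control background from every gene row.

    The background is the per-sample mean of the negative-control counts
    (optionally mean + 2 SD); results clamp at ``cfg.count_floor`` and the
    control rows are dropped from the output.
    """
    cfg = cfg or NormalizationConfig()
    if counts.scale != "counts":
        raise SSP50Error("background_subtract expects a counts-scale matrix")
    missing = [r for r in negative_control_rows if r not in counts.values.index]
    if missing:
        raise SSP50Error(f"negative-control row(s) absent from matrix: {missing}")
    neg = counts.values.loc[negative_control_rows]
    background = neg.mean(axis=0)
    if cfg.background == "mean_2sd":
        background = background + 2.0 * neg.std(axis=0, ddof=1)
    body = counts.values.drop(index=negative_control_rows)
    if body.empty:
        raise SSP50Error("no gene rows remain after dropping negative controls")
    adjusted = (body - background).clip(lower=cfg.count_floor)
    return ExpressionMatrix(adjusted, platform=counts.platform, scale="counts")


def housekeeping_normalize(
    counts: ExpressionMatrix, cfg: NormalizationConfig | None = None
) -> ExpressionMatrix:
    """Divide each sample by its housekeeper geometric mean, then log2.

    Content normalization: the output is invariant to any per-sample global
    scaling of the raw counts. Housekeeper rows are retained (they become
    near-constant rows) so downstream gene matching is unaffected; they are
    never part of the classifier gene set.
    """
    cfg = cfg or NormalizationConfig()
    if counts.scale != "counts":
        raise SSP50Error("housekeeping_normalize expects a counts-scale matrix")
    missing = [h for h in cfg.housekeepers if h not in counts.values.index]
    if missing:
        raise SSP50Error(f"housekeeper row(s) absent from matrix: {missing}")
    hk = counts.values.loc[list(cfg.housekeepers)]
    if (hk <= 0).any().any():
        raise SSP50Error("housekeeper with non-positive count; run background_subtract first")
    geo_mean = np.exp(np.log(hk).mean(axis=0))
    normalized = np.log2(counts.values / geo_mean)
    return ExpressionMatrix(normalized, platform=counts.platform, scale="log2")


def collapse_probes(expr: ExpressionMatrix, ann: ProbeAnnotation) -> ExpressionMatrix:
    """Keep one probe per gene: the one with the largest IQR across samples.

    The printed variability criterion is read as the interquartile range
    (Q3 - Q1, linear-interpolation quantiles). Ties break by probe row order.
    Unmapped probes are dropped with a logged count.
    """
    if expr.scale != "log2":
        raise SSP50Error("collapse_probes expects a log2-scale matrix")
    mapped = [p for p in expr.values.index if p in ann.mapping]
    n_unmapped = expr.shape[0] - len(mapped)
    if not mapped:
        raise SSP50Error("no probe in the matrix maps to a gene")
    if n_unmapped:
        logger.info("collapse_probes: dropped %d unmapped probe(s)", n_unmapped)
    arr = expr.values.loc[mapped]
    q1 = arr.quantile(0.25, axis=1, interpolation="linear")
    q3 = arr.quantile(0.75, axis=1, interpolation="linear")
    iqr = q3 - q1
    best_rows: dict[str, str] = {}
    best_iqr: dict[str, float] = {}
    gene_order: list[str] = []
    for probe in mapped:
        gene = ann.mapping[probe]
        if gene not in best_rows:
            gene_order.append(gene)
            best_rows[gene] = probe
            best_iqr[gene] = iqr[probe]
        elif iqr[probe] > best_iqr[gene]:  # strict: ties keep the earlier probe
            best_rows[gene] = probe
            best_iqr[gene] = iqr[probe]
    out = arr.loc[[best_rows[g] for g in gene_order]]
    out.index = pd.Index(gene_order, name="gene")
    return ExpressionMatrix(out, platform=expr.platform, scale="log2")


def center_genes(expr: ExpressionMatrix, method: str = "mean") -> ExpressionMatrix:
    """Subtract each gene row's within-matrix mean (or median)."""
    if expr.scale != "log2":
        raise SSP50Error("center_genes expects a log2-scale matrix")
    if method == "mean":
        center = expr.values.mean(axis=1)
    elif method == "median":
        center = expr.values.median(axis=1)
    else:
        raise SSP50Error(f"unknown centering method {method!r}")
    return ExpressionMatrix(expr.values.sub(center, axis=0), platform=expr.platform, scale="log2")
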