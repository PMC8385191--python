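"""Spearman nearest-centroid single-sample prediction (SSP).

Each sample is assigned to the subtype whose centroid it correlates with most
strongly (Spearman's rank correlation over the genes shared between sample
and centroid table). Two modes: SSP5 uses all five intrinsic-subtype
centroids; SSP2 drops the Normal-like centroid. A sample whose maximum
correlation is below the unclassified threshold (default 0.1, strict) gets
no label.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .centroid_model import CentroidSet
from .core import SSP50Error, SUBTYPES_4, SUBTYPES_5, UNCLASSIFIED, ExpressionMatrix, SubtypeCall

__all__ = ["ClassifierConfig", "spearman_rho", "classify_sample", "classify_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class ClassifierConfig:
    unclassified_threshold: float = 0.1
    min_genes: int = 40
    mode: str = "SSP5"  # "SSP5" | "SSP2"

    def __post_init__(self) -> None:
        if not 0.0 < self.unclassified_threshold < 1.0:
            raise SSP50Error("unclassified_threshold must be in (0, 1)")
        if self.min_genes < 2:
            raise SSP50Error("min_genes must be >= 2")
        if self.mode not in ("SSP5", "SSP2"):
            raise SSP50Error(f"unknown mode {self.mode!r}")

    @property
    def subtypes(self) -> tuple[str, ...]:
        return SUBTYPES_5 if self.mode == "SSP5" else SUBTYPES_4


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman's rank correlation: Pearson correlation of average-tie ranks.

    Returns NaN when either vector has zero rank variance (constant input);
    callers treat NaN as -inf for argmax purposes so an undefined correlation
    can never win.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise SSP50Error("spearman_rho needs two equal-length vectors of size >= 2")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    rho = np.corrcoef(rx, ry)[0, 1]
    return float(rho)


def classify_sample(
    expr: dict[str, float] | pd.Series,
    centroids: CentroidSet,
    cfg: ClassifierConfig | None = None,
) -> SubtypeCall:
    """Call one sample against each centroid of the configured mode.

    Correlations are computed over the genes present in both the sample and
    the centroid table (identical gene order); fewer than ``cfg.min_genes``
    overlapping genes is a hard error. Exact correlation ties break by
    canonical subtype order with a logged warning.
    """
    cfg = cfg or ClassifierConfig()
    if isinstance(expr, dict):
        expr = pd.Series(expr)
    sample_id = expr.name if expr.name is not None else "<sample>"
    if not centroids.is_complete:
        raise SSP50Error("centroid set has missing values; impute first")
    active = [s for s in cfg.subtypes if s in centroids.subtypes]
    if len(active) != len(cfg.subtypes):
        missing = set(cfg.subtypes) - set(active)
        raise SSP50Error(f"centroid set lacks subtype(s) {sorted(missing)} for mode {cfg.mode}")

    expr = expr.dropna()
    genes = [g for g in centroids.genes if g in expr.index]
    if len(genes) < cfg.min_genes:
        absent = [g for g in centroids.genes if g not in expr.index]
        raise SSP50Error(
            f"sample {sample_id!r}: only {len(genes)} genes overlap the centroids "
            f"(min {cfg.min_genes}); missing: {absent}"
        )
    x = expr.loc[genes].to_numpy(dtype=float)
    cors: dict[str, float] = {}
    for s in active:
        cors[s] = spearman_rho(x, centroids.values.loc[genes, s].to_numpy(dtype=float))

    # NaN (undefined) correlations never win the argmax
    keyed = [(s, cors[s]) for s in active if not math.isnan(cors[s])]
    if not keyed:
        best, best_rho = None, float("-inf")
    else:
        best_rho = max(r for _, r in keyed)
        winners = [s for s, r in keyed if r == best_rho]
        if len(winners) > 1:
            logger.warning(
                "sample %s: correlation tie among %s; canonical order breaks it", sample_id, winners
            )
        best = winners[0]

    if best is None or best_rho < cfg.unclassified_threshold:
        label = UNCLASSIFIED
    else:
        label = best
    return SubtypeCall(
        sample_id=str(sample_id),
        correlations=cors,
        label=label,
        mode=cfg.mode,
        n_genes_used=len(genes),
    )


def classify_cohort(
    expr: ExpressionMatrix,
    centroids: CentroidSet,
    cfg: ClassifierConfig | None = None,
) -> list[SubtypeCall]:
    """Call every sample of a gene-centered matrix; order preserved.

    A per-sample failure (e.g. insufficient gene overlap) skips that sample
    with a logged error rather than aborting the cohort.
    """
    cfg = cfg or ClassifierConfig()
    row_means = expr.values.mean(axis=1).abs()
    if (row_means > 0.05).any():
        logger.warning(
            "classify_cohort: %d gene row(s) have |mean| > 0.05 — matrix may not be gene-centered",
            int((row_means > 0.05).sum()),
        )
    calls: list[SubtypeCall] = []
    for sample in expr.samples:
        col = expr.values[sample]
        col.name = sample
        try:
            calls.append(classify_sample(col, centroids, cfg))
        except SSP50Error as exc:
            logger.error("sample %s skipped: %s", sample, exc)
    counts = Counter(c.label for c in calls)
    logger.info("classify_cohort: %s", dict(counts))
    return calls


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    """Tabulate calls: sample_id, label, rho_<subtype>..., n_genes_used, mode."""
    if not calls:
        return pd.DataFrame(columns=["sample_id", "label", "n_genes_used", "mode"])
    subtypes = list(calls[0].correlations)
    rows = []
    for c in calls:
        row = {"sample_id": c.sample_id, "label": c.label}
        for s in subtypes:
            row[f"rho_{s}"] = c.correlations.get(s, float("nan"))
        row["n_genes_used"] = c.n_genes_used
        row["mode"] = c.mode
        rows.append(row)
    return pd.DataFrame(rows)


def calls_from_frame(df: pd.DataFrame) -> list[SubtypeCall]:
    """Inverse of :func:`calls_to_frame`."""
    rho_cols = [c for c in df.columns if c.startswith("rho_")]
    calls = []
    for _, row in df.iterrows():
        calls.append(
            SubtypeCall(
                sample_id=str(row["sample_id"]),
                correlations={c[4:]: float(row[c]) for c in rho_cols},
                label=str(row["label"]),
                mode=str(row.get("mode", "SSP5")),
                n_genes_used=int(row.get("n_genes_used", 0)),
            )
        )
    return calls
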