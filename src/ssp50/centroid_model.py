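"""Subtype centroid table: loading, validation, and KNN completion.

The classifier is defined by a gene-by-subtype prototype matrix (50 genes x 5
intrinsic subtypes in the standard configuration). Published centroid tables
carry occasional missing entries; these are completed with gene-wise
K-nearest-neighbor imputation (k = 10 by default), the de-facto standard for
expression matrices: for a missing cell the k most similar gene rows —
Euclidean distance over co-observed columns, scaled by the number of shared
columns — vote with inverse-distance weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SSP50Error, SUBTYPES_5

__all__ = ["CentroidSet", "ImputationConfig", "load_centroids", "impute_missing_knn"]


@dataclass
class ImputationConfig:
    """Gene-wise KNN imputation settings."""

    k: int = 10

    def validate(self, n_genes: int) -> None:
        if self.k < 1:
            raise SSP50Error(f"k must be >= 1, got {self.k}")
        if self.k >= n_genes:
            raise SSP50Error(f"k={self.k} must be < number of genes ({n_genes})")


@dataclass
class CentroidSet:
    """Gene-by-subtype centroid matrix (log2 scale, possibly incomplete).

    Gene symbols are uppercase and unique; subtype labels unique. The
    four-subtype reduction is always the five-subtype set minus Normal-like.
    """

    values: pd.DataFrame  # genes x subtypes; NaN = missing

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise SSP50Error(f"duplicate gene symbol(s): {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise SSP50Error(f"duplicate subtype label(s): {dup}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def subtypes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def impute(self, cfg: ImputationConfig | None = None) -> "CentroidSet":
        """Return a complete CentroidSet with missing entries KNN-imputed."""
        cfg = cfg or ImputationConfig()
        return CentroidSet(impute_missing_knn(self.values, cfg))

    def subset(self, subtypes: list[str]) -> "CentroidSet":
        missing = [s for s in subtypes if s not in self.values.columns]
        if missing:
            raise SSP50Error(f"subtype(s) not in centroid set: {missing}")
        return CentroidSet(self.values[list(subtypes)])


def load_centroids(path, expected_subtypes: list[str] | None = None) -> CentroidSet:
    """Read a centroid TSV: header 'gene<TAB>label...', '.'/empty = missing.

    Genes are uppercased; file row order is preserved. Duplicate symbols,
    non-numeric cells and absent expected subtype labels are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise SSP50Error(f"{path}: expected a gene column plus subtype columns")
    gene_col = df.columns[0]
    genes = df[gene_col].str.strip().str.upper()
    dup = genes[genes.duplicated()].unique().tolist()
    if dup:
        raise SSP50Error(f"{path}: duplicate gene symbol(s): {dup}")
    subtype_cols = list(df.columns[1:])
    values = np.full((len(df), len(subtype_cols)), np.nan)
    for j, col in enumerate(subtype_cols):
        for i, cell in enumerate(df[col].str.strip()):
            if cell in ("", "."):
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise SSP50Error(
                    f"{path}: non-numeric cell {cell!r} at row {i + 2}, column {col!r}"
                ) from None
    if expected_subtypes:
        absent = [s for s in expected_subtypes if s not in subtype_cols]
        if absent:
            raise SSP50Error(f"{path}: missing expected subtype label(s): {absent}")
    return CentroidSet(pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=subtype_cols))


def write_centroids(cs: CentroidSet, path) -> None:
    """Write a centroid TSV (missing entries as empty cells)."""
    out = cs.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.17g", na_rep="")


def impute_missing_knn(matrix: pd.DataFrame, cfg: ImputationConfig | None = None) -> pd.DataFrame:
    """Complete a gene-by-column matrix by gene-wise KNN.

    For each missing cell (g, c): among gene rows observed at column c, take
    the ``cfg.k`` nearest to row g by Euclidean distance over columns observed
    in both rows, normalized by the number of shared columns (so rows with
    different missingness patterns are comparable); the imputed value is the
    inverse-distance-weighted mean of their column-c values. Ties in distance
    break by row order. Rows with no observed entries are a hard error; fewer
    than k eligible neighbors uses all of them with a warning.
    """
    cfg = cfg or ImputationConfig()
    X = matrix.to_numpy(dtype=float)
    n_genes, n_cols = X.shape
    cfg.validate(n_genes)
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        bad = matrix.index[~obs.any(axis=1)].tolist()
        raise SSP50Error(f"gene row(s) with zero observed entries: {bad}")
    if obs.all():
        return matrix.copy()
    out = X.copy()
    for g in range(n_genes):
        miss_cols = np.flatnonzero(~obs[g])
        if miss_cols.size == 0:
            continue
        # distances from row g to every other row (NaN when no shared column)
        dists = np.full(n_genes, np.nan)
        for h in range(n_genes):
            if h == g:
                continue
            shared = obs[g] & obs[h]
            n_shared = int(shared.sum())
            if n_shared == 0:
                continue
            diff = X[g, shared] - X[h, shared]
            dists[h] = np.sqrt(np.sum(diff * diff) / n_shared)
        for c in miss_cols:
            eligible = np.flatnonzero(obs[:, c] & ~np.isnan(dists))
            if eligible.size == 0:
                raise SSP50Error(
                    f"no eligible neighbor for row {matrix.index[g]!r}, column {matrix.columns[c]!r}"
                )
            if eligible.size < cfg.k:
                warnings.warn(
                    f"only {eligible.size} eligible neighbors (< k={cfg.k}) for "
                    f"row {matrix.index[g]!r}, column {matrix.columns[c]!r}",
                    stacklevel=2,
                )
                chosen = eligible
            else:
                # stable sort => distance ties break by row order
                order = np.argsort(dists[eligible], kind="stable")
                chosen = eligible[order[: cfg.k]]
            d = dists[chosen]
            if np.any(d == 0):
                # exact duplicates dominate: average them with equal weight
                zero = chosen[d == 0]
                out[g, c] = float(np.mean(X[zero, c]))
            else:
                w = 1.0 / d
                out[g, c] = float(np.sum(w * X[chosen, c]) / np.sum(w))
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
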