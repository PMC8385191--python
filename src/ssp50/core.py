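"""Shared containers and constants for the subtyping pipeline.

The pipeline's common currency is a gene-by-sample matrix of log2 expression
(or raw digital counts, pre-normalization) carried in :class:`ExpressionMatrix`.
Subtype labels follow the intrinsic-taxonomy canonical order used everywhere
for deterministic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical intrinsic-subtype order (also the tie-break order).
SUBTYPES_5: tuple[str, ...] = (
    "Basal-like",
    "HER2-enriched",
    "LuminalA",
    "LuminalB",
    "Normal-like",
)

#: Four-subtype reduction: the five-subtype set minus Normal-like.
SUBTYPES_4: tuple[str, ...] = SUBTYPES_5[:4]

#: Label for samples whose maximum centroid correlation falls below threshold.
UNCLASSIFIED = "UNCLASSIFIED"

#: IHC phenotype categories in reporting order.
IHC_PHENOTYPES: tuple[str, ...] = (
    "HR+/HER2+",
    "HR+/HER2-",
    "HR-/HER2+",
    "HR-/HER2-",
)
IHC_MISSING = "missing"


class SSP50Error(ValueError):
    """Hard error raised on contract violations (bad input, failed validation)."""


@dataclass
class ExpressionMatrix:
    """Gene(or probe)-by-sample expression values with platform/scale tags.

    ``values`` is a pandas DataFrame indexed by gene symbol (or probe ID
    before collapse) with one column per sample. ``scale`` is ``"counts"``
    (raw digital counts, all >= 0) or ``"log2"`` (all finite).
    """

    values: pd.DataFrame
    platform: str = "unknown"
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("counts", "log2"):
            raise SSP50Error(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise SSP50Error(f"duplicate gene/probe IDs: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise SSP50Error(f"duplicate sample IDs: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if self.scale == "counts":
            if np.nanmin(arr) < 0 if arr.size else False:
                raise SSP50Error("counts-scale matrix contains negative values")
        else:
            if arr.size and not np.all(np.isfinite(arr[~np.isnan(arr)])):
                raise SSP50Error("log2-scale matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.platform, self.scale)


@dataclass
class ClinicalRecord:
    """Per-sample clinical annotation: IHC receptor status and follow-up."""

    sample_id: str
    hr_status: str = IHC_MISSING  # "positive" | "negative" | "missing"
    her2_status: str = IHC_MISSING
    followup_time: float = 0.0  # years
    event_death: bool = False  # all-cause mortality (overall survival)
    event_bc: bool = False  # recurrence / metastasis / BC-specific death

    def __post_init__(self) -> None:
        for name, value in (("hr_status", self.hr_status), ("her2_status", self.her2_status)):
            if value not in ("positive", "negative", IHC_MISSING):
                raise SSP50Error(f"unknown {name} token {value!r}")
        if self.followup_time < 0:
            raise SSP50Error(f"negative follow-up time for {self.sample_id}")

    @property
    def ihc_phenotype(self) -> str:
        """Combined HR/HER2 phenotype; 'missing' if either status is missing."""
        if IHC_MISSING in (self.hr_status, self.her2_status):
            return IHC_MISSING
        hr = "+" if self.hr_status == "positive" else "-"
        her2 = "+" if self.her2_status == "positive" else "-"
        return f"HR{hr}/HER2{her2}"


@dataclass
class SubtypeCall:
    """One sample's centroid correlations and the resulting subtype label."""

    sample_id: str
    correlations: dict[str, float] = field(default_factory=dict)
    label: str = UNCLASSIFIED
    mode: str = "SSP5"  # "SSP5" | "SSP2"
    n_genes_used: int = 0
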