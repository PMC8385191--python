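"""Agreement between paired subtype call sets and against IHC phenotypes.

The cross-platform question — do two expression assays assign the same
intrinsic subtype to the same tumor? — is quantified with a paired confusion
matrix (reference platform columns, test platform rows), per-class accuracy
against the reference, overall agreement, and unweighted Cohen's kappa.
Pairs where either platform left the sample unclassified are excluded from
the matrix body but reported, so the body total plus the exclusion count
always equals the number of pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    IHC_MISSING,
    IHC_PHENOTYPES,
    SSP50Error,
    UNCLASSIFIED,
    ClinicalRecord,
    SubtypeCall,
)

__all__ = [
    "ConcordanceResult",
    "confusion_matrix",
    "per_class_accuracy",
    "overall_agreement",
    "cohens_kappa",
    "ihc_crosstab",
    "normal_pair_summary",
]


@dataclass
class ConcordanceResult:
    """Paired-call agreement bookkeeping.

    ``matrix`` rows are test-platform labels, columns reference-platform
    labels; per-class denominators are reference column totals over
    classified pairs only.
    """

    matrix: pd.DataFrame  # test (rows) x reference (cols) counts, body only
    n_pairs_total: int
    n_unclassified_excluded: int
    per_class_accuracy: dict[str, tuple[int, int, float | None]] = field(default_factory=dict)
    agreement: tuple[int, float] | None = None
    kappa: float | None = None

    @property
    def body_total(self) -> int:
        return int(self.matrix.to_numpy().sum())


def _check_paired(calls_ref: list[SubtypeCall], calls_test: list[SubtypeCall]) -> None:
    ids_ref = {c.sample_id for c in calls_ref}
    ids_test = {c.sample_id for c in calls_test}
    if len(ids_ref) != len(calls_ref) or len(ids_test) != len(calls_test):
        raise SSP50Error("duplicate sample IDs within a call list")
    unpaired = ids_ref ^ ids_test
    if unpaired:
        raise SSP50Error(f"unpaired sample ID(s): {sorted(unpaired)}")


def confusion_matrix(
    calls_ref: list[SubtypeCall], calls_test: list[SubtypeCall]
) -> ConcordanceResult:
    """Tally paired calls; either-side UNCLASSIFIED pairs counted separately."""
    _check_paired(calls_ref, calls_test)
    modes = {c.mode for c in calls_ref} | {c.mode for c in calls_test}
    if len(modes) > 1:
        raise SSP50Error(f"mixed call modes: {sorted(modes)}")
    ref_by_id = {c.sample_id: c for c in calls_ref}
    labels = [s for s in _label_order(calls_ref + calls_test)]
    mat = pd.DataFrame(0, index=pd.Index(labels, name="test"), columns=pd.Index(labels, name="reference"))
    n_excluded = 0
    for t in calls_test:
        r = ref_by_id[t.sample_id]
        if UNCLASSIFIED in (r.label, t.label):
            n_excluded += 1
            continue
        mat.loc[t.label, r.label] += 1
    return ConcordanceResult(
        matrix=mat, n_pairs_total=len(calls_test), n_unclassified_excluded=n_excluded
    )


def _label_order(calls: list[SubtypeCall]) -> list[str]:
    from .core import SUBTYPES_5

    seen = {c.label for c in calls if c.label != UNCLASSIFIED}
    ordered = [s for s in SUBTYPES_5 if s in seen]
    ordered += sorted(seen - set(ordered))
    return ordered


def per_class_accuracy(result: ConcordanceResult) -> ConcordanceResult:
    """Diagonal cell over reference column total, per reference subtype.

    Undefined accuracies (empty reference column) are reported as None.
    """
    if result.matrix.empty:
        raise SSP50Error("confusion matrix body is empty")
    acc: dict[str, tuple[int, int, float | None]] = {}
    for s in result.matrix.columns:
        denom = int(result.matrix[s].sum())
        num = int(result.matrix.loc[s, s]) if s in result.matrix.index else 0
        acc[s] = (num, denom, num / denom if denom else None)
    result.per_class_accuracy = acc
    return result


def overall_agreement(result: ConcordanceResult) -> ConcordanceResult:
    """Diagonal sum over the classified-pairs body."""
    body = result.body_total
    if body == 0:
        raise SSP50Error("confusion matrix body is empty")
    diag = int(np.trace(result.matrix.to_numpy()))
    result.agreement = (diag, diag / body)
    return result


def cohens_kappa(result: ConcordanceResult) -> ConcordanceResult:
    """Unweighted Cohen's kappa on the classified-pairs body.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e = sum_i row_i * col_i / N^2 the chance agreement from the marginals.
    Degenerate marginals (p_e = 1) yield kappa = None.
    """
    M = result.matrix.to_numpy(dtype=float)
    N = M.sum()
    if N == 0:
        raise SSP50Error("confusion matrix body is empty")
    nonzero = ((M.sum(axis=0) > 0) | (M.sum(axis=1) > 0)).sum()
    if nonzero < 2:
        raise SSP50Error("kappa needs at least 2 classes with nonzero marginals")
    p_o = np.trace(M) / N
    p_e = float(M.sum(axis=1) @ M.sum(axis=0)) / N**2
    result.kappa = None if p_e == 1.0 else float((p_o - p_e) / (1.0 - p_e))
    return result


def concordance_report(
    calls_ref: list[SubtypeCall], calls_test: list[SubtypeCall]
) -> ConcordanceResult:
    """Convenience: confusion matrix with accuracies, agreement and kappa."""
    res = confusion_matrix(calls_ref, calls_test)
    per_class_accuracy(res)
    overall_agreement(res)
    cohens_kappa(res)
    return res


def ihc_crosstab(
    calls: list[SubtypeCall], clinical: list[ClinicalRecord]
) -> pd.DataFrame:
    """Subtype-by-IHC-phenotype counts, with an explicit missing-IHC row.

    Rows are the four HR/HER2 phenotypes plus 'missing'; columns are subtype
    labels (UNCLASSIFIED included when present). Per-subtype fractions are
    conventionally computed over non-missing IHC only — see
    :func:`phenotype_fraction`.
    """
    clin_by_id = {r.sample_id: r for r in clinical}
    unmatched = [c.sample_id for c in calls if c.sample_id not in clin_by_id]
    if unmatched:
        raise SSP50Error(f"call sample(s) without clinical record: {unmatched}")
    labels = _label_order(calls)
    if any(c.label == UNCLASSIFIED for c in calls):
        labels = labels + [UNCLASSIFIED]
    rows = list(IHC_PHENOTYPES) + [IHC_MISSING]
    tab = pd.DataFrame(0, index=pd.Index(rows, name="ihc"), columns=pd.Index(labels, name="subtype"))
    for c in calls:
        tab.loc[clin_by_id[c.sample_id].ihc_phenotype, c.label] += 1
    return tab


def phenotype_fraction(
    crosstab: pd.DataFrame, subtype: str, phenotypes: list[str]
) -> tuple[int, int, float | None]:
    """(numerator, denominator, fraction) of the given phenotypes within a
    subtype column, excluding missing-IHC cases from the denominator."""
    col = crosstab[subtype]
    denom = int(col.drop(IHC_MISSING).sum())
    num = int(col.loc[phenotypes].sum())
    return num, denom, (num / denom if denom else None)


def normal_pair_summary(
    calls_normal: list[SubtypeCall], calls_tumor: list[SubtypeCall]
) -> dict:
    """Summarize matched normal-tissue calls against their paired tumors.

    Reports (a) how many normals are called Normal-like (SSP5), and (b) among
    normals NOT called Normal-like, how many share the matched tumor's label.
    Pairing is positional by list order after ID validation.
    """
    if len(calls_normal) != len(calls_tumor):
        raise SSP50Error("normal and tumor call lists must pair 1:1")
    if any(c.mode != "SSP5" for c in calls_normal):
        raise SSP50Error("normal-tissue calls must be SSP5 (Normal-like centroid present)")
    n = len(calls_normal)
    n_normal_like = sum(1 for c in calls_normal if c.label == "Normal-like")
    others = [
        (cn, ct)
        for cn, ct in zip(calls_normal, calls_tumor)
        if cn.label != "Normal-like"
    ]
    n_match = sum(1 for cn, ct in others if cn.label == ct.label and cn.label != UNCLASSIFIED)
    return {
        "n_pairs": n,
        "n_normal_like": n_normal_like,
        "frac_normal_like": n_normal_like / n if n else None,
        "n_not_normal_like": len(others),
        "n_matching_tumor": n_match,
        "frac_matching_tumor": n_match / len(others) if others else None,
    }
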