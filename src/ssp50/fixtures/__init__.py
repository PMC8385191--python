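"""Transcribed study count tables, validated at load against printed totals.

Four tables ship with the package as reviewable TSV data files rather than
code literals:

* ``T1`` — IHC phenotype x subtype counts for the 109-tumor microarray
  cohort (one case unclassified; stored as an explicit UNCLASSIFIED column).
* ``T2`` — matched tumor subtype x normal-tissue subtype counts for the 24
  normal-breast pairs (five-centroid calls for the normals).
* ``T3`` — IHC phenotype x subtype counts for the 144-tumor digital-count
  cohort, including a missing-IHC row (one case unclassified).
* ``T4`` — paired subtype agreement between the two platforms for the 64
  tumors assayed on both (rows: microarray calls; columns: digital-count
  calls; one pair unclassified on the microarray side).

Helpers expand the count tables into paired call/clinical objects so the
concordance machinery consumes them exactly as it would real cohort calls.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..core import IHC_MISSING, SSP50Error, UNCLASSIFIED, ClinicalRecord, SubtypeCall

__all__ = ["load_fixture", "table4_calls", "table2_calls", "table_ihc_calls"]

_FILES = {"T1": "table1.tsv", "T2": "table2.tsv", "T3": "table3.tsv", "T4": "table4.tsv"}
_TOTALS = {"T1": 109, "T2": 24, "T3": 144, "T4": 64}


def load_fixture(table_id: str) -> pd.DataFrame:
    """Return the transcribed count table; totals checked against print."""
    if table_id not in _FILES:
        raise SSP50Error(f"unknown table id {table_id!r}; expected one of {sorted(_FILES)}")
    path = resources.files(__package__).joinpath(_FILES[table_id])
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", index_col=0)
    total = int(df.to_numpy().sum())
    if total != _TOTALS[table_id]:
        raise SSP50Error(
            f"{table_id}: transcription total {total} != printed total {_TOTALS[table_id]}"
        )
    if table_id == "T4" and int(df.drop(index=UNCLASSIFIED).to_numpy().sum()) != 63:
        raise SSP50Error("T4: classified body must sum to 63")
    return df


def _expand(counts_iter, mode: str):
    """Yield paired SubtypeCall lists from (ref_label, test_label, n) triples."""
    calls_ref, calls_test = [], []
    i = 0
    for ref_label, test_label, n in counts_iter:
        for _ in range(int(n)):
            i += 1
            sid = f"P{i:04d}"
            calls_ref.append(SubtypeCall(sample_id=sid, label=ref_label, mode=mode))
            calls_test.append(SubtypeCall(sample_id=sid, label=test_label, mode=mode))
    return calls_ref, calls_test


def table4_calls() -> tuple[list[SubtypeCall], list[SubtypeCall]]:
    """(reference = digital-count calls, test = microarray calls), paired."""
    df = load_fixture("T4")
    triples = (
        (col, row, df.loc[row, col]) for row in df.index for col in df.columns
    )
    return _expand(triples, mode="SSP2")


def table2_calls() -> tuple[list[SubtypeCall], list[SubtypeCall]]:
    """(normal-tissue SSP5 calls, matched tumor calls), paired by position."""
    df = load_fixture("T2")
    calls_normal, calls_tumor = [], []
    i = 0
    for tumor_label in df.index:
        for normal_label in df.columns:
            for _ in range(int(df.loc[tumor_label, normal_label])):
                i += 1
                calls_normal.append(
                    SubtypeCall(sample_id=f"N{i:04d}", label=normal_label, mode="SSP5")
                )
                calls_tumor.append(
                    SubtypeCall(sample_id=f"T{i:04d}", label=tumor_label, mode="SSP5")
                )
    return calls_normal, calls_tumor


def table_ihc_calls(table_id: str) -> tuple[list[SubtypeCall], list[ClinicalRecord]]:
    """Expand an IHC-by-subtype table into calls plus clinical records."""
    if table_id not in ("T1", "T3"):
        raise SSP50Error("IHC crosstab fixtures are T1 and T3")
    df = load_fixture(table_id)
    calls, clinical = [], []
    i = 0
    for pheno in df.index:
        if pheno == IHC_MISSING:
            hr = her2 = IHC_MISSING
        else:
            hr = "positive" if pheno.startswith("HR+") else "negative"
            her2 = "positive" if pheno.endswith("HER2+") else "negative"
        for label in df.columns:
            for _ in range(int(df.loc[pheno, label])):
                i += 1
                sid = f"C{i:04d}"
                calls.append(SubtypeCall(sample_id=sid, label=label, mode="SSP2"))
                clinical.append(ClinicalRecord(sample_id=sid, hr_status=hr, her2_status=her2))
    return calls, clinical
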