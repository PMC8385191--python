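"""File formats: expression TSV (with a scale metadata line), clinical CSV.

Expression matrices ship gene-major as TSV with a single comment line
``#scale=counts|log2 platform=<tag>`` followed by an ``id`` column and one
column per sample. Clinical records are CSV with a controlled vocabulary for
receptor statuses. Round trips are lossless at 12 significant digits.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd

from .core import IHC_MISSING, SSP50Error, ClinicalRecord, ExpressionMatrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical_csv",
    "write_clinical_csv",
]

_STATUS_TOKENS = {"positive", "negative", "missing"}
_BOOL_TOKENS = {"1": True, "0": False, "true": True, "false": False, "True": True, "False": False}


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a gene-by-sample TSV; scale/platform from the # metadata line."""
    scale, platform = "log2", "unknown"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if token.startswith("scale="):
                    scale = token[6:]
                elif token.startswith("platform="):
                    platform = token[9:]
            header_line = fh.readline()
        else:
            header_line = first
        header = header_line.rstrip("\n").split("\t")
        if len(header) < 2:
            raise SSP50Error(f"{path}: expected an id column plus sample columns")
        samples = header[1:]
        dup = {s for s in samples if samples.count(s) > 1}
        if dup:
            raise SSP50Error(f"{path}: duplicate sample column(s): {sorted(dup)}")
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=3 if first.startswith("#") else 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise SSP50Error(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(parts)} fields, expected {len(header)})"
                )
            ids.append(parts[0])
            try:
                rows.append([float(v) if v not in ("", ".") else np.nan for v in parts[1:]])
            except ValueError as exc:
                raise SSP50Error(f"{path}: non-numeric cell at line {lineno}: {exc}") from None
    if len(ids) != len(set(ids)):
        dup = {i for i in ids if ids.count(i) > 1}
        raise SSP50Error(f"{path}: duplicate row ID(s): {sorted(dup)}")
    df = pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=samples, dtype=float)
    return ExpressionMatrix(df, platform=platform, scale=scale)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#scale={matrix.scale} platform={matrix.platform}\n")
        fh.write("id\t" + "\t".join(str(s) for s in matrix.samples) + "\n")
        arr = matrix.values.to_numpy(dtype=float)
        for gene, row in zip(matrix.genes, arr):
            cells = "\t".join("" if np.isnan(v) else f"{v:.12g}" for v in row)
            fh.write(f"{gene}\t{cells}\n")


_CLINICAL_COLUMNS = [
    "sample_id",
    "hr_status",
    "her2_status",
    "followup_time",
    "event_death",
    "event_bc",
]


def read_clinical_csv(path) -> list[ClinicalRecord]:
    """Parse clinical records; unknown status tokens are hard errors."""
    records: list[ClinicalRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing_cols = [c for c in _CLINICAL_COLUMNS if c not in (reader.fieldnames or [])]
        if missing_cols:
            raise SSP50Error(f"{path}: missing column(s): {missing_cols}")
        for i, row in enumerate(reader, start=2):
            for col in ("hr_status", "her2_status"):
                if row[col] not in _STATUS_TOKENS:
                    raise SSP50Error(f"{path}: line {i}: unknown {col} token {row[col]!r}")
            for col in ("event_death", "event_bc"):
                if row[col] not in _BOOL_TOKENS:
                    raise SSP50Error(f"{path}: line {i}: unknown boolean token {row[col]!r}")
            try:
                t = float(row["followup_time"])
            except ValueError:
                raise SSP50Error(
                    f"{path}: line {i}: non-numeric time {row['followup_time']!r}"
                ) from None
            if t < 0:
                raise SSP50Error(f"{path}: line {i}: negative follow-up time")
            records.append(
                ClinicalRecord(
                    sample_id=row["sample_id"],
                    hr_status=row["hr_status"],
                    her2_status=row["her2_status"],
                    followup_time=t,
                    event_death=_BOOL_TOKENS[row["event_death"]],
                    event_bc=_BOOL_TOKENS[row["event_bc"]],
                )
            )
    return records


def write_clinical_csv(records: list[ClinicalRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CLINICAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    r.hr_status,
                    r.her2_status,
                    f"{r.followup_time:.12g}",
                    int(r.event_death),
                    int(r.event_bc),
                ]
            )
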