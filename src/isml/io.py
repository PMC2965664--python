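"""Readers and writers for the flat tab-separated formats the pipeline touches.

Dialect: UTF-8 TSV, first row header, first column gene identifier, empty
cell = missing.  Matrices are stored genes-in-rows, samples-in-columns (the
microarray convention); a ``transpose`` dialect flag accepts samples-in-rows
exports.  All floating-point output uses 6 significant digits except
percentages, which are printed to 1 decimal.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .datatypes import ExpressionMatrix, SampleAnnotation, SpikeInTable, check_unique
from .errors import FormatError, ValidationError

__all__ = [
    "TableDialect",
    "read_expression_table",
    "write_expression_table",
    "read_sample_annotation",
    "write_sample_annotation",
    "read_spikein_table",
    "write_spikein_table",
    "write_ranked_genes",
    "write_run_summary",
]

FLOAT_FMT = "%.6g"

_ANNOTATION_OPTIONAL = {
    "compound": str,
    "concentration_mg_per_kg": float,
    "duration_days": float,
    "experiment_block": str,
    "replicate": int,
}


@dataclass(frozen=True)
class TableDialect:
    """How a flat expression table is laid out on disk."""

    sep: str = "\t"
    missing: tuple[str, ...] = ("",)
    transpose: bool = False  # True when the file stores samples in rows


def _read_rows(path: str | Path, sep: str) -> list[list[str]]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows:
        raise FormatError(f"{path}: empty file")
    width = len(rows[0])
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged row at line {lineno} "
                f"({len(row)} fields, expected {width})"
            )
    return rows


def read_expression_table(
    path: str | Path, dialect: TableDialect = TableDialect()
) -> ExpressionMatrix:
    """Read a genes x samples TSV into an :class:`ExpressionMatrix`.

    Missing cells (any sentinel in ``dialect.missing``) become masked NaNs.
    Row and column order of the file is preserved.  Duplicated gene or sample
    identifiers and ragged rows raise :class:`FormatError` naming the
    offender.
    """
    rows = _read_rows(path, dialect.sep)
    header = rows[0][1:]
    row_ids = [r[0] for r in rows[1:]]
    if dialect.transpose:
        gene_ids, sample_ids = header, row_ids
    else:
        gene_ids, sample_ids = row_ids, header
    try:
        check_unique(gene_ids, "gene")
        check_unique(sample_ids, "sample")
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from None

    missing = set(dialect.missing)
    n_rows, n_cols = len(rows) - 1, len(header)
    values = np.empty((n_rows, n_cols))
    mask = np.ones((n_rows, n_cols), dtype=bool)
    for i, row in enumerate(rows[1:]):
        for j, cell in enumerate(row[1:]):
            if cell in missing:
                values[i, j] = np.nan
                mask[i, j] = False
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell {cell!r} at line {i + 2}"
                    ) from None
    if dialect.transpose:
        values, mask = values.T, mask.T
    return ExpressionMatrix(gene_ids, sample_ids, values, mask)


def write_expression_table(
    m: ExpressionMatrix, path: str | Path, dialect: TableDialect = TableDialect()
) -> None:
    """Write the matrix in the standard dialect; masked cells become empty."""
    sentinel = dialect.missing[0]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id" + dialect.sep + dialect.sep.join(m.sample_ids) + "\n")
        for i, gene in enumerate(m.gene_ids):
            cells = [
                (FLOAT_FMT % m.values[i, j]) if m.mask[i, j] else sentinel
                for j in range(m.n_samples)
            ]
            fh.write(gene + dialect.sep + dialect.sep.join(cells) + "\n")


def read_sample_annotation(
    path: str | Path, class_names: Sequence[str] | None = None
) -> list[SampleAnnotation]:
    """Read per-sample treatment annotations.

    Required columns: ``sample_id``, ``class_label``.  When ``class_names``
    is given every label is validated against it and an unknown label raises
    :class:`ValidationError` listing the allowed set.
    """
    rows = _read_rows(path, "\t")
    header = rows[0]
    for required in ("sample_id", "class_label"):
        if required not in header:
            raise FormatError(f"{path}: missing required column {required!r}")
    col = {name: idx for idx, name in enumerate(header)}
    out: list[SampleAnnotation] = []
    allowed = set(class_names) if class_names is not None else None
    for row in rows[1:]:
        label = row[col["class_label"]]
        if allowed is not None and label not in allowed:
            raise ValidationError(
                f"unknown class label {label!r} for sample "
                f"{row[col['sample_id']]!r}; allowed: {sorted(allowed)}"
            )
        kwargs: dict = {"sample_id": row[col["sample_id"]], "class_label": label}
        for name, cast in _ANNOTATION_OPTIONAL.items():
            if name in col and row[col[name]] != "":
                key = "concentration" if name == "concentration_mg_per_kg" else name
                kwargs[key] = cast(row[col[name]])
        out.append(SampleAnnotation(**kwargs))
    check_unique([a.sample_id for a in out], "sample")
    return out


def write_sample_annotation(
    annotations: Sequence[SampleAnnotation], path: str | Path
) -> None:
    cols = [
        "sample_id",
        "class_label",
        "compound",
        "concentration_mg_per_kg",
        "duration_days",
        "experiment_block",
        "replicate",
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in annotations:
            row = [
                a.sample_id,
                a.class_label,
                a.compound or "",
                "" if a.concentration is None else FLOAT_FMT % a.concentration,
                "" if a.duration_days is None else FLOAT_FMT % a.duration_days,
                a.experiment_block or "",
                "" if a.replicate is None else str(a.replicate),
            ]
            fh.write("\t".join(row) + "\n")


def read_spikein_table(path: str | Path) -> SpikeInTable:
    rows = _read_rows(path, "\t")
    header = rows[0]
    for required in ("probe_id", "known_concentration"):
        if required not in header:
            raise FormatError(f"{path}: missing required column {required!r}")
    col = {name: idx for idx, name in enumerate(header)}
    probes = [r[col["probe_id"]] for r in rows[1:]]
    concs = [float(r[col["known_concentration"]]) for r in rows[1:]]
    return SpikeInTable(probes, np.asarray(concs))


def write_spikein_table(spikes: SpikeInTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("probe_id\tknown_concentration\n")
        for p, c in zip(spikes.probe_ids, spikes.known_concentrations):
            fh.write(f"{p}\t{FLOAT_FMT % c}\n")


def write_ranked_genes(table, path: str | Path) -> None:
    """Write a ranked gene-weight table as TSV sorted by rank ascending.

    ``table`` is any object exposing ``gene_ids``, ``overall`` (weight per
    gene) and ``rank`` (1 = highest weight).  Output is byte-identical for
    identical input.
    """
    order = np.argsort(np.asarray(table.rank))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\toverall_weight\trank\n")
        for i in order:
            fh.write(
                f"{table.gene_ids[i]}\t{FLOAT_FMT % table.overall[i]}\t{int(table.rank[i])}\n"
            )


def write_run_summary(summary: dict, path: str | Path) -> None:
    """Machine-readable key -> value summary of one pipeline invocation."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
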