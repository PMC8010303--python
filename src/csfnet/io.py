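"""Readers and writers for the delimited-text formats the pipeline consumes.

Abundance matrices and sample metadata are plain TSV/CSV (delimiter sniffed
from the header line unless given); gene sets use the GMT dialect and
protein-to-gene maps a 2-column table.  Empty cells and configurable
sentinel tokens ("NA" by default) become missing values.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    AbundanceMatrix,
    FormatError,
    GeneMap,
    GeneSetCollection,
    SampleInfo,
    validate_metadata,
)

__all__ = [
    "read_abundance",
    "write_abundance",
    "read_metadata",
    "write_metadata",
    "read_gene_map",
    "write_gene_map",
    "read_gmt",
    "write_gmt",
]

DEFAULT_SENTINELS = ("", "NA", "NaN", "nan")

METADATA_COLUMNS = ["sample_id", "subject_id", "group", "visit", "months_from_baseline"]


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_abundance(
    path: str | Path,
    orientation: str = "proteins_in_rows",
    scale: str = "linear",
    delimiter: str | None = None,
    sentinels: Sequence[str] = DEFAULT_SENTINELS,
) -> AbundanceMatrix:
    """Parse a delimited abundance matrix.

    ``orientation`` declares the file layout (``proteins_in_rows`` or
    ``proteins_in_columns``); the returned matrix is always proteins x
    samples.  Cells equal to a sentinel token (or empty) become NaN; any
    other non-numeric cell is a format error, as are duplicate identifiers.
    """
    path = Path(path)
    if orientation not in ("proteins_in_rows", "proteins_in_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    delim = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(
        path,
        sep=delim,
        index_col=0,
        dtype=str,
        keep_default_na=False,
        na_values=[],
    )
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate row or column identifiers")
    sent = set(sentinels)
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for (i, j), cell in np.ndenumerate(raw):
        token = cell.strip()
        if token in sent:
            values[i, j] = np.nan
        else:
            try:
                values[i, j] = float(token)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at row "
                    f"{df.index[i]!r}, column {df.columns[j]!r}"
                ) from None
    if orientation == "proteins_in_columns":
        values = values.T
        protein_ids, sample_ids = list(df.columns), list(df.index)
    else:
        protein_ids, sample_ids = list(df.index), list(df.columns)
    return AbundanceMatrix(protein_ids, sample_ids, values, scale=scale)


def write_abundance(
    matrix: AbundanceMatrix,
    path: str | Path,
    delimiter: str = "\t",
    missing_token: str = "NA",
) -> None:
    """Write proteins-in-rows; full float precision (repr round-trip)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["protein_id", *matrix.sample_ids])
        for i, pid in enumerate(matrix.protein_ids):
            row = [
                missing_token if np.isnan(v) else repr(float(v))
                for v in matrix.values[i]
            ]
            writer.writerow([pid, *row])


def read_metadata(path: str | Path, delimiter: str | None = None) -> list[SampleInfo]:
    """Parse sample metadata with required columns
    sample_id/subject_id/group/visit/months_from_baseline and validate the
    per-subject visit invariants."""
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False, na_values=[])
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    records = []
    for _, row in df.iterrows():
        try:
            records.append(
                SampleInfo(
                    sample_id=row["sample_id"],
                    subject_id=row["subject_id"],
                    group=row["group"],
                    visit=int(row["visit"]),
                    months_from_baseline=float(row["months_from_baseline"]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: bad metadata row {row.to_dict()}: {exc}") from None
    validate_metadata(records)
    return records


def write_metadata(records: Iterable[SampleInfo], path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(METADATA_COLUMNS)
        for r in records:
            writer.writerow(
                [r.sample_id, r.subject_id, r.group, r.visit, repr(float(r.months_from_baseline))]
            )


def group_labels_in_order(records: Sequence[SampleInfo]) -> list[str]:
    """Distinct group labels in first-appearance order."""
    seen: list[str] = []
    for r in records:
        if r.group not in seen:
            seen.append(r.group)
    return seen


def orphan_samples(
    matrix: AbundanceMatrix, records: Sequence[SampleInfo]
) -> tuple[set[str], set[str]]:
    """Samples present in only one of matrix/metadata: (matrix-only, metadata-only)."""
    in_matrix = set(matrix.sample_ids)
    in_meta = {r.sample_id for r in records}
    return in_matrix - in_meta, in_meta - in_matrix


def read_gene_map(path: str | Path, delimiter: str | None = None) -> GeneMap:
    """2-column protein_id -> gene_symbol table (header optional, detected
    when the first line reads like column names)."""
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(delim)
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            pid, gene = parts[0].strip(), parts[1].strip()
            if lineno == 1 and pid.lower() in ("protein_id", "protein", "id"):
                continue
            if pid in mapping and mapping[pid] != gene:
                raise FormatError(f"{path}: protein {pid!r} mapped to multiple genes")
            mapping[pid] = gene
    return GeneMap(mapping)


def write_gene_map(gene_map: GeneMap, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"protein_id{delimiter}gene_symbol\n")
        for pid, gene in gene_map.mapping.items():
            fh.write(f"{pid}{delimiter}{gene}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Standard GMT: one set per line, fields set-name, description, members."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m.strip()]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
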