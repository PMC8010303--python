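"""Shared data model for the analysis pipeline.

The single currency flowing through every stage is the
:class:`AbundanceMatrix`: a proteins x samples matrix of abundance values
with missing entries encoded as NaN and an explicit scale flag (``linear``
raw abundances vs natural-``log`` abundances).  Sample annotations travel
as lists of :class:`SampleInfo` records; protein-to-gene mappings and gene
sets are small mapping types used by the enrichment stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "SampleInfo",
    "GeneMap",
    "GeneSetCollection",
    "FormatError",
    "metadata_frame",
    "validate_metadata",
]


class FormatError(ValueError):
    """Raised when an input file or in-memory structure violates the data model."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise FormatError(f"duplicate {what} identifiers: {dups[:5]}")
    return ids


@dataclass
class AbundanceMatrix:
    """Proteins x samples abundance matrix with NaN for missing values.

    Parameters
    ----------
    protein_ids, sample_ids:
        Ordered, duplicate-free identifiers for rows and columns.
    values:
        Float array of shape ``(n_proteins, n_samples)``; NaN marks missing.
    scale:
        ``"linear"`` (all observed values strictly positive, so a log
        transform is valid) or ``"log"`` (natural-log abundances).
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.protein_ids = _check_unique(self.protein_ids, "protein")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.protein_ids)} proteins, {len(self.sample_ids)} samples)"
            )
        if self.scale not in ("linear", "log"):
            raise FormatError(f"unknown scale {self.scale!r}")
        if self.scale == "linear":
            obs = self.values[~np.isnan(self.values)]
            if obs.size and (obs <= 0).any():
                raise FormatError("linear-scale matrix contains non-positive values")

    # -- convenience -------------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.sample_ids)

    def protein_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.protein_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.sample_ids)}

    def subset_proteins(self, keep: Sequence[str]) -> "AbundanceMatrix":
        idx = self.protein_index()
        rows = [idx[p] for p in keep]
        return AbundanceMatrix(list(keep), list(self.sample_ids), self.values[rows, :], self.scale)

    def subset_samples(self, keep: Sequence[str]) -> "AbundanceMatrix":
        idx = self.sample_index()
        cols = [idx[s] for s in keep]
        return AbundanceMatrix(list(self.protein_ids), list(keep), self.values[:, cols], self.scale)


@dataclass(frozen=True)
class SampleInfo:
    """One sample's annotations: subject, group, visit number and time."""

    sample_id: str
    subject_id: str
    group: str
    visit: int
    months_from_baseline: float

    def __post_init__(self) -> None:
        if self.visit < 1:
            raise FormatError(f"sample {self.sample_id}: visit must be >= 1")
        if self.months_from_baseline < 0:
            raise FormatError(f"sample {self.sample_id}: negative months_from_baseline")
        if self.visit == 1 and self.months_from_baseline != 0:
            raise FormatError(
                f"sample {self.sample_id}: visit 1 must have months_from_baseline = 0"
            )


def validate_metadata(records: Sequence[SampleInfo]) -> None:
    """Check cross-record invariants: unique sample ids, strictly increasing
    visit times within each subject, and visit-1 anchoring at month 0."""
    _check_unique([r.sample_id for r in records], "sample")
    by_subject: dict[str, list[SampleInfo]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    for subject, recs in by_subject.items():
        recs = sorted(recs, key=lambda r: r.visit)
        visits = [r.visit for r in recs]
        if len(set(visits)) != len(visits):
            raise FormatError(f"subject {subject}: duplicate visit numbers")
        months = [r.months_from_baseline for r in recs]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise FormatError(
                f"subject {subject}: months_from_baseline not strictly increasing across visits"
            )


def metadata_frame(records: Sequence[SampleInfo]) -> pd.DataFrame:
    """Tabular view of SampleInfo records, indexed by sample_id."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "visit": [r.visit for r in records],
            "months_from_baseline": [r.months_from_baseline for r in records],
        }
    ).set_index("sample_id", drop=False)


@dataclass
class GeneMap:
    """Many-to-one mapping from protein identifiers to gene symbols."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}

    def __getitem__(self, protein_id: str) -> str:
        return self.mapping[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.mapping

    def genes(self) -> set[str]:
        return set(self.mapping.values())

    @classmethod
    def identity(cls, ids: Sequence[str]) -> "GeneMap":
        return cls({str(i): str(i) for i in ids})


@dataclass
class GeneSetCollection:
    """Named gene sets (deduplicated, non-empty) with optional descriptions."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, set[str]] = {}
        for name, members in self.sets.items():
            members = {str(m) for m in members}
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            clean[str(name)] = members
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


GroupMapping = Mapping[str, Sequence[str]]
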