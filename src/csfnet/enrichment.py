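"""Hypergeometric set enrichment and cross-network module preservation.

A foreground list (e.g. dyscorrelated or longitudinally changing proteins,
abstracted to genes) is tested against each candidate set (module
memberships or user-supplied gene sets) with the upper-tail hypergeometric
probability P(X >= a) for a = |foreground & set| drawn without replacement
from the background.  Odds ratios are sample odds ratios with the
Haldane-Anscombe +0.5 correction when any 2x2 cell is zero.  Module
preservation between two networks is the full grid of such tests on the
identifier intersection ("cross-tabulation").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .model import GeneMap, GeneSetCollection
from .differential import bh_adjust

__all__ = [
    "EnrichmentRecord",
    "CrossTabResult",
    "abstract_to_genes",
    "hypergeometric_enrichment",
    "cross_tabulation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRecord:
    """2x2 overlap of a foreground with one set, within a shared background."""

    set_id: str
    a: int  # foreground & set
    b: int  # foreground \ set
    c: int  # set \ foreground
    d: int  # neither
    odds_ratio: float
    p_value: float
    p_adjusted: float = np.nan

    @property
    def background_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class CrossTabResult:
    modules_a: list[int]
    modules_b: list[int]
    records: dict[tuple[int, int], EnrichmentRecord]
    background: set[str]

    def neg_log10_p(self) -> np.ndarray:
        """Matrix of -log10 raw p, modules_a x modules_b."""
        out = np.zeros((len(self.modules_a), len(self.modules_b)))
        for i, ma in enumerate(self.modules_a):
            for j, mb in enumerate(self.modules_b):
                out[i, j] = -np.log10(max(self.records[(ma, mb)].p_value, 1e-300))
        return out


def abstract_to_genes(
    ids: Iterable[str],
    gene_map: GeneMap,
    kin: Mapping[str, float] | None = None,
) -> set[str]:
    """Collapse protein identifiers to gene symbols through ``gene_map``.

    Unmapped proteins are dropped with a logged count.  ``kin`` only
    matters to callers that assign genes to modules: when a gene's proteins
    span modules the caller should keep the highest-kin protein (see
    :func:`module_gene_sets`).
    """
    del kin  # resolution handled by module_gene_sets; kept for signature parity
    ids = list(ids)
    mapped = {gene_map[p] for p in ids if p in gene_map}
    dropped = sum(1 for p in ids if p not in gene_map)
    if dropped:
        log.info("abstract_to_genes: dropped %d/%d unmapped identifiers", dropped, len(ids))
    return mapped


def module_gene_sets(
    protein_ids: Sequence[str],
    module_assignment: Sequence[int],
    gene_map: GeneMap,
    kin: Sequence[float] | None = None,
) -> dict[int, set[str]]:
    """Gene-level module memberships.

    A gene inherits the module of its protein; when a gene's proteins span
    several modules it is assigned to the module of its highest-kin protein
    (ties break toward the smaller module id).
    """
    best: dict[str, tuple[float, int]] = {}
    for idx, (pid, m) in enumerate(zip(protein_ids, module_assignment)):
        if pid not in gene_map or m == 0:
            continue
        gene = gene_map[pid]
        k = float(kin[idx]) if kin is not None else 0.0
        cur = best.get(gene)
        if cur is None or (k, -m) > (cur[0], -cur[1]):
            best[gene] = (k, int(m))
    out: dict[int, set[str]] = {}
    for gene, (_k, m) in best.items():
        out.setdefault(m, set()).add(gene)
    return out


def _record(set_id: str, foreground: set, background: set, members: set) -> EnrichmentRecord:
    members = members & background
    a = len(foreground & members)
    b = len(foreground - members)
    c = len(members - foreground)
    d = len(background) - a - b - c
    # upper-tail: P(X >= a) for X ~ Hypergeom(N, K, n)
    p = float(stats.hypergeom.sf(a - 1, len(background), len(members), len(foreground)))
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    odds = (cells[0] * cells[3]) / (cells[1] * cells[2])
    return EnrichmentRecord(set_id=set_id, a=a, b=b, c=c, d=d, odds_ratio=float(odds), p_value=min(p, 1.0))


def hypergeometric_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection | Mapping[str, set[str]],
    alpha: float = 0.1,
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric enrichment of ``foreground`` in each set.

    The foreground must be contained in the background; each set is
    intersected with the background before counting.  BH adjustment runs
    across all tested sets.
    """
    foreground = set(foreground)
    background = set(background)
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    records = [
        _record(str(name), foreground, background, set(members)) for name, members in sets.items()
    ]
    if records:
        q = bh_adjust([r.p_value for r in records])
        records = [
            EnrichmentRecord(
                set_id=r.set_id, a=r.a, b=r.b, c=r.c, d=r.d,
                odds_ratio=r.odds_ratio, p_value=r.p_value, p_adjusted=float(qv),
            )
            for r, qv in zip(records, q)
        ]
    del alpha  # significance is the caller's reading of p_adjusted
    return records


def cross_tabulation(
    assignment_a: Mapping[str, int],
    assignment_b: Mapping[str, int],
    gene_map_a: GeneMap | None = None,
    gene_map_b: GeneMap | None = None,
) -> CrossTabResult:
    """Module-preservation grid between two networks.

    Assignments map identifier -> module (0 = unassigned).  Identifiers are
    abstracted through the gene maps when given (identity otherwise); the
    background is the identifier intersection, and every (module of A,
    module of B) cell gets an upper-tail hypergeometric enrichment record,
    BH-adjusted across the whole grid.
    """
    def genes_by_module(assignment: Mapping[str, int], gmap: GeneMap | None) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for pid, m in assignment.items():
            if m == 0:
                continue
            gene = gmap[pid] if gmap is not None and pid in gmap else (pid if gmap is None else None)
            if gene is None:
                continue
            out.setdefault(int(m), set()).add(gene)
        return out

    by_a = genes_by_module(assignment_a, gene_map_a)
    by_b = genes_by_module(assignment_b, gene_map_b)
    univ_a = set().union(*by_a.values()) if by_a else set()
    univ_b = set().union(*by_b.values()) if by_b else set()
    background = univ_a & univ_b
    if not background:
        raise ValueError("no shared identifiers between the two networks")
    modules_a = sorted(by_a)
    modules_b = sorted(by_b)
    cells: dict[tuple[int, int], EnrichmentRecord] = {}
    for ma in modules_a:
        fg = by_a[ma] & background
        for mb in modules_b:
            rec = _record(f"A{ma}|B{mb}", fg, background, by_b[mb])
            cells[(ma, mb)] = rec
    keys = list(cells)
    q = bh_adjust([cells[k].p_value for k in keys])
    for k, qv in zip(keys, q):
        r = cells[k]
        cells[k] = EnrichmentRecord(
            set_id=r.set_id, a=r.a, b=r.b, c=r.c, d=r.d,
            odds_ratio=r.odds_ratio, p_value=r.p_value, p_adjusted=float(qv),
        )
    return CrossTabResult(modules_a=modules_a, modules_b=modules_b, records=cells, background=background)
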