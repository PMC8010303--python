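"""Group comparisons: eigenprotein shifts and differential correlation.

Module eigenproteins are compared between each disease group and the
reference group with a two-sided Mann-Whitney U test (exact null when both
groups are small and untied, normal approximation with tie and continuity
correction otherwise); with fewer than 20 such tests, raw p-values are
reported.  Protein-pair correlations are compared between groups through
Fisher's r-to-z transform,

    Z = (atanh(r_ref) - atanh(r_dis)) / sqrt(1/(n_ref - 3) + 1/(n_dis - 3)),

with two-sided normal p-values corrected by the Benjamini-Hochberg step-up
procedure across all tested pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import AbundanceMatrix, SampleInfo, metadata_frame
from .network import pairwise_correlation

__all__ = [
    "EigenproteinTestRecord",
    "DiffCorrRecord",
    "eigenprotein_group_tests",
    "group_correlation_profiles",
    "differential_correlation",
    "differential_correlation_table",
    "bh_adjust",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EigenproteinTestRecord:
    module: int
    group_a: str
    group_b: str
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float


@dataclass(frozen=True)
class DiffCorrRecord:
    protein_i: str
    protein_j: str
    r_ref: float
    n_ref: int
    r_dis: float
    n_dis: int
    z_ref: float
    z_dis: float
    z_statistic: float
    p_value: float
    p_adjusted: float = np.nan
    significant: bool = False


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Sorted ascending, ``q_(i) = min_{j >= i} p_(j) * m / j`` capped at 1,
    returned in the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact when both n <= 12 without ties,
    tie/continuity-corrected normal approximation otherwise.  Degenerate
    all-tied input carries no evidence and yields p = 1."""
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        return len(a) * len(b) / 2.0, 1.0
    if len(a) <= 12 and len(b) <= 12 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def eigenprotein_group_tests(
    eigenproteins: np.ndarray,
    sample_ids: Sequence[str],
    metadata: Sequence[SampleInfo],
    reference_group: str,
    module_labels: Sequence[int] | None = None,
) -> list[EigenproteinTestRecord]:
    """Mann-Whitney test of each module eigenprotein, each non-reference
    group against the reference group only (no disease-vs-disease tests)."""
    eigenproteins = np.asarray(eigenproteins, dtype=float)
    meta = metadata_frame(metadata).loc[list(sample_ids)]
    groups = meta["group"].to_numpy()
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} has no samples")
    others = [g for g in dict.fromkeys(groups) if g != reference_group]
    labels = (
        list(module_labels)
        if module_labels is not None
        else list(range(1, eigenproteins.shape[0] + 1))
    )
    ref_cols = groups == reference_group
    records = []
    for k, module in enumerate(labels):
        e = eigenproteins[k]
        ref_vals = e[ref_cols]
        if ref_vals.size < 2:
            raise ValueError("reference group needs >= 2 samples")
        for g in others:
            vals = e[groups == g]
            if vals.size < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples")
            u, p = _mannwhitney(ref_vals, vals)
            records.append(
                EigenproteinTestRecord(
                    module=int(module),
                    group_a=reference_group,
                    group_b=g,
                    median_a=float(np.median(ref_vals)),
                    median_b=float(np.median(vals)),
                    u_statistic=u,
                    p_value=p,
                )
            )
    return records


def group_correlation_profiles(
    matrix: AbundanceMatrix,
    metadata: Sequence[SampleInfo],
    group: str,
    min_pairwise_n: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson correlations restricted to one group's samples."""
    meta = metadata_frame(metadata).loc[matrix.sample_ids]
    keep = [s for s, g in zip(matrix.sample_ids, meta["group"]) if g == group]
    if len(keep) < max(2, min_pairwise_n):
        raise ValueError(
            f"group {group!r} has {len(keep)} samples; needs >= {max(2, min_pairwise_n)}"
        )
    return pairwise_correlation(matrix.subset_samples(keep), min_pairwise_n)


def differential_correlation(
    r_ref: np.ndarray,
    n_ref: np.ndarray,
    r_dis: np.ndarray,
    n_dis: np.ndarray,
    protein_ids: Sequence[str],
    alpha: float = 0.1,
    pair_mask: np.ndarray | None = None,
) -> list[DiffCorrRecord]:
    """Fisher r-to-z comparison of two groups' correlation matrices.

    Tests every upper-triangle pair with defined correlations and more than
    3 complete observations in both groups (optionally restricted by
    ``pair_mask``); pairs failing the requirement are skipped with a logged
    count.  Returns all records, flagged by BH-adjusted p < ``alpha``.
    """
    table = differential_correlation_table(
        r_ref, n_ref, r_dis, n_dis, protein_ids, alpha=alpha, pair_mask=pair_mask
    )
    return [
        DiffCorrRecord(
            protein_i=row.protein_i,
            protein_j=row.protein_j,
            r_ref=row.r_ref,
            n_ref=int(row.n_ref),
            r_dis=row.r_dis,
            n_dis=int(row.n_dis),
            z_ref=row.z_ref,
            z_dis=row.z_dis,
            z_statistic=row.z_statistic,
            p_value=row.p_value,
            p_adjusted=row.p_adjusted,
            significant=bool(row.significant),
        )
        for row in table.itertuples(index=False)
    ]


def differential_correlation_table(
    r_ref: np.ndarray,
    n_ref: np.ndarray,
    r_dis: np.ndarray,
    n_dis: np.ndarray,
    protein_ids: Sequence[str],
    alpha: float = 0.1,
    pair_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Vectorized form of :func:`differential_correlation` returning a
    DataFrame; preferred at whole-network scale (hundreds of thousands of
    pairs)."""
    r_ref = np.asarray(r_ref, float)
    r_dis = np.asarray(r_dis, float)
    n_ref = np.asarray(n_ref)
    n_dis = np.asarray(n_dis)
    P = r_ref.shape[0]
    iu = np.triu_indices(P, k=1)
    ok = (
        ~np.isnan(r_ref[iu])
        & ~np.isnan(r_dis[iu])
        & (n_ref[iu] > 3)
        & (n_dis[iu] > 3)
    )
    if pair_mask is not None:
        mask_u = np.asarray(pair_mask, bool)[iu]
        skipped = int((mask_u & ~ok).sum())
        ok &= mask_u
    else:
        skipped = int((~ok).sum())
    if skipped:
        log.info("differential_correlation: skipped %d pairs (undefined r or n <= 3)", skipped)
    ii, jj = iu[0][ok], iu[1][ok]
    # atanh saturates at |r| = 1; clip just inside to keep z finite
    rr = np.clip(r_ref[ii, jj], -1 + 1e-15, 1 - 1e-15)
    rd = np.clip(r_dis[ii, jj], -1 + 1e-15, 1 - 1e-15)
    z_ref = np.arctanh(rr)
    z_dis = np.arctanh(rd)
    se = np.sqrt(1.0 / (n_ref[ii, jj] - 3) + 1.0 / (n_dis[ii, jj] - 3))
    z_stat = (z_ref - z_dis) / se
    p = 2.0 * stats.norm.sf(np.abs(z_stat))
    q = bh_adjust(p)
    ids = np.asarray(list(protein_ids), dtype=object)
    return pd.DataFrame(
        {
            "protein_i": ids[ii],
            "protein_j": ids[jj],
            "r_ref": r_ref[ii, jj],
            "n_ref": n_ref[ii, jj].astype(int),
            "r_dis": r_dis[ii, jj],
            "n_dis": n_dis[ii, jj].astype(int),
            "z_ref": z_ref,
            "z_dis": z_dis,
            "z_statistic": z_stat,
            "p_value": p,
            "p_adjusted": q,
            "significant": q < alpha,
        }
    )
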