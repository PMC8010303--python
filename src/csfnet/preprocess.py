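"""Normalization, missingness filtering and outlier-sample exclusion.

The processing chain mirrors common label-free proteomics practice: work on
natural-log abundances, drop proteins with excessive missingness in any
group, center every sample to the median of a low-variance "background"
protein panel and scale it by the background's median absolute deviation
(raw MAD, no 1.4826 consistency factor), then flag outlying samples by
hierarchical-clustering distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .model import AbundanceMatrix, SampleInfo, metadata_frame

__all__ = [
    "PreprocessReport",
    "log_transform",
    "filter_missing_by_group",
    "select_background",
    "normalize",
    "detect_outlier_samples",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """Record of what preprocessing removed and how samples were rescaled."""

    excluded_proteins: dict[str, dict[str, float]] = field(default_factory=dict)
    excluded_samples: dict[str, float] = field(default_factory=dict)
    background_protein_ids: list[str] = field(default_factory=list)
    centering_offsets: dict[str, float] = field(default_factory=dict)
    scale_factors: dict[str, float] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "excluded_proteins": self.excluded_proteins,
            "excluded_samples": self.excluded_samples,
            "n_background_proteins": len(self.background_protein_ids),
            "background_protein_ids": self.background_protein_ids,
            "centering_offsets": self.centering_offsets,
            "scale_factors": self.scale_factors,
        }


def log_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise natural log of a linear-scale matrix; missingness preserved."""
    if matrix.scale != "linear":
        raise ValueError("log_transform expects a linear-scale matrix")
    obs = matrix.values[~np.isnan(matrix.values)]
    if obs.size and (obs <= 0).any():
        raise ValueError("cannot log-transform non-positive abundances")
    return AbundanceMatrix(
        list(matrix.protein_ids), list(matrix.sample_ids), np.log(matrix.values), scale="log"
    )


def filter_missing_by_group(
    matrix: AbundanceMatrix,
    metadata: Sequence[SampleInfo],
    max_frac: float = 0.5,
) -> tuple[AbundanceMatrix, PreprocessReport]:
    """Remove proteins whose missing fraction is strictly above ``max_frac``
    in at least one group (the ">50% from any group" rule at the default)."""
    meta = metadata_frame(metadata).loc[matrix.sample_ids]
    groups = meta["group"].unique().tolist()
    cols_of = {g: np.flatnonzero((meta["group"] == g).to_numpy()) for g in groups}
    for g, cols in cols_of.items():
        if cols.size == 0:
            raise ValueError(f"group {g!r} has zero samples")
    miss = matrix.missing_mask
    report = PreprocessReport()
    keep: list[str] = []
    for i, pid in enumerate(matrix.protein_ids):
        fracs = {g: float(miss[i, cols].mean()) for g, cols in cols_of.items()}
        if max(fracs.values()) > max_frac:
            report.excluded_proteins[pid] = fracs
        else:
            keep.append(pid)
    if report.excluded_proteins:
        log.info(
            "filter_missing_by_group: removed %d/%d proteins (> %.0f%% missing in a group)",
            len(report.excluded_proteins), matrix.n_proteins, 100 * max_frac,
        )
    return matrix.subset_proteins(keep), report


def select_background(matrix: AbundanceMatrix, frac: float = 0.9) -> list[str]:
    """The ``floor(frac * P)`` proteins with the lowest variance of observed
    values across samples; ties at the cutoff break lexicographically.
    Proteins with fewer than two observed values never enter the background."""
    if matrix.n_proteins < 2:
        raise ValueError("need at least 2 proteins to select a background")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to compute variances")
    variances = []
    for i, pid in enumerate(matrix.protein_ids):
        row = matrix.values[i]
        obs = row[~np.isnan(row)]
        v = float(np.var(obs, ddof=1)) if obs.size >= 2 else np.inf
        variances.append((v, pid))
    variances.sort(key=lambda t: (t[0], t[1]))
    k = int(np.floor(frac * matrix.n_proteins))
    return [pid for _v, pid in variances[:k]]


def normalize(
    matrix: AbundanceMatrix,
    background: Sequence[str],
    scale_axis: str = "sample",
) -> tuple[AbundanceMatrix, PreprocessReport]:
    """Center each sample to its background median and scale by background MAD.

    After the transform every sample's observed background values have
    median exactly 0 and MAD exactly 1.  ``scale_axis="protein"`` instead
    divides each protein row by its own MAD after the per-sample centering
    (the alternative reading of a per-axis MAD rescale).
    """
    if matrix.scale != "log":
        raise ValueError("normalize expects log-scale values")
    bg = set(background)
    unknown = bg - set(matrix.protein_ids)
    if unknown:
        raise ValueError(f"background proteins not in matrix: {sorted(unknown)[:5]}")
    if scale_axis not in ("sample", "protein"):
        raise ValueError(f"unknown scale_axis {scale_axis!r}")
    bg_rows = np.array([p in bg for p in matrix.protein_ids])
    values = matrix.values.copy()
    report = PreprocessReport(background_protein_ids=sorted(bg))
    for j, sid in enumerate(matrix.sample_ids):
        col = values[bg_rows, j]
        obs = col[~np.isnan(col)]
        if obs.size < 3:
            raise ValueError(f"sample {sid!r} has fewer than 3 observed background values")
        med = float(np.median(obs))
        mad = float(np.median(np.abs(obs - med)))
        if scale_axis == "sample" and mad == 0:
            raise ValueError(f"sample {sid!r} has zero background MAD")
        values[:, j] -= med
        if scale_axis == "sample":
            values[:, j] /= mad
        report.centering_offsets[sid] = med
        report.scale_factors[sid] = mad if scale_axis == "sample" else 1.0
    if scale_axis == "protein":
        for i, pid in enumerate(matrix.protein_ids):
            row = values[i]
            obs = row[~np.isnan(row)]
            med = float(np.median(obs))
            mad = float(np.median(np.abs(obs - med)))
            if mad == 0:
                raise ValueError(f"protein {pid!r} has zero MAD")
            values[i] /= mad
    out = AbundanceMatrix(list(matrix.protein_ids), list(matrix.sample_ids), values, scale="log")
    return out, report


def _pairwise_sample_distance(values: np.ndarray) -> np.ndarray:
    """Root-mean-square difference over shared-observed proteins for each
    sample pair (missingness-robust Euclidean analogue)."""
    P, S = values.shape
    mask = ~np.isnan(values)
    X0 = np.where(mask, values, 0.0)
    M = mask.astype(float)
    shared = M.T @ M  # samples x samples
    sq = X0**2
    cross = X0.T @ X0
    a2 = sq.T @ M  # sum of x_j^2 over shared with k -> [j,k]
    d2 = a2 + a2.T - 2 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = np.where(shared > 0, d2 / shared, np.nan)
    msd = np.clip(msd, 0, None)
    return np.sqrt(msd)


def detect_outlier_samples(
    matrix: AbundanceMatrix,
    linkage_method: str = "average",
    z_cut: float = 3.0,
) -> tuple[set[str], PreprocessReport]:
    """Flag samples whose mean distance to all other samples is an outlier.

    Samples are clustered hierarchically (``linkage_method``) on the
    missingness-robust Euclidean distance; a sample is flagged iff the
    robust z-score of its mean distance to the others exceeds ``z_cut``.
    The z-score is median-centered with scale ``max(1.4826 * MAD, SD)``:
    the MAD term resists masking by genuine outliers, while the SD floor
    keeps the scale estimate from collapsing on small sample counts (a raw
    MAD over a few dozen samples is noisy enough to flag several percent of
    clean samples per run).  The dendrogram drives the report only; the
    decision rule is the distance criterion, which is what a reader of the
    cluster tree applies by eye.
    """
    if matrix.n_samples < 4:
        raise ValueError("need at least 4 samples for outlier detection")
    D = _pairwise_sample_distance(matrix.values)
    np.fill_diagonal(D, 0.0)
    if np.isnan(D).any():
        raise ValueError("sample pairs with no shared observed proteins")
    # cluster for the record (hierarchical clustering is the method of note)
    linkage(squareform(D, checks=False), method=linkage_method)
    S = matrix.n_samples
    mean_dist = D.sum(axis=1) / (S - 1)
    med = np.median(mean_dist)
    mad = np.median(np.abs(mean_dist - med))
    scale = max(1.4826 * mad, float(np.std(mean_dist, ddof=1)))
    if scale == 0:
        robust_z = np.zeros(S)
    else:
        robust_z = (mean_dist - med) / scale
    flagged = {sid for sid, z in zip(matrix.sample_ids, robust_z) if z > z_cut}
    report = PreprocessReport(
        excluded_samples={sid: float(z) for sid, z in zip(matrix.sample_ids, robust_z) if z > z_cut}
    )
    if flagged:
        log.info("detect_outlier_samples: flagged %s at z > %.2f", sorted(flagged), z_cut)
    return flagged, report
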