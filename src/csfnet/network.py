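"""Signed weighted correlation network: modules, eigenproteins, hubs, stability.

The network is built from pairwise-complete Pearson correlations mapped
through the signed soft-threshold ``a_ij = ((1 + r_ij)/2)^beta``.  Modules
are branches of an average-linkage dendrogram on the chosen dissimilarity
(1 - adjacency by default, topological overlap optionally), cut adaptively
and then merged whenever two module eigenproteins are closer than the merge
cut height.  An eigenprotein is the first principal component of a module's
standardized member profiles, oriented to correlate positively with the
module mean.  Intramodular connectivity ``kin`` is a protein's summed
adjacency to its own module; the top decile per module are hub proteins.
Module stability is the per-protein rate of consistent assignment under
leave-one-sample-out network reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .model import AbundanceMatrix

__all__ = [
    "NetworkConfig",
    "NetworkResult",
    "pairwise_correlation",
    "signed_adjacency",
    "dissimilarity",
    "detect_modules",
    "compute_eigenproteins",
    "intramodular_connectivity",
    "module_stability",
    "build_network",
    "edge_list",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkConfig:
    """Knobs of network construction; defaults follow the motivating study
    (power 7, signed, minimum module size 5, merge cut height 0.05)."""

    beta: float = 7.0
    network_sign: str = "signed"
    dissimilarity_mode: str = "adjacency"
    linkage_method: str = "average"
    min_module_size: int = 5
    merge_cut_height: float = 0.05
    min_pairwise_n: int = 10
    cut_mode: str = "adaptive"
    cut_fraction: float = 0.95
    static_cut_height: float | None = None

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must lie in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.network_sign not in ("signed", "unsigned"):
            raise ValueError("network_sign must be 'signed' or 'unsigned'")
        if self.dissimilarity_mode not in ("adjacency", "tom"):
            raise ValueError("dissimilarity_mode must be 'adjacency' or 'tom'")
        if self.cut_mode not in ("adaptive", "static"):
            raise ValueError("cut_mode must be 'adaptive' or 'static'")


@dataclass
class NetworkResult:
    """Everything the downstream stages need from one network build."""

    protein_ids: list[str]
    correlation: np.ndarray
    pair_counts: np.ndarray
    adjacency: np.ndarray
    dissim: np.ndarray
    dendrogram: np.ndarray
    module_assignment: np.ndarray  # 1..M by decreasing size, 0 = unassigned
    eigenproteins: np.ndarray  # modules x samples
    sample_ids: list[str]
    variance_explained: np.ndarray
    kin: np.ndarray
    hub: np.ndarray
    stability: np.ndarray | None = None
    config: NetworkConfig = field(default_factory=NetworkConfig)

    @property
    def n_modules(self) -> int:
        return int(self.module_assignment.max(initial=0))

    def module_members(self, m: int) -> list[str]:
        return [p for p, a in zip(self.protein_ids, self.module_assignment) if a == m]


# ---------------------------------------------------------------------------
# correlation / adjacency / dissimilarity
# ---------------------------------------------------------------------------

def pairwise_correlation(
    matrix: AbundanceMatrix | np.ndarray,
    min_pairwise_n: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson correlation between protein rows.

    Returns ``(r, n)`` where ``n_ij`` counts samples with both proteins
    observed.  Entries with fewer than ``min_pairwise_n`` complete pairs, or
    with zero variance on the shared samples, are NaN (undefined); the
    adjacency step maps them to r = 0 with a logged warning.
    """
    values = matrix.values if isinstance(matrix, AbundanceMatrix) else np.asarray(matrix, float)
    mask = ~np.isnan(values)
    X0 = np.where(mask, values, 0.0)
    M = mask.astype(float)
    n = M @ M.T
    sx = X0 @ M.T
    sxx = (X0**2) @ M.T
    sxy = X0 @ X0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx**2 / n
        denom = np.sqrt(varx * varx.T)
        r = cov / denom
    r = np.clip(r, -1.0, 1.0)
    undefined = (n < min_pairwise_n) | ~np.isfinite(r)
    np.fill_diagonal(undefined, False)
    r[undefined] = np.nan
    np.fill_diagonal(r, 1.0)
    n_undef = int(np.triu(undefined, 1).sum())
    if n_undef:
        log.warning(
            "pairwise_correlation: %d pairs undefined (n < %d or zero variance)",
            n_undef, min_pairwise_n,
        )
    return r, n.astype(int)


def signed_adjacency(r: np.ndarray, beta: float = 7.0, sign: str = "signed") -> np.ndarray:
    """Soft-threshold adjacency: ``((1+r)/2)^beta`` signed, ``|r|^beta`` unsigned.

    Undefined correlations (NaN) enter as r = 0, a neutral weight.
    """
    r = np.asarray(r, dtype=float)
    n_undef = int(np.isnan(np.triu(r, 1)).sum())
    if n_undef:
        log.warning("signed_adjacency: %d undefined correlations treated as r = 0", n_undef)
    r = np.where(np.isnan(r), 0.0, r)
    if sign == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    elif sign == "unsigned":
        a = np.abs(r) ** beta
    else:
        raise ValueError(f"unknown sign {sign!r}")
    np.fill_diagonal(a, 1.0)
    return a


def dissimilarity(adjacency: np.ndarray, mode: str = "adjacency") -> np.ndarray:
    """``1 - a`` or ``1 - TOM(a)`` (topological overlap)."""
    a = np.asarray(adjacency, dtype=float)
    if mode == "adjacency":
        d = 1.0 - a
    elif mode == "tom":
        a0 = a.copy()
        np.fill_diagonal(a0, 0.0)
        k = a0.sum(axis=1)
        shared = a0 @ a0
        kmin = np.minimum.outer(k, k)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (shared + a0) / (kmin + 1.0 - a0)
        t = np.where(np.isfinite(t), t, 0.0)
        np.fill_diagonal(t, 1.0)
        d = 1.0 - t
    else:
        raise ValueError(f"unknown dissimilarity mode {mode!r}")
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def _relabel_by_size(assignment: np.ndarray) -> np.ndarray:
    """Renumber modules 1..M by decreasing size (ties: first protein index)."""
    out = np.zeros_like(assignment)
    labels = [m for m in np.unique(assignment) if m != 0]
    order = sorted(
        labels,
        key=lambda m: (-(assignment == m).sum(), int(np.argmax(assignment == m))),
    )
    for new, old in enumerate(order, start=1):
        out[assignment == old] = new
    return out


def detect_modules(
    d: np.ndarray,
    min_module_size: int,
    merge_cut_height: float,
    matrix: AbundanceMatrix | np.ndarray,
    linkage_method: str = "average",
    cut_mode: str = "adaptive",
    cut_fraction: float = 0.95,
    static_cut_height: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster the dissimilarity matrix into modules.

    Average-linkage clustering; the tree is cut either adaptively at
    ``cut_fraction`` of the maximum merge height (scales with the data's own
    dissimilarity range, so near-random proteins stay unassigned) or at an
    absolute ``static_cut_height``.  Branches smaller than
    ``min_module_size`` are unassigned (label 0).  Modules whose
    eigenproteins are closer than ``merge_cut_height`` (1 - Pearson r) are
    merged iteratively, then labels are renumbered 1..M by decreasing size.

    Returns ``(dendrogram, module_assignment)``.
    """
    d = np.asarray(d, dtype=float)
    P = d.shape[0]
    values = matrix.values if isinstance(matrix, AbundanceMatrix) else np.asarray(matrix, float)
    if P < 2 or P < min_module_size:
        return np.empty((0, 4)), np.zeros(P, dtype=int)
    Z = linkage(squareform(d, checks=False), method=linkage_method)
    if cut_mode == "static":
        if static_cut_height is None:
            raise ValueError("static cut requires static_cut_height")
        height = static_cut_height
    else:
        height = cut_fraction * float(Z[:, 2].max())
    raw = fcluster(Z, t=height, criterion="distance")
    assignment = raw.astype(int)
    for label in np.unique(assignment):
        if (assignment == label).sum() < min_module_size:
            assignment[assignment == label] = 0

    # iterative eigenprotein merge
    while True:
        labels = [m for m in np.unique(assignment) if m != 0]
        if len(labels) < 2:
            break
        eig, _ = compute_eigenproteins(values, assignment, labels=labels)
        c = np.corrcoef(eig)
        np.fill_diagonal(c, -np.inf)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if 1.0 - c[i, j] < merge_cut_height:
            assignment[assignment == labels[j]] = labels[i]
        else:
            break

    return Z, _relabel_by_size(assignment)


# ---------------------------------------------------------------------------
# eigenproteins
# ---------------------------------------------------------------------------

def _standardize_rows(values: np.ndarray) -> np.ndarray:
    """Median-impute missing entries, then scale rows to mean 0 / sd 1 (ddof=1)."""
    X = values.copy()
    for i in range(X.shape[0]):
        row = X[i]
        nan = np.isnan(row)
        if nan.any():
            med = np.nanmedian(row)
            row[nan] = med
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant protein profile in module")
    return (X - mean) / sd


def compute_eigenproteins(
    matrix: AbundanceMatrix | np.ndarray,
    module_assignment: np.ndarray,
    labels: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """First-PC summary per module.

    Member proteins are median-imputed and standardized; the eigenprotein is
    the first principal-component score vector scaled to unit variance
    (ddof=1), with sign chosen so it correlates non-negatively with the
    module's mean standardized profile.  Also returns the fraction of
    variance explained by the first component.
    """
    values = matrix.values if isinstance(matrix, AbundanceMatrix) else np.asarray(matrix, float)
    module_assignment = np.asarray(module_assignment)
    if labels is None:
        labels = [m for m in np.unique(module_assignment) if m != 0]
    S = values.shape[1]
    eig = np.zeros((len(labels), S))
    var_expl = np.zeros(len(labels))
    for k, m in enumerate(labels):
        rows = np.flatnonzero(module_assignment == m)
        if rows.size < 2:
            raise ValueError(f"module {m} has fewer than 2 proteins")
        X = _standardize_rows(values[rows])  # members x samples
        # PCA across proteins: SVD of the samples x members matrix
        U, s, _ = np.linalg.svd(X.T, full_matrices=False)
        scores = U[:, 0] * s[0]
        sd = scores.std(ddof=1)
        if sd == 0:
            raise ValueError(f"module {m}: degenerate first component")
        e = (scores - scores.mean()) / sd
        mean_profile = X.mean(axis=0)
        if np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
        eig[k] = e
        var_expl[k] = s[0] ** 2 / (s**2).sum()
    return eig, var_expl


# ---------------------------------------------------------------------------
# connectivity and hubs
# ---------------------------------------------------------------------------

def intramodular_connectivity(
    adjacency: np.ndarray,
    module_assignment: np.ndarray,
    protein_ids: Sequence[str] | None = None,
    hub_frac: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Summed within-module adjacency and hub flags.

    ``kin_i`` sums a protein's adjacency to same-module partners (0 for
    unassigned proteins).  Per module the ``ceil(hub_frac * size)`` proteins
    with the largest kin are hubs; ties at the cutoff break by protein id.
    """
    a = np.asarray(adjacency, dtype=float)
    module_assignment = np.asarray(module_assignment)
    P = a.shape[0]
    ids = list(protein_ids) if protein_ids is not None else [f"{i}" for i in range(P)]
    kin = np.zeros(P)
    hub = np.zeros(P, dtype=bool)
    for m in np.unique(module_assignment):
        if m == 0:
            continue
        rows = np.flatnonzero(module_assignment == m)
        sub = a[np.ix_(rows, rows)]
        k = sub.sum(axis=1) - np.diag(sub)
        kin[rows] = k
        n_hub = int(np.ceil(hub_frac * rows.size))
        order = sorted(range(rows.size), key=lambda t: (-k[t], ids[rows[t]]))
        hub[rows[order[:n_hub]]] = True
    return kin, hub


# ---------------------------------------------------------------------------
# full build + stability
# ---------------------------------------------------------------------------

def build_network(
    matrix: AbundanceMatrix,
    config: NetworkConfig = NetworkConfig(),
    stability_iterations: int = 0,
    seed: int | None = None,
) -> NetworkResult:
    """Run the whole network stage on one matrix."""
    r, n = pairwise_correlation(matrix, config.min_pairwise_n)
    a = signed_adjacency(r, config.beta, config.network_sign)
    d = dissimilarity(a, config.dissimilarity_mode)
    Z, assignment = detect_modules(
        d,
        config.min_module_size,
        config.merge_cut_height,
        matrix,
        linkage_method=config.linkage_method,
        cut_mode=config.cut_mode,
        cut_fraction=config.cut_fraction,
        static_cut_height=config.static_cut_height,
    )
    labels = [m for m in np.unique(assignment) if m != 0]
    if labels:
        eig, var_expl = compute_eigenproteins(matrix, assignment, labels=labels)
    else:
        eig, var_expl = np.zeros((0, matrix.n_samples)), np.zeros(0)
    kin, hub = intramodular_connectivity(a, assignment, matrix.protein_ids)
    result = NetworkResult(
        protein_ids=list(matrix.protein_ids),
        correlation=r,
        pair_counts=n,
        adjacency=a,
        dissim=d,
        dendrogram=Z,
        module_assignment=assignment,
        eigenproteins=eig,
        sample_ids=list(matrix.sample_ids),
        variance_explained=var_expl,
        kin=kin,
        hub=hub,
        config=config,
    )
    if stability_iterations > 0:
        result.stability = module_stability(
            matrix, config, n_iter=stability_iterations, seed=seed or 0, reference=result
        )
    return result


def _greedy_jaccard_match(ref: np.ndarray, other: np.ndarray) -> dict[int, int]:
    """Map labels of ``other`` onto labels of ``ref`` by greedy maximum
    Jaccard overlap; unmatched labels are absent from the result."""
    ref_labels = [m for m in np.unique(ref) if m != 0]
    other_labels = [m for m in np.unique(other) if m != 0]
    scores = []
    for rm in ref_labels:
        rset = ref == rm
        for om in other_labels:
            oset = other == om
            inter = np.logical_and(rset, oset).sum()
            union = np.logical_or(rset, oset).sum()
            if union:
                scores.append((inter / union, rm, om))
    scores.sort(key=lambda t: (-t[0], t[1], t[2]))
    mapping: dict[int, int] = {}
    used_ref: set[int] = set()
    for jac, rm, om in scores:
        if jac <= 0 or om in mapping or rm in used_ref:
            continue
        mapping[om] = rm
        used_ref.add(rm)
    return mapping


def module_stability(
    matrix: AbundanceMatrix,
    config: NetworkConfig,
    n_iter: int,
    seed: int = 0,
    reference: NetworkResult | None = None,
) -> np.ndarray:
    """Leave-one-sample-out assignment stability per protein.

    Each iteration drops one uniformly chosen sample, rebuilds the network
    with the same configuration, matches iteration modules to the reference
    modules by greedy maximum-Jaccard label matching, and records whether
    each protein keeps its reference label (unassigned counts as a label).
    Returns the per-protein fraction of concordant iterations.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if matrix.n_samples < 5:
        raise ValueError("need at least 5 samples for leave-one-out stability")
    if reference is None:
        reference = build_network(matrix, config)
    ref = reference.module_assignment
    rng = np.random.default_rng(seed)
    hits = np.zeros(matrix.n_proteins)
    for _ in range(n_iter):
        drop = int(rng.integers(matrix.n_samples))
        keep = [s for j, s in enumerate(matrix.sample_ids) if j != drop]
        sub = matrix.subset_samples(keep)
        res = build_network(sub, config)
        mapping = _greedy_jaccard_match(ref, res.module_assignment)
        mapped = np.array([mapping.get(m, -1) if m != 0 else 0 for m in res.module_assignment])
        hits += mapped == ref
    return hits / n_iter


def edge_list(
    result: NetworkResult,
    min_abs_r: float = 0.0,
) -> list[tuple[str, str, float, float]]:
    """Flat (protein_a, protein_b, r, adjacency) tuples for export,
    filtered to ``|r| >= min_abs_r``; NaN correlations are skipped."""
    out = []
    P = len(result.protein_ids)
    for i in range(P):
        for j in range(i + 1, P):
            r = result.correlation[i, j]
            if np.isnan(r) or abs(r) < min_abs_r:
                continue
            out.append(
                (result.protein_ids[i], result.protein_ids[j], float(r), float(result.adjacency[i, j]))
            )
    return out
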