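"""Per-protein random-intercept mixed-model screening of longitudinal drift.

For each protein the model is

    y_it = beta0 + b_i + beta1 * t_it + eps_it,
    b_i ~ N(0, sigma_b^2),  eps_it ~ N(0, sigma^2),  b _|_ eps,

fitted by restricted maximum likelihood on subjects with at least two
visits, with time anchored at each subject's first visit.  Because the
model has a single variance ratio theta = sigma_b^2 / sigma^2, REML reduces
to a one-dimensional profiled optimization with closed-form GLS estimates
at each theta; the boundary cases theta = 0 (no subject effect) and
sigma^2 -> 0 (noise-free trajectories) are handled exactly.  The slope's
denominator degrees of freedom follow the inner-outer rule for a
within-subject covariate: df = n_obs - n_subjects - 1.

Screening fits every protein with sufficient longitudinal coverage,
adjusts p-values by Benjamini-Hochberg and labels directions at the chosen
FDR level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .model import AbundanceMatrix, SampleInfo, metadata_frame
from .differential import bh_adjust

__all__ = ["LmmFit", "LongitudinalRecord", "fit_lmm", "longitudinal_screen"]

log = logging.getLogger(__name__)

_THETA_MAX = 1e8


@dataclass(frozen=True)
class LmmFit:
    protein_id: str
    n_obs: int
    n_subjects: int
    intercept: float
    slope: float
    slope_se: float
    sigma_b2: float
    sigma2: float
    df: int
    t_statistic: float
    p_value: float


@dataclass(frozen=True)
class LongitudinalRecord:
    fit: LmmFit
    p_adjusted: float
    direction: str  # increasing / decreasing / null


def _group_blocks(subjects: Sequence) -> list[np.ndarray]:
    order: dict = {}
    for idx, s in enumerate(subjects):
        order.setdefault(s, []).append(idx)
    return [np.array(v) for v in order.values()]


def _profile(theta: float, y: np.ndarray, X: np.ndarray, blocks: list[np.ndarray]):
    """GLS estimates and REML pieces at a fixed variance ratio theta.

    V = sigma^2 (I + theta * Z Z'); per-subject inverse is
    (I - c J) with c = theta / (1 + n_i theta), and
    log|I + theta J| = log(1 + n_i theta).
    """
    p = X.shape[1]
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    logdet_v = 0.0
    for idx in blocks:
        Xi, yi = X[idx], y[idx]
        ni = len(idx)
        c = theta / (1.0 + ni * theta)
        sx, sy = Xi.sum(axis=0), yi.sum()
        XtWX += Xi.T @ Xi - c * np.outer(sx, sx)
        XtWy += Xi.T @ yi - c * sx * sy
        logdet_v += np.log1p(ni * theta)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = 0.0
    for idx in blocks:
        resid = y[idx] - X[idx] @ beta
        ni = len(idx)
        c = theta / (1.0 + ni * theta)
        rss += resid @ resid - c * resid.sum() ** 2
    rss = max(rss, 0.0)
    return beta, XtWX, rss, logdet_v


def _reml_criterion(theta: float, y: np.ndarray, X: np.ndarray, blocks: list[np.ndarray]) -> float:
    n, p = X.shape
    _beta, XtWX, rss, logdet_v = _profile(theta, y, X, blocks)
    sign, logdet_x = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    # -2 restricted log-likelihood, profiled over sigma^2 (constants dropped)
    return (n - p) * np.log(max(rss, 1e-300)) + logdet_v + logdet_x


def reml_loglik(
    y: np.ndarray, X: np.ndarray, subjects: Sequence, sigma_b2: float, sigma2: float
) -> float:
    """Unprofiled restricted log-likelihood at explicit variance components
    (used by local-optimality checks)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    blocks = _group_blocks(subjects)
    n, p = X.shape
    theta = sigma_b2 / sigma2
    _beta, XtWX, rss, logdet_v = _profile(theta, y, X, blocks)
    _sign, logdet_x = np.linalg.slogdet(XtWX)
    # log|V| = n log sigma^2 + sum log(1 + n_i theta);
    # log|X'V^-1X| = logdet_x - p log sigma^2
    return -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + (n - p) * np.log(sigma2)
        + logdet_v
        + logdet_x
        + rss / sigma2
    )


def fit_lmm(
    values: Sequence[float],
    times: Sequence[float],
    subjects: Sequence,
    protein_id: str = "",
) -> LmmFit:
    """REML fit of the random-intercept, fixed-slope model.

    ``values`` are log abundances, ``times`` months from each subject's
    baseline, ``subjects`` the grouping labels.  Subjects must number at
    least two and each must contribute at least two observations; time must
    vary within subjects (otherwise the slope is confounded with the random
    intercepts).
    """
    y = np.asarray(values, float)
    t = np.asarray(times, float)
    subjects = list(subjects)
    if y.shape != t.shape or len(subjects) != y.size:
        raise ValueError("values, times and subjects must have equal length")
    obs = ~np.isnan(y)
    y, t = y[obs], t[obs]
    subjects = [s for s, o in zip(subjects, obs) if o]
    blocks = _group_blocks(subjects)
    blocks = [b for b in blocks if len(b) >= 2]
    keep = np.concatenate(blocks) if blocks else np.array([], dtype=int)
    if len(blocks) < 2:
        raise ValueError("need >= 2 subjects with >= 2 observations each")
    y, t = y[keep], t[keep]
    pos = 0
    new_blocks = []
    for b in blocks:
        new_blocks.append(np.arange(pos, pos + len(b)))
        pos += len(b)
    blocks = new_blocks
    n = y.size
    n_subjects = len(blocks)
    within_var = sum(float(np.var(t[b])) for b in blocks)
    if within_var == 0:
        raise ValueError("time does not vary within subjects; slope not identifiable")
    X = np.column_stack([np.ones(n), t])

    # theta = expm1(u) maps u in [0, 25] onto [0, ~7e10] with resolution near 0
    res = optimize.minimize_scalar(
        lambda u: _reml_criterion(float(np.expm1(u)), y, X, blocks),
        bounds=(0.0, 25.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    theta = float(np.expm1(res.x))
    if _reml_criterion(0.0, y, X, blocks) <= _reml_criterion(theta, y, X, blocks):
        theta = 0.0
    beta, XtWX, rss, _ = _profile(theta, y, X, blocks)
    sigma2 = rss / (n - 2)
    sigma_b2 = theta * sigma2
    cov = np.linalg.inv(XtWX) * sigma2
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    df = n - n_subjects - 1
    if se == 0.0:
        tstat = np.inf if beta[1] > 0 else (-np.inf if beta[1] < 0 else 0.0)
        p = 0.0 if beta[1] != 0 else 1.0
    else:
        tstat = float(beta[1] / se)
        p = float(2.0 * stats.t.sf(abs(tstat), df))
    return LmmFit(
        protein_id=protein_id,
        n_obs=int(n),
        n_subjects=int(n_subjects),
        intercept=float(beta[0]),
        slope=float(beta[1]),
        slope_se=se,
        sigma_b2=float(sigma_b2),
        sigma2=float(sigma2),
        df=int(df),
        t_statistic=tstat,
        p_value=p,
    )


def longitudinal_screen(
    matrix: AbundanceMatrix,
    metadata: Sequence[SampleInfo],
    alpha: float = 0.1,
    min_subjects: int = 5,
    group: str | None = None,
) -> list[LongitudinalRecord]:
    """Fit every protein on the repeated-measures subjects and BH-screen.

    Only subjects with >= 2 visits enter (optionally restricted to one
    ``group``); a protein needs at least ``min_subjects`` such subjects with
    >= 2 observed values to be fitted, otherwise it is skipped with a
    logged count.  Directions are labeled at BH-adjusted p < ``alpha``.
    """
    if matrix.scale != "log":
        raise ValueError("longitudinal_screen expects a log-scale matrix")
    meta = metadata_frame(metadata)
    meta = meta.loc[[s for s in matrix.sample_ids if s in meta.index]]
    if group is not None:
        meta = meta[meta["group"] == group]
    visits_per_subject = meta.groupby("subject_id")["visit"].count()
    keep_subjects = set(visits_per_subject[visits_per_subject >= 2].index)
    meta = meta[meta["subject_id"].isin(keep_subjects)]
    if meta.empty:
        raise ValueError("no subjects with repeated measures")
    sample_ids = list(meta["sample_id"])
    sub = matrix.subset_samples(sample_ids)
    times = meta["months_from_baseline"].to_numpy(float)
    subjects = meta["subject_id"].to_list()

    fits: list[LmmFit] = []
    skipped = 0
    for i, pid in enumerate(sub.protein_ids):
        row = sub.values[i]
        obs = ~np.isnan(row)
        counts: dict[str, int] = {}
        for s, o in zip(subjects, obs):
            if o:
                counts[s] = counts.get(s, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) < min_subjects:
            skipped += 1
            continue
        try:
            fits.append(fit_lmm(row, times, subjects, protein_id=pid))
        except (ValueError, np.linalg.LinAlgError):
            skipped += 1
    if skipped:
        log.info("longitudinal_screen: skipped %d proteins with insufficient coverage", skipped)
    if not fits:
        raise ValueError("no protein could be fitted")
    q = bh_adjust([f.p_value for f in fits])
    records = []
    for f, qv in zip(fits, q):
        if qv < alpha and f.slope > 0:
            direction = "increasing"
        elif qv < alpha and f.slope < 0:
            direction = "decreasing"
        else:
            direction = "null"
        records.append(LongitudinalRecord(fit=f, p_adjusted=float(qv), direction=direction))
    return records
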