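"""Recovery metrics on synthetic data with planted ground truth.

These helpers run the actual pipeline machinery on generated datasets and
score the result against the planted truth: module recovery (adjusted Rand
index, eigenprotein-factor correlation), differential-correlation ranking
and calibration, and mixed-model parameter recovery.  They back both the
test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .differential import differential_correlation_table, group_correlation_profiles
from .longitudinal import fit_lmm, longitudinal_screen
from .network import NetworkConfig, _greedy_jaccard_match, build_network
from .preprocess import (
    detect_outlier_samples,
    filter_missing_by_group,
    log_transform,
    normalize,
    select_background,
)
from .synthetic import SyntheticTruth, default_study_fixture

__all__ = [
    "adjusted_rand_index",
    "prepare_study_fixture",
    "module_recovery_metrics",
    "diffcorr_fixture_metrics",
    "diffcorr_null_type1",
    "lmm_parameter_recovery",
    "longitudinal_fixture_metrics",
]


def adjusted_rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index between two partitions (pair-counting form)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((ua.size, ub.size), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)

    def comb2(x):
        return x * (x - 1) // 2

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    n = comb2(a.size)
    expected = sum_a * sum_b / n
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def prepare_study_fixture(seed: int, mad_normalize: bool = False):
    """Generate the study-shaped fixture and run preprocessing.

    Returns ``(full_matrix, full_metadata, baseline_matrix,
    baseline_metadata, truth)`` after log transform, per-group missingness
    filtering and outlier-sample exclusion.  Outliers are always detected on
    the MAD-normalized matrix; the returned values are MAD-normalized only
    when ``mad_normalize`` is set (module-recovery scoring runs on plain log
    abundances, where the planted factor structure is untouched by
    per-sample rescaling).
    """
    matrix, metadata, truth = default_study_fixture(seed=seed)
    matrix = log_transform(matrix)
    matrix, _ = filter_missing_by_group(matrix, metadata)
    normalized, _ = normalize(matrix, select_background(matrix))
    flagged, _ = detect_outlier_samples(normalized)
    chosen = normalized if mad_normalize else matrix
    keep = [s for s in chosen.sample_ids if s not in flagged]
    full = chosen.subset_samples(keep)
    full_meta = [r for r in metadata if r.sample_id in set(keep)]
    baseline_ids = [r.sample_id for r in full_meta if r.visit == 1]
    baseline = full.subset_samples(baseline_ids)
    baseline_meta = [r for r in full_meta if r.visit == 1]
    return full, full_meta, baseline, baseline_meta, truth


def _factor_columns(truth: SyntheticTruth, sample_ids) -> list[int]:
    order = {r.sample_id: k for k, r in enumerate(truth.sample_records)}
    return [order[s] for s in sample_ids]


def module_recovery_metrics(seed: int, config: NetworkConfig = NetworkConfig()) -> dict:
    """ARI of detected vs planted modules and the weakest eigenprotein-factor
    correlation, on the study fixture's baseline log abundances."""
    _full, _fm, baseline, _bm, truth = prepare_study_fixture(seed)
    net = build_network(baseline, config)
    planted = truth.assignment_vector(net.protein_ids)
    ari = adjusted_rand_index(planted, net.module_assignment)
    mapping = _greedy_jaccard_match(planted, net.module_assignment)
    cols = _factor_columns(truth, baseline.sample_ids)
    cors = []
    for det_label, planted_label in mapping.items():
        e = net.eigenproteins[det_label - 1]
        f = truth.factors[planted_label - 1, cols]
        cors.append(abs(float(np.corrcoef(e, f)[0, 1])))
    return {
        "ari": float(ari),
        "n_matched_modules": len(mapping),
        "min_factor_cor": min(cors) if cors else np.nan,
        "median_factor_cor": float(np.median(cors)) if cors else np.nan,
    }


def diffcorr_fixture_metrics(
    seed: int,
    reference_group: str = "HC",
    disease_group: str = "ALS",
    top_frac: float = 0.01,
) -> dict:
    """Rank of planted decorrelated pairs among within-module |Z| values.

    Builds the network on baseline samples, computes the full differential
    correlation table between disease and reference, and reports the
    fraction of planted pairs inside the top ``top_frac`` of within-module
    pairs, plus whether the most-enriched module for the significant
    foreground hosts planted pairs.
    """
    from .enrichment import hypergeometric_enrichment

    _full, _fm, baseline, bmeta, truth = prepare_study_fixture(seed)
    net = build_network(baseline)
    r_ref, n_ref = group_correlation_profiles(baseline, bmeta, reference_group)
    r_dis, n_dis = group_correlation_profiles(baseline, bmeta, disease_group)
    table = differential_correlation_table(r_ref, n_ref, r_dis, n_dis, baseline.protein_ids)
    modules = dict(zip(net.protein_ids, net.module_assignment))
    ma = table["protein_i"].map(modules).to_numpy()
    mb = table["protein_j"].map(modules).to_numpy()
    within = table[(ma == mb) & (ma > 0)].copy()
    abs_z = within["z_statistic"].abs()
    k = max(1, int(np.ceil(top_frac * len(within))))
    threshold = abs_z.nlargest(k).iloc[-1]
    scores = {
        tuple(sorted((a, b))): z
        for a, b, z in zip(within["protein_i"], within["protein_j"], abs_z)
    }
    planted = {tuple(sorted(p[:2])) for p in truth.decorrelated_pairs}
    in_top = sum(1 for p in planted if scores.get(p, -np.inf) >= threshold)

    sig = table[table["significant"]]
    foreground = (set(sig["protein_i"]) | set(sig["protein_j"])) & set(net.protein_ids)
    planted_modules = {truth.module_assignment[p[0]] for p in truth.decorrelated_pairs}
    top_is_planted = False
    if foreground:
        module_sets = {m: set(net.module_members(m)) for m in range(1, net.n_modules + 1)}
        recs = hypergeometric_enrichment(foreground, set(net.protein_ids), module_sets)
        best = min(recs, key=lambda r: r.p_value)
        mapping = _greedy_jaccard_match(
            truth.assignment_vector(net.protein_ids), net.module_assignment
        )
        top_is_planted = mapping.get(int(best.set_id), -1) in planted_modules
    return {
        "top_fraction": in_top / len(planted),
        "n_significant_pairs": int(len(sig)),
        "n_foreground": len(foreground),
        "top_enriched_module_is_planted": bool(top_is_planted),
    }


def diffcorr_null_type1(
    seed: int,
    n_pairs: int = 2000,
    n_ref: int = 50,
    n_dis: int = 50,
    rho: float = 0.5,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the Fisher r-to-z test on independent null pairs
    (both groups share the same true correlation)."""
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    rejections = 0
    for _ in range(n_pairs):
        x = (chol @ rng.normal(size=(2, n_ref)))
        y = (chol @ rng.normal(size=(2, n_dis)))
        r1 = np.corrcoef(x)[0, 1]
        r2 = np.corrcoef(y)[0, 1]
        z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n_ref - 3) + 1 / (n_dis - 3))
        if 2 * stats.norm.sf(abs(z)) < alpha:
            rejections += 1
    return rejections / n_pairs


def lmm_parameter_recovery(
    seed: int,
    n_seeds: int = 200,
    n_subjects: int = 20,
    visit_months: tuple = (0.0, 6.0, 12.0),
    slope: float = -0.05,
    sigma_b: float = 0.5,
    sigma: float = 0.3,
) -> dict:
    """Bias and 95% CI coverage of the REML slope over repeated simulations."""
    rng = np.random.default_rng(seed)
    t = np.tile(visit_months, n_subjects)
    subj = np.repeat(np.arange(n_subjects), len(visit_months))
    estimates, covered = [], 0
    for _ in range(n_seeds):
        b = rng.normal(0.0, sigma_b, n_subjects)
        y = 1.0 + b[subj] + slope * t + rng.normal(0.0, sigma, t.size)
        fit = fit_lmm(y, t, subj)
        estimates.append(fit.slope)
        half = stats.t.ppf(0.975, fit.df) * fit.slope_se
        if fit.slope - half <= slope <= fit.slope + half:
            covered += 1
    estimates = np.asarray(estimates)
    return {
        "mean_slope": float(estimates.mean()),
        "bias": float(estimates.mean() - slope),
        "coverage": covered / n_seeds,
    }


def longitudinal_fixture_metrics(seed: int, alpha: float = 0.1) -> dict:
    """Sensitivity and false discovery proportion of the longitudinal screen
    against the fixture's planted slopes (disease group, all visits)."""
    full, full_meta, _b, _bm, truth = prepare_study_fixture(seed, mad_normalize=True)
    records = longitudinal_screen(full, full_meta, alpha=alpha, group="ALS")
    dec = {r.fit.protein_id for r in records if r.direction == "decreasing"}
    inc = {r.fit.protein_id for r in records if r.direction == "increasing"}
    true_dec = {p for p, s in truth.longitudinal_slopes.items() if s < 0}
    true_inc = {p for p, s in truth.longitudinal_slopes.items() if s > 0}
    discoveries = dec | inc
    false = discoveries - (true_dec | true_inc)
    return {
        "n_discoveries": len(discoveries),
        "fdp": len(false) / max(len(discoveries), 1),
        "sensitivity_decreasing": len(dec & true_dec) / len(true_dec),
        "sensitivity_increasing": len(inc & true_inc) / len(true_inc),
    }
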