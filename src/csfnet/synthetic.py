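"""Synthetic CSF-proteome generator with planted network structure.

The generator emulates the processed form of a case-control CSF proteomic
study: a proteins x samples abundance matrix in which groups of proteins
("modules") share a latent per-subject factor, disease groups shift whole
module factors up or down, selected protein pairs lose their correlation in
one group only, a subset of subjects is re-sampled longitudinally with
per-protein log-linear drift, values go missing at group-specific rates and
a few samples are globally corrupted ("outliers").

The factor model for protein *i* in module *m*, sample of subject *s* in
group *g*::

    log x_is = mu_i + tau_i * (lambda_m * (f_ms + delta_gm) + sqrt(1 - lambda_m^2) * eps_is)
               + slope_i * months_s

with ``f_ms ~ N(0,1)`` per subject, ``lambda_m = sqrt(w_m)`` so that
same-module pairs have correlation ``w_m``, ``eps`` iid standard normal and
``tau_i`` a per-protein log-SD.  Unassigned "noise" proteins are pure
``mu_i + tau_i * eps``.  Follow-up visits reuse the subject's factor draw
(a subject-level random effect) with fresh measurement noise.

Every random draw flows from a single :func:`numpy.random.default_rng`
seed, so identical configurations are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import AbundanceMatrix, SampleInfo, validate_metadata

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "default_study_fixture"]


@dataclass
class SyntheticConfig:
    """Everything :func:`generate` needs, with validation.

    ``decorrelated_pairs`` holds ``(protein_a, protein_b, group)`` triples of
    same-module proteins; the *first* protein's factor contribution is
    resampled independently within the named group, which removes its
    correlation with the whole module there while leaving its marginal
    variance untouched.
    """

    n_proteins: int
    module_sizes: Sequence[int]
    within_module_cor: Sequence[float] | float
    group_sizes: Mapping[str, int]
    eigenprotein_shift: Mapping[tuple[str, int], float] = field(default_factory=dict)
    decorrelated_pairs: Sequence[tuple[str, str, str]] = ()
    longitudinal_slopes: Mapping[str, float] = field(default_factory=dict)
    longitudinal_group: str | None = None
    visits_per_subject: Sequence[int] = ()
    visit_spacing_months: float = 6.0
    missing_rate: Mapping[str, float] = field(default_factory=dict)
    extra_missing: Sequence[tuple[str, str, float]] = ()
    mnar: bool = False
    outlier_groups: Sequence[str] = ()
    mean_log_abundance: float = 5.0
    protein_sd_range: tuple[float, float] = (0.3, 0.8)
    seed: int = 0

    # -- derived helpers ---------------------------------------------------
    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_outlier_samples(self) -> int:
        return len(self.outlier_groups)

    def protein_ids(self) -> list[str]:
        width = max(4, len(str(self.n_proteins)))
        return [f"P{i + 1:0{width}d}" for i in range(self.n_proteins)]

    def module_assignment(self) -> np.ndarray:
        """Planted module per protein index; 0 marks noise proteins."""
        assignment = np.zeros(self.n_proteins, dtype=int)
        pos = 0
        for m, size in enumerate(self.module_sizes, start=1):
            assignment[pos : pos + size] = m
            pos += size
        return assignment

    def within_cor_vector(self) -> np.ndarray:
        w = self.within_module_cor
        if np.isscalar(w):
            return np.full(self.n_modules, float(w))
        w = np.asarray(w, dtype=float)
        if w.shape != (self.n_modules,):
            raise ValueError("within_module_cor must be scalar or one value per module")
        return w

    def validate(self) -> None:
        sizes = list(self.module_sizes)
        if any(s < 1 for s in sizes):
            raise ValueError("module sizes must be >= 1")
        if sum(sizes) > self.n_proteins:
            raise ValueError("module sizes sum exceeds n_proteins")
        if not all(0 < w < 1 for w in self.within_cor_vector()):
            raise ValueError("within_module_cor must lie in (0, 1)")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        for g, p in self.missing_rate.items():
            if not 0 <= p <= 1:
                raise ValueError(f"missing_rate[{g!r}] outside [0,1]")
        for pid, g, p in self.extra_missing:
            if not 0 <= p <= 1:
                raise ValueError(f"extra_missing rate for {pid!r} outside [0,1]")
        ids = self.protein_ids()
        index = {p: i for i, p in enumerate(ids)}
        assignment = self.module_assignment()
        for a, b, g in self.decorrelated_pairs:
            if a not in index or b not in index:
                raise ValueError(f"decorrelated pair ({a}, {b}) references unknown proteins")
            ma, mb = assignment[index[a]], assignment[index[b]]
            if ma == 0 or ma != mb:
                raise ValueError(
                    f"decorrelated pair ({a}, {b}) must lie in the same planted module"
                )
            if g not in self.group_sizes:
                raise ValueError(f"decorrelated pair group {g!r} unknown")
        for pid in self.longitudinal_slopes:
            if pid not in index:
                raise ValueError(f"longitudinal protein {pid!r} unknown")
        if self.visits_per_subject:
            if self.longitudinal_group not in self.group_sizes:
                raise ValueError("longitudinal_group must name a configured group")
            if len(self.visits_per_subject) > self.group_sizes[self.longitudinal_group]:
                raise ValueError("more longitudinal subjects than subjects in the group")
            if any(v < 2 for v in self.visits_per_subject):
                raise ValueError("longitudinal subjects need >= 2 visits")
        for g in self.outlier_groups:
            if g not in self.group_sizes:
                raise ValueError(f"outlier group {g!r} unknown")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated dataset, for recovery tests."""

    protein_ids: list[str]
    module_assignment: dict[str, int]
    sample_records: list[SampleInfo]
    factors: np.ndarray  # modules x samples, shift included
    eigenprotein_shift: dict[tuple[str, int], float]
    decorrelated_pairs: list[tuple[str, str, str]]
    longitudinal_slopes: dict[str, float]
    outlier_samples: list[str]
    high_missing_proteins: list[str]
    seed: int

    def assignment_vector(self, protein_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = list(protein_ids) if protein_ids is not None else self.protein_ids
        return np.array([self.module_assignment[p] for p in ids], dtype=int)

    def to_jsonable(self) -> dict:
        return {
            "seed": self.seed,
            "module_assignment": self.module_assignment,
            "eigenprotein_shift": {f"{g}:{m}": v for (g, m), v in self.eigenprotein_shift.items()},
            "decorrelated_pairs": [list(t) for t in self.decorrelated_pairs],
            "longitudinal_slopes": self.longitudinal_slopes,
            "outlier_samples": self.outlier_samples,
            "high_missing_proteins": self.high_missing_proteins,
            "factors": {
                "sample_ids": [r.sample_id for r in self.sample_records],
                "values": self.factors.tolist(),
            },
        }


def _subject_ids(group: str, n: int, offset: int = 0) -> list[str]:
    return [f"{group}{i + 1 + offset:03d}" for i in range(n)]


def generate(config: SyntheticConfig) -> tuple[AbundanceMatrix, list[SampleInfo], SyntheticTruth]:
    """Draw one dataset from the planted factor model.

    Returns the abundance matrix on *linear* scale (exponentiated log
    abundances, so the pipeline's log transform applies cleanly), the sample
    metadata, and the ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    protein_ids = config.protein_ids()
    index = {p: i for i, p in enumerate(protein_ids)}
    assignment = config.module_assignment()
    M = config.n_modules
    w = config.within_cor_vector()
    lam = np.sqrt(w)

    mu = rng.normal(config.mean_log_abundance, 1.0, size=config.n_proteins)
    lo, hi = config.protein_sd_range
    tau = rng.uniform(lo, hi, size=config.n_proteins)

    # --- subjects and samples --------------------------------------------
    groups = list(config.group_sizes)
    subjects: list[tuple[str, str, bool]] = []  # (subject_id, group, is_outlier)
    for g in groups:
        for sid in _subject_ids(g, config.group_sizes[g]):
            subjects.append((sid, g, False))
    for k, g in enumerate(config.outlier_groups):
        sid = f"{g}X{k + 1:02d}"
        subjects.append((sid, g, True))

    followed = set()
    visits_of: dict[str, int] = {}
    if config.visits_per_subject:
        candidates = [s for s, g, out in subjects if g == config.longitudinal_group and not out]
        for sid, nv in zip(candidates, config.visits_per_subject):
            followed.add(sid)
            visits_of[sid] = int(nv)

    records: list[SampleInfo] = []
    sample_subject: list[int] = []  # index into subjects
    sample_months: list[float] = []
    for si, (sid, g, _out) in enumerate(subjects):
        n_visits = visits_of.get(sid, 1)
        for v in range(1, n_visits + 1):
            t = (v - 1) * config.visit_spacing_months
            records.append(SampleInfo(f"{sid}_v{v}", sid, g, v, t))
            sample_subject.append(si)
            sample_months.append(t)
    validate_metadata(records)
    S = len(records)
    sample_subject_arr = np.array(sample_subject)
    months = np.array(sample_months)

    # --- subject-level factors (shift included) ---------------------------
    n_subj = len(subjects)
    f_subj = rng.normal(size=(M, n_subj))
    for (g, m), delta in config.eigenprotein_shift.items():
        cols = [i for i, (_s, gg, _o) in enumerate(subjects) if gg == g]
        f_subj[m - 1, cols] += delta

    # independent factor copies for decorrelated proteins, per subject
    decor_factor: dict[int, np.ndarray] = {}
    decor_group: dict[int, str] = {}
    for a, _b, g in config.decorrelated_pairs:
        i = index[a]
        if i not in decor_factor:
            decor_factor[i] = rng.normal(size=n_subj)
            decor_group[i] = g

    factors = f_subj[:, sample_subject_arr]  # modules x samples

    # --- assemble log abundances -----------------------------------------
    eps = rng.normal(size=(config.n_proteins, S))
    unit = np.empty((config.n_proteins, S))
    noise_rows = assignment == 0
    unit[noise_rows] = eps[noise_rows]
    for m in range(1, M + 1):
        rows = assignment == m
        unit[rows] = lam[m - 1] * factors[m - 1] + np.sqrt(1 - w[m - 1]) * eps[rows]
    # swap in the resampled factor for decorrelated proteins in their group
    group_of_sample = np.array([subjects[si][1] for si in sample_subject])
    for i, f_alt in decor_factor.items():
        g = decor_group[i]
        m = assignment[i]
        cols = group_of_sample == g
        alt = f_alt[sample_subject_arr[cols]] + config.eigenprotein_shift.get((g, m), 0.0)
        unit[i, cols] = lam[m - 1] * alt + np.sqrt(1 - w[m - 1]) * eps[i, cols]

    log_x = mu[:, None] + tau[:, None] * unit

    # longitudinal drift
    for pid, slope in config.longitudinal_slopes.items():
        log_x[index[pid]] += slope * months

    # outlier corruption: +4 SD location shift plus 3 SD extra noise
    outlier_sample_ids: list[str] = []
    for j, r in enumerate(records):
        si = sample_subject[j]
        if subjects[si][2]:
            log_x[:, j] += 4.0 * tau + 3.0 * tau * rng.normal(size=config.n_proteins)
            outlier_sample_ids.append(r.sample_id)

    # --- missingness ------------------------------------------------------
    miss = np.zeros_like(log_x, dtype=bool)
    for g, rate in config.missing_rate.items():
        if rate <= 0:
            continue
        cols = group_of_sample == g
        u = rng.uniform(size=(config.n_proteins, int(cols.sum())))
        if config.mnar:
            # intensity-dependent: acceptance probability shrinks for
            # low-abundance cells (logistic in the per-protein z-score)
            sub = log_x[:, cols]
            z = (sub - sub.mean(axis=1, keepdims=True)) / (sub.std(axis=1, keepdims=True) + 1e-12)
            p = rate * 2.0 / (1.0 + np.exp(2.0 * z))
            miss[:, cols] = u < p
        else:
            miss[:, cols] = u < rate
    high_missing: list[str] = []
    for pid, g, rate in config.extra_missing:
        i = index[pid]
        cols = np.where(group_of_sample == g)[0]
        miss[i, cols] |= rng.uniform(size=cols.size) < rate
        high_missing.append(pid)

    values = np.exp(log_x)
    values[miss] = np.nan

    matrix = AbundanceMatrix(protein_ids, [r.sample_id for r in records], values, scale="linear")
    truth = SyntheticTruth(
        protein_ids=protein_ids,
        module_assignment={p: int(m) for p, m in zip(protein_ids, assignment)},
        sample_records=records,
        factors=factors,
        eigenprotein_shift=dict(config.eigenprotein_shift),
        decorrelated_pairs=list(config.decorrelated_pairs),
        longitudinal_slopes=dict(config.longitudinal_slopes),
        outlier_samples=outlier_sample_ids,
        high_missing_proteins=high_missing,
        seed=config.seed,
    )
    return matrix, records, truth


# ---------------------------------------------------------------------------
# ready-made study-shaped fixture
# ---------------------------------------------------------------------------

#: module sizes: the reported range 7-183 with ten modules totalling 776
STUDY_MODULE_SIZES = (183, 115, 110, 90, 75, 67, 64, 58, 7, 7)
STUDY_GROUP_SIZES = {"ALS": 41, "HC": 20, "PD": 19}
#: follow-up ladder for the 20 longitudinally sampled disease subjects:
#: 20 reach visit 2, 12 visit 3, 10 visit 4, 2 visit 5
STUDY_VISIT_LADDER = tuple([5] * 2 + [4] * 8 + [3] * 2 + [2] * 8)


def default_study_fixture(
    seed: int = 0,
) -> tuple[AbundanceMatrix, list[SampleInfo], SyntheticTruth]:
    """A ready-made configuration shaped like the motivating CSF study.

    883 proteins (776 in 10 modules of 7-183 proteins plus 107 noise
    proteins), three groups of 41/20/19 subjects plus 3 planted outlier
    subjects, module-level disease shifts (module 2 down and modules 4/9 up
    in the first disease group; module 9 up in the second), 10 decorrelated
    pairs (8 in module 1, 2 in module 9), 18 high-missingness proteins, and
    15 decreasing / 10 increasing longitudinal proteins among 20 disease
    subjects re-sampled at 6-month intervals.
    """
    sizes = STUDY_MODULE_SIZES
    n_assigned = sum(sizes)
    n_proteins = n_assigned + 107
    within = [0.8] * len(sizes)
    within[0] = 0.9  # module 1: tight gene-expression module
    within[8] = 0.9  # module 9: blood gas-transport proteins
    within[9] = 0.9  # module 10: clotting/fibrinogen complex

    width = max(4, len(str(n_proteins)))

    def pid(i: int) -> str:  # 1-based protein index -> id
        return f"P{i:0{width}d}"

    starts = np.cumsum((0,) + sizes)
    module_members = {m + 1: [pid(i + 1) for i in range(starts[m], starts[m + 1])] for m in range(len(sizes))}
    noise_members = [pid(i + 1) for i in range(n_assigned, n_proteins)]

    shifts = {
        ("ALS", 2): -1.5,
        ("ALS", 4): 1.5,
        ("ALS", 9): 1.5,
        ("PD", 9): 1.5,
    }

    # 10 pairs through 4 perturbed proteins in the two small, tight modules:
    # the first protein of each pair loses its module factor in the disease
    # group, so its pairs are all truly decorrelated while the bulk of
    # within-module pairs stays intact.  Small host modules keep the set of
    # perturbed pairs sparse relative to the whole within-module family.
    m9 = module_members[9]
    m10 = module_members[10]
    decorrelated = []
    for mod in (m9, m10):
        decorrelated += [(mod[0], mod[1], "ALS"), (mod[0], mod[2], "ALS"),
                         (mod[0], mod[5], "ALS"),
                         (mod[3], mod[4], "ALS"), (mod[3], mod[5], "ALS")]

    m6 = module_members[6]
    m2 = module_members[2]
    slopes: dict[str, float] = {}
    for p in m6[:10]:
        slopes[p] = -0.04
    for p in m2[:5]:
        slopes[p] = -0.04
    for p in noise_members[:10]:
        slopes[p] = 0.04

    # 18 high-missingness proteins, clear of any other planted structure
    m3 = module_members[3]
    extra_missing = [(p, "PD", 0.7) for p in m3[:6]] + [
        (p, "PD", 0.7) for p in noise_members[10:22]
    ]

    config = SyntheticConfig(
        n_proteins=n_proteins,
        module_sizes=sizes,
        within_module_cor=within,
        group_sizes=STUDY_GROUP_SIZES,
        eigenprotein_shift=shifts,
        decorrelated_pairs=decorrelated,
        longitudinal_slopes=slopes,
        longitudinal_group="ALS",
        visits_per_subject=STUDY_VISIT_LADDER,
        visit_spacing_months=6.0,
        missing_rate={"ALS": 0.03, "HC": 0.03, "PD": 0.03},
        extra_missing=extra_missing,
        outlier_groups=("ALS", "ALS", "PD"),
        seed=seed,
    )
    return generate(config)
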