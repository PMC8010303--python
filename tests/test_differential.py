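import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfnet.differential import (
    bh_adjust,
    differential_correlation,
    differential_correlation_table,
    eigenprotein_group_tests,
    group_correlation_profiles,
)
from csfnet.model import AbundanceMatrix, SampleInfo
from csfnet.network import compute_eigenproteins
from csfnet.synthetic import SyntheticConfig, generate


def brute_force_bh(p):
    """Literal step-up definition: q_(i) = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05]), [0.05] * 5
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-14)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_output_dominates_raw_and_preserves_ranks(self, p):
        q = bh_adjust(p)
        p = np.asarray(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestMannWhitneyEigenproteinTests:
    @staticmethod
    def _records(values_by_group, n_modules=1):
        sample_ids, meta, cols = [], [], []
        for g, vals in values_by_group.items():
            for i, v in enumerate(vals):
                sid = f"{g}{i}"
                sample_ids.append(sid)
                meta.append(SampleInfo(sid, sid, g, 1, 0.0))
                cols.append(v)
        eig = np.tile(np.asarray(cols, float), (n_modules, 1))
        return eigenprotein_group_tests(eig, sample_ids, meta, "HC")

    def test_exact_enumeration_small_groups(self):
        recs = self._records({"HC": [1.0, 2.0], "DIS": [3.0, 4.0]})
        assert recs[0].u_statistic == 0.0
        assert recs[0].p_value == pytest.approx(1 / 3)

    def test_all_ties_carry_no_evidence(self):
        recs = self._records({"HC": [1.0] * 5, "DIS": [1.0] * 5})
        assert recs[0].p_value == 1.0

    def test_reference_compared_to_each_disease_only(self):
        recs = self._records({"HC": [1, 2, 3.0], "A": [2, 3, 4.0], "B": [5, 6, 7.0]})
        assert {(r.group_a, r.group_b) for r in recs} == {("HC", "A"), ("HC", "B")}
        medians = {r.group_b: (r.median_a, r.median_b) for r in recs}
        assert medians["A"] == (2.0, 3.0) and medians["B"] == (2.0, 6.0)

    def test_planted_shift_detected_with_power(self):
        """A 1.5-latent-unit eigenprotein shift is significant (raw p < 0.05)
        in >= 80% of 20 simulated cohorts."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SyntheticConfig(
                n_proteins=40, module_sizes=[20, 20], within_module_cor=0.8,
                group_sizes={"HC": 20, "ALS": 41},
                eigenprotein_shift={("ALS", 1): 1.5},
                seed=seed,
            )
            matrix, meta, truth = generate(cfg)
            X = np.log(matrix.values)
            eig, _ = compute_eigenproteins(X, truth.assignment_vector())
            recs = eigenprotein_group_tests(
                eig, matrix.sample_ids, meta, "HC", module_labels=[1, 2]
            )
            shifted = next(r for r in recs if r.module == 1)
            hits += shifted.p_value < 0.05
        assert hits / n_seeds >= 0.8


class TestDifferentialCorrelation:
    def test_fisher_z_closed_form(self):
        """r1 = 0.97 (n 20) vs r2 = 0.56 (n 41): Z and p match an
        independent high-precision evaluation to 6 significant figures."""
        r_ref = np.array([[1.0, 0.97], [0.97, 1.0]])
        r_dis = np.array([[1.0, 0.56], [0.56, 1.0]])
        rec = differential_correlation(
            r_ref, np.full((2, 2), 20), r_dis, np.full((2, 2), 41), ["a", "b"]
        )[0]
        # frozen values from an independent high-precision evaluation
        # (50-digit arithmetic: z = atanh(r), Z = (z1-z2)/sqrt(1/17+1/38))
        assert rec.z_statistic == pytest.approx(5.00181776, rel=1e-8)
        assert rec.p_value == pytest.approx(5.679226e-7, rel=1e-6)

    def test_equal_correlations_give_null(self):
        r = np.array([[1.0, 0.4], [0.4, 1.0]])
        rec = differential_correlation(r, np.full((2, 2), 30), r, np.full((2, 2), 12), ["a", "b"])[0]
        assert rec.z_statistic == 0.0 and rec.p_value == 1.0

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 30))
        y = rng.normal(size=(5, 25))
        r1, r2 = np.corrcoef(x), np.corrcoef(y)
        n1, n2 = np.full((5, 5), 30), np.full((5, 5), 25)
        fwd = differential_correlation_table(r1, n1, r2, n2, [f"P{i}" for i in range(5)])
        rev = differential_correlation_table(r2, n2, r1, n1, [f"P{i}" for i in range(5)])
        np.testing.assert_allclose(fwd["z_statistic"], -rev["z_statistic"])
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"])

    def test_small_n_pairs_skipped(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        recs = differential_correlation(r, np.full((2, 2), 3), r, np.full((2, 2), 30), ["a", "b"])
        assert recs == []

    def test_type_one_error_calibrated(self):
        from csfnet.validation import diffcorr_null_type1

        rate = diffcorr_null_type1(seed=12345, n_pairs=2000)
        assert 0.04 <= rate <= 0.06


class TestGroupProfiles:
    @staticmethod
    def _dataset():
        cfg = SyntheticConfig(
            n_proteins=20, module_sizes=[10], within_module_cor=0.7,
            group_sizes={"HC": 25, "DIS": 25}, seed=8,
        )
        matrix, meta, truth = generate(cfg)
        matrix = AbundanceMatrix(
            matrix.protein_ids, matrix.sample_ids, np.log(matrix.values), "log"
        )
        return matrix, meta, truth

    def test_counts_bounded_by_group_size(self):
        matrix, meta, _ = self._dataset()
        _r, n = group_correlation_profiles(matrix, meta, "HC", min_pairwise_n=5)
        assert n.max() <= 25

    def test_recovers_planted_group_correlation(self):
        rs = []
        for seed in range(10):
            cfg = SyntheticConfig(
                n_proteins=20, module_sizes=[10], within_module_cor=0.7,
                group_sizes={"HC": 30, "DIS": 30}, seed=seed,
            )
            matrix, meta, _ = generate(cfg)
            matrix = AbundanceMatrix(
                matrix.protein_ids, matrix.sample_ids, np.log(matrix.values), "log"
            )
            r, _ = group_correlation_profiles(matrix, meta, "HC", min_pairwise_n=5)
            rs.append(r[0, 1])
        assert abs(np.mean(rs) - 0.7) < 0.15

    def test_too_small_group_rejected(self):
        matrix, meta, _ = self._dataset()
        meta = meta + [SampleInfo("solo", "solo", "TINY", 1, 0.0)]
        with pytest.raises(ValueError):
            group_correlation_profiles(matrix, meta, "TINY", min_pairwise_n=5)
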