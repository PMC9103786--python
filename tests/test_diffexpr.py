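import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wregdiv.diffexpr import (
    ContrastSpec,
    binomial_divergence_test,
    call_contrast,
    estimate_qvalues,
    fisher_divergence_test,
    fold_change,
    integerize_counts,
)
from wregdiv.expression_io import ExpressionMatrix
from wregdiv.synthetic_data import SimulationConfig, generate_null_dataset


def _binomial_minlike_oracle(k: int, n: int, p: float) -> float:
    """Brute-force two-sided binomial p: sum pmf(j) over j with pmf(j) <= pmf(k)."""
    pmf = stats.binom.pmf(np.arange(n + 1), n, p)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-12)].sum())


class TestFoldChange:
    def test_identity(self):
        assert fold_change(7.0, 7.0) == 1.0

    @given(
        a=st.floats(0.0, 1e4, allow_nan=False),
        b=st.floats(0.0, 1e4, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_reciprocal_symmetry(self, a, b):
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)

    def test_boundary_not_exceeded(self):
        # a 10-vs-8 gene sits exactly at 1.25 as pseudo -> 0; the strict
        # ">" comparison must not fire
        fc = fold_change(10.0, 8.0, pseudo=1e-12)
        assert fc == pytest.approx(1.25)
        assert not fc > 1.25 + 1e-9

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            fold_change(-1.0, 1.0)


class TestIntegerize:
    def test_single_replicate(self):
        assert integerize_counts(np.array([[2.4]]), 10.0) == [24]

    def test_all_zero(self):
        np.testing.assert_array_equal(
            integerize_counts(np.zeros((3, 4)), 10.0), [0, 0, 0]
        )

    def test_half_up_rounding(self):
        assert integerize_counts(np.array([[0.25]]), 10.0) == [3]
        assert integerize_counts(np.array([[0.35]]), 10.0) == [4]

    def test_scale_invariance_of_fold_change_verdicts(self):
        rng = np.random.default_rng(5)
        values = rng.gamma(3.0, 8.0, size=(50, 6))
        m = ExpressionMatrix(
            tuple(f"g{i}" for i in range(50)),
            tuple(f"s{j}" for j in range(6)),
            values,
        )
        results = {}
        for scale in (1.0, 100.0):
            spec = ContrastSpec(
                "c", ("s0", "s1", "s2"), ("s3", "s4", "s5"), library_scale=scale
            )
            results[scale] = call_contrast(m, spec)
        np.testing.assert_allclose(
            results[1.0]["fold_change"], results[100.0]["fold_change"]
        )
        fc_pass_1 = (results[1.0]["fold_change"] > 1.25) | (results[1.0]["fold_change"] < 0.8)
        fc_pass_100 = (results[100.0]["fold_change"] > 1.25) | (results[100.0]["fold_change"] < 0.8)
        assert (fc_pass_1 == fc_pass_100).all()


class TestBinomialTest:
    def test_balanced_counts_p_one(self):
        assert binomial_divergence_test(50, 50, 0.5) == pytest.approx(1.0)

    def test_one_sided_extreme_vs_enumeration(self):
        # 20-vs-0 at fraction 0.5: only the two extreme outcomes are as
        # unlikely as observed -> p = 2 * 0.5**20
        expected = _binomial_minlike_oracle(20, 20, 0.5)
        assert expected == pytest.approx(2 * 0.5**20)
        assert binomial_divergence_test(20, 0, 0.5) == pytest.approx(expected)

    @given(
        k=st.integers(0, 30),
        n_extra=st.integers(0, 30),
        p=st.floats(0.1, 0.9),
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_enumeration_oracle(self, k, n_extra, p):
        n = k + n_extra
        got = binomial_divergence_test(k, n - k, p)
        assert got == pytest.approx(_binomial_minlike_oracle(k, n, p), abs=1e-10)

    def test_swap_symmetry(self):
        assert binomial_divergence_test(3, 17, 0.5) == pytest.approx(
            binomial_divergence_test(17, 3, 0.5)
        )

    def test_both_zero(self):
        assert binomial_divergence_test(0, 0, 0.5) == 1.0

    def test_non_integer_errors(self):
        with pytest.raises(ValueError):
            binomial_divergence_test(1.5, 2, 0.5)


class TestFisherTest:
    def test_identical_proportions(self):
        assert fisher_divergence_test(5, 5, 100, 100) == pytest.approx(1.0)

    def test_disjoint_vs_enumeration(self):
        # rows (0, 10) and (10, 0): enumerate the 11 possible tables under
        # the hypergeometric null
        n = 20
        k_total = 10
        pmf = stats.hypergeom.pmf(np.arange(0, 11), n, k_total, 10)
        observed = pmf[0]
        expected = float(pmf[pmf <= observed * (1 + 1e-12)].sum())
        assert expected == pytest.approx(2 / math.comb(20, 10))
        assert fisher_divergence_test(0, 10, 10, 10) == pytest.approx(expected)

    def test_row_transpose_symmetry(self):
        assert fisher_divergence_test(3, 9, 20, 30) == pytest.approx(
            fisher_divergence_test(9, 3, 30, 20)
        )

    def test_count_exceeding_total_errors(self):
        with pytest.raises(ValueError):
            fisher_divergence_test(11, 0, 10, 10)


class TestQvalues:
    def test_all_ones(self):
        np.testing.assert_array_equal(
            estimate_qvalues(np.ones(10), "bh"), np.ones(10)
        )

    def test_bh_hand_check(self):
        # step-up on (0.01, 0.02, 0.03, 0.04), m = 4:
        # q4 = 0.04, q3 = min(0.04, 0.03*4/3) = 0.04, q2 = 0.04, q1 = 0.04
        q = estimate_qvalues(np.array([0.01, 0.02, 0.03, 0.04]), "bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equal_p_equal_q(self):
        q = estimate_qvalues(np.array([0.2, 0.05, 0.2, 0.01, 0.2] * 5), "storey")
        vals = q[np.array([0, 2, 4])]
        assert vals[0] == vals[1] == vals[2]

    def test_storey_not_above_bh_when_pi0_lt_one(self):
        rng = np.random.default_rng(11)
        p = np.concatenate([rng.uniform(0, 0.01, 50), rng.uniform(0, 1, 50)])
        bh = estimate_qvalues(p, "bh")
        storey = estimate_qvalues(p, "storey")
        assert np.mean(p > 0.5) / 0.5 < 1.0  # pi0 estimate below 1 here
        assert (storey <= bh + 1e-12).all()

    def test_small_sets_fall_back_to_bh(self):
        p = np.array([0.001] * 10)
        np.testing.assert_allclose(
            estimate_qvalues(p, "storey"), estimate_qvalues(p, "bh")
        )

    @given(
        shift=st.floats(0.01, 0.5),
        seed=st.integers(0, 100),
        method=st.sampled_from(["bh", "storey"]),
    )
    @settings(max_examples=30, deadline=None)
    def test_monotone_under_constant_shift(self, shift, seed, method):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 0.5, 30)
        q0 = estimate_qvalues(p, method)
        q1 = estimate_qvalues(np.minimum(p + shift, 1.0), method)
        assert (q1 >= q0 - 1e-12).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            estimate_qvalues(np.array([0.5, 1.5]))


def _two_pop_matrix(mean_a, mean_b, n_genes=30, reps=3, cv=0.0, seed=0):
    rng = np.random.default_rng(seed)
    base = np.concatenate(
        [np.full((n_genes, reps), mean_a), np.full((n_genes, reps), mean_b)], axis=1
    )
    if cv > 0:
        sigma = math.sqrt(math.log(1 + cv**2))
        base = base * rng.lognormal(-sigma**2 / 2, sigma, size=base.shape)
    samples = tuple(f"a{i}" for i in range(reps)) + tuple(f"b{i}" for i in range(reps))
    return (
        ExpressionMatrix(tuple(f"g{i}" for i in range(n_genes)), samples, base),
        tuple(f"a{i}" for i in range(reps)),
        tuple(f"b{i}" for i in range(reps)),
    )


class TestCallContrast:
    def test_identical_populations_not_significant(self):
        m, a, b = _two_pop_matrix(10.0, 10.0)
        res = call_contrast(m, ContrastSpec("c", a, b))
        assert not res["significant"].any()
        assert (res["direction"] == "none").all()

    def test_true_fourfold_detected(self):
        m, a, b = _two_pop_matrix(40.0, 10.0, cv=0.05, seed=1)
        res = call_contrast(m, ContrastSpec("c", a, b))
        assert res["significant"].all()
        assert (res["direction"] == "A_up").all()

    def test_fold_change_without_fdr_not_significant(self):
        # 2-fold difference at trace expression: window passes, q does not
        m, a, b = _two_pop_matrix(0.1, 0.05)
        res = call_contrast(m, ContrastSpec("c", a, b))
        assert (res["fold_change"] > 1.25).all()
        assert not res["significant"].any()

    def test_swap_flips_directions(self):
        m, a, b = _two_pop_matrix(40.0, 10.0, cv=0.1, seed=2)
        fwd = call_contrast(m, ContrastSpec("c", a, b))
        rev = call_contrast(m, ContrastSpec("c", b, a))
        np.testing.assert_array_equal(fwd["significant"], rev["significant"])
        sig = fwd["significant"]
        assert (fwd.loc[sig, "direction"] == "A_up").equals(
            rev.loc[sig, "direction"] == "B_up"
        )

    def test_empty_population_errors(self):
        with pytest.raises(ValueError, match="zero samples"):
            ContrastSpec("c", (), ("b1",))

    def test_overlapping_populations_error(self):
        with pytest.raises(ValueError, match="overlap"):
            ContrastSpec("c", ("x",), ("x",))

    def test_null_false_positive_rate(self):
        # no true divergence, 200 genes, 3 replicates/side: the fraction
        # called significant stays within 0.05 + 3 binomial SEs
        cfg = SimulationConfig(
            class_counts={"null": 200},
            seed=5,
            noise_cv=0.2,
            baseline_log2_mean=2.0,
            baseline_log2_sd=0.8,
            tissues=("brain",),
        )
        matrix, sheet, _ = generate_null_dataset(cfg)
        spec = ContrastSpec(
            "parental",
            sheet.select(population="Cor", tissue="brain"),
            sheet.select(population="WL", tissue="brain"),
        )
        frac = call_contrast(matrix, spec)["significant"].mean()
        bound = 0.05 + 3 * math.sqrt(0.05 * 0.95 / 200)
        assert frac <= bound
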