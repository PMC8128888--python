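"""Exact and Monte-Carlo permutation tests and the grand combination methods."""

import math
from itertools import combinations

import numpy as np
import pytest

from cochmap.permutation import (
    PermutationTestResult,
    ReductionTimeTable,
    exact_test_single,
    grand_test_method1,
    grand_test_method2,
    mc_test_single,
    n_exact_assignments,
    n_grand_assignments,
    run_full_inference,
    set_difference,
)


def _brute_force_p(values, n_op, osd, sided="one"):
    """Independent oracle: enumerate every assignment with itertools."""
    n = len(values)
    count = total = 0
    for op_idx in combinations(range(n), n_op):
        op = [values[i] for i in op_idx]
        ctrl = [values[i] for i in range(n) if i not in op_idx]
        pd_ = sum(ctrl) / len(ctrl) - sum(op) / len(op)
        hit = pd_ >= osd if sided == "one" else abs(pd_) >= abs(osd)
        count += hit
        total += 1
    return count / total


def _single_freq_table(operated, control, freq=4.0):
    n_op, n_ct = len(operated), len(control)
    return ReductionTimeTable(
        ear_ids=tuple(f"o{i}" for i in range(n_op))
        + tuple(f"c{i}" for i in range(n_ct)),
        groups=("operated",) * n_op + ("control",) * n_ct,
        freqs_khz=(freq,),
        t50=np.array(list(operated) + list(control), dtype=float)[:, None],
    )


class TestSetDifference:
    def test_arithmetic(self, toy_table):
        # mean({8,9,10,11}) - mean({1,2,3}) = 9.5 - 2
        assert set_difference(toy_table, 4.0) == pytest.approx(7.5)

    def test_identical_groups_zero(self):
        table = _single_freq_table([5.0, 6.0], [5.0, 6.0])
        assert set_difference(table, 4.0) == pytest.approx(0.0)

    def test_label_swap_negates(self, toy_table):
        swapped = ReductionTimeTable(
            toy_table.ear_ids,
            tuple(
                "control" if g == "operated" else "operated" for g in toy_table.groups
            ),
            toy_table.freqs_khz,
            toy_table.t50,
        )
        assert set_difference(swapped, 4.0) == pytest.approx(
            -set_difference(toy_table, 4.0)
        )

    def test_unknown_frequency(self, toy_table):
        with pytest.raises(KeyError):
            set_difference(toy_table, 99.0)


class TestExactSingle:
    def test_enumeration_size_5_of_13(self, study_table):
        res = exact_test_single(study_table, 2.0)
        assert res.n_perm == 1287 == math.comb(13, 5)

    def test_toy_p_matches_brute_force(self, toy_table):
        res = exact_test_single(toy_table, 4.0)
        values = toy_table.t50[:, 0].tolist()
        oracle = _brute_force_p(values, 3, res.osd)
        assert res.p == pytest.approx(oracle)
        assert res.p == pytest.approx(1.0 / 35.0)

    def test_two_sided_matches_brute_force(self, study_table):
        for f in (2.0, 8.0):
            res = exact_test_single(study_table, f, sided="two")
            oracle = _brute_force_p(
                study_table.column(f).tolist(), 5, res.osd, sided="two"
            )
            assert res.p == pytest.approx(oracle)

    def test_all_equal_values_p_one(self):
        table = _single_freq_table([3.0] * 5, [3.0] * 8)
        assert exact_test_single(table, 4.0).p == 1.0

    def test_p_is_multiple_of_reciprocal_count(self, study_table):
        res = exact_test_single(study_table, 6.0)
        assert res.exceed_count == pytest.approx(res.p * res.n_perm)
        assert res.p >= 1.0 / res.n_perm  # observed assignment included

    def test_one_sided_not_larger_than_two_sided(self, study_table):
        for f in study_table.freqs_khz:
            if set_difference(study_table, f) > 0:
                p1 = exact_test_single(study_table, f, "one").p
                p2 = exact_test_single(study_table, f, "two").p
                assert p1 <= p2

    def test_label_swap_tests_opposite_tail(self, toy_table):
        swapped = ReductionTimeTable(
            toy_table.ear_ids,
            tuple(
                "control" if g == "operated" else "operated" for g in toy_table.groups
            ),
            toy_table.freqs_khz,
            toy_table.t50,
        )
        # OSD is negative after the swap: nearly every assignment exceeds it
        res = exact_test_single(swapped, 4.0)
        oracle = _brute_force_p(toy_table.t50[:, 0].tolist(), 4, res.osd)
        assert res.p == pytest.approx(oracle)
        assert res.p > 0.9


class TestMonteCarloSingle:
    def test_converges_to_exact_within_3_sigma(self, toy_table):
        p_exact = exact_test_single(toy_table, 4.0).p
        n_perm = 100_000
        res = mc_test_single(toy_table, 4.0, n_perm=n_perm, seed=7)
        band = 3.0 * math.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(res.p - p_exact) <= band

    def test_deterministic_given_seed(self, study_table):
        a = mc_test_single(study_table, 4.0, n_perm=5000, seed=11)
        b = mc_test_single(study_table, 4.0, n_perm=5000, seed=11)
        assert a == b

    def test_estimators(self, toy_table):
        paper = mc_test_single(toy_table, 4.0, n_perm=1000, seed=3)
        plus1 = mc_test_single(
            toy_table, 4.0, n_perm=1000, seed=3, estimator="plus-one"
        )
        assert paper.p == paper.exceed_count / 1000
        assert plus1.p == (paper.exceed_count + 1) / 1001
        assert plus1.p > 0.0

    def test_incomplete_table_rejected(self):
        t50 = np.array([[1.0], [2.0], [np.nan], [4.0]])
        with pytest.raises(ValueError, match="complete"):
            ReductionTimeTable(
                ("a", "b", "c", "d"),
                ("operated", "operated", "control", "control"),
                (4.0,),
                t50,
            )


class TestGrandMethods:
    def test_single_frequency_degenerates_to_mc_single(self, toy_table):
        single = mc_test_single(toy_table, 4.0, n_perm=20_000, seed=5)
        g1 = grand_test_method1(toy_table, n_perm=20_000, seed=5)
        g2 = grand_test_method2(toy_table, n_perm=20_000, seed=5)
        assert g2.p == pytest.approx(single.p)  # shared RNG stream: identical
        band = 3.0 * math.sqrt(max(single.p, 1e-6) * (1 - single.p) / 20_000)
        assert abs(g1.p - single.p) <= 2 * band + 1e-9

    def test_method2_equals_single_p_for_identical_columns(self, study_table):
        col = study_table.column(2.0)
        table5 = ReductionTimeTable(
            study_table.ear_ids,
            study_table.groups,
            (2.0, 4.0, 6.0, 8.0, 12.0),
            np.tile(col[:, None], (1, 5)),
        )
        g2 = grand_test_method2(table5, n_perm=30_000, seed=9)
        single = mc_test_single(table5, 2.0, n_perm=30_000, seed=9)
        assert g2.p == single.p
        assert g2.osd == pytest.approx(5 * single.osd)
        # and both agree with the exact enumeration to binomial accuracy
        p_exact = exact_test_single(table5, 2.0).p
        band = 3.0 * math.sqrt(p_exact * (1 - p_exact) / 30_000)
        assert abs(g2.p - p_exact) <= band

    def test_all_equal_values_p_one(self):
        table = ReductionTimeTable(
            tuple("abcdefg"),
            ("operated",) * 3 + ("control",) * 4,
            (2.0, 4.0),
            np.full((7, 2), 5.0),
        )
        assert grand_test_method1(table, n_perm=2000, seed=1).p == 1.0
        assert grand_test_method2(table, n_perm=2000, seed=1).p == 1.0

    def test_method1_order_invariant(self, study_table):
        fwd = grand_test_method1(
            study_table, freqs_khz=(2.0, 4.0, 6.0), n_perm=10_000, seed=2
        )
        rev = grand_test_method1(
            study_table, freqs_khz=(6.0, 4.0, 2.0), n_perm=10_000, seed=2
        )
        assert fwd.p == rev.p

    def test_correlated_ears_method2_more_conservative(self):
        """With strong across-frequency ear correlation and a true shift,
        shared permutations (method 2) lose the averaging-out of ear noise
        that independent permutations (method 1) enjoy, so method-2 p is
        larger in the median across replicates."""
        rng = np.random.default_rng(123)
        wins = 0
        n_rep = 40
        for _ in range(n_rep):
            u = rng.normal(0.0, 3.0, 13)  # ear effect shared across freqs
            eps = rng.normal(0.0, 0.3, (13, 5))
            t50 = 20.0 + u[:, None] + eps
            t50[:5] -= 3.0
            table = ReductionTimeTable(
                tuple(f"e{i}" for i in range(13)),
                ("operated",) * 5 + ("control",) * 8,
                (2.0, 4.0, 6.0, 8.0, 12.0),
                t50,
            )
            p1 = grand_test_method1(table, n_perm=4000, seed=1).p
            p2 = grand_test_method2(table, n_perm=4000, seed=1).p
            wins += p2 >= p1
        assert wins > n_rep / 2


class TestAssignmentCounts:
    def test_exact_count(self):
        assert n_exact_assignments(5, 8) == 1287

    def test_grand_independent_count(self):
        assert n_grand_assignments(5, 8, 5) == 1287**5


class TestFullInference:
    def test_report_structure_and_determinism(self, study_table):
        r1 = run_full_inference(study_table, n_perm=2000, seed=4)
        r2 = run_full_inference(study_table, n_perm=2000, seed=4)
        assert r1 == r2
        assert len(r1["per_freq"]) == 5
        for entry in r1["per_freq"]:
            assert set(entry["exact"]) == {"one", "two"}
            assert 0.0 <= entry["mc"]["one"]["p"] <= 1.0
        assert r1["meta"]["n_exact_assignments"] == 1287
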