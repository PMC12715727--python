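import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from behavnet.exceptions import UndefinedStatisticError
from behavnet.oe import (
    PairCounts,
    joint_percent,
    oe_confidence_interval,
    oe_ratio,
    oe_table,
    pairwise_counts,
    rank_combinations,
    stratified_oe,
)
from behavnet.synthetic import (
    IsingParameters,
    enumerate_joint_pmf,
    sample_behaviors,
    true_pairwise_oe,
)


def brute_force_counts(values):
    """Exhaustive per-record double loop (oracle)."""
    N, p = values.shape
    out = {}
    for i in range(p):
        for j in range(i + 1, p):
            n_i = n_j = n_ij = 0
            for r in range(N):
                n_i += values[r, i]
                n_j += values[r, j]
                n_ij += values[r, i] and values[r, j]
            out[(i, j)] = (int(values[:, i].sum()), int(values[:, j].sum()), n_ij)
    return out


class TestPairwiseCounts:
    def test_identical_columns(self):
        m = np.column_stack([np.array([1, 1, 0, 1])] * 2)
        (pc,) = pairwise_counts(m)
        assert pc.n_ij == pc.n_i == pc.n_j == 3

    def test_disjoint_columns(self):
        m = np.array([[1, 0], [0, 1], [1, 0]])
        (pc,) = pairwise_counts(m)
        assert pc.n_ij == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        m = rng.integers(0, 2, (20, 7))
        oracle = brute_force_counts(m)
        pcs = pairwise_counts(m)
        assert len(pcs) == 21
        for pc in pcs:
            assert (pc.n_i, pc.n_j, pc.n_ij) == oracle[(pc.i, pc.j)]

    def test_invalid_counts_rejected(self):
        with pytest.raises(Exception):
            PairCounts(i=0, j=1, N=10, n_i=5, n_j=5, n_ij=6)


class TestOERatio:
    def test_exact_independence(self):
        assert oe_ratio(PairCounts(0, 1, 100, 50, 40, 20)) == 1.0

    def test_direct_arithmetic(self):
        assert oe_ratio(PairCounts(0, 1, 100, 50, 40, 30)) == 1.5

    def test_zero_joint(self):
        assert oe_ratio(PairCounts(0, 1, 100, 50, 40, 0)) == 0.0

    def test_zero_marginal_error(self):
        with pytest.raises(UndefinedStatisticError):
            oe_ratio(PairCounts(0, 1, 100, 0, 40, 0))

    def test_exact_independence_identity_property(self):
        # whenever n_ij * N == n_i * n_j the ratio must be exactly 1.0
        for (N, n_i, n_j, n_ij) in [(12, 6, 4, 2), (1000, 100, 10, 1), (9, 3, 3, 1)]:
            assert oe_ratio(PairCounts(0, 1, N, n_i, n_j, n_ij)) == 1.0

    def test_estimator_consistency(self, two_block_pmf):
        # sample O/E converges to the enumerated truth (3 Monte-Carlo SDs,
        # with the SD from the multinomial delta method on the true cells)
        n = 100_000
        X = sample_behaviors(two_block_pmf, n, seed=17)
        states = two_block_pmf.states
        probs = two_block_pmf.probs
        for pc in pairwise_counts(X):
            truth = true_pairwise_oe(two_block_pmf, pc.i, pc.j)
            sample = oe_ratio(pc)
            xi, xj = states[:, pc.i], states[:, pc.j]
            p11 = probs[(xi == 1) & (xj == 1)].sum()
            p1 = probs[xi == 1].sum()
            p2 = probs[xj == 1].sum()
            # gradient of ln O/E over the four 2x2 cells
            cells = np.array(
                [p11, p1 - p11, p2 - p11, 1 - p1 - p2 + p11]
            )
            grad = np.array([1 / p11 - 1 / p1 - 1 / p2, -1 / p1, -1 / p2, 0.0])
            var_log = (cells @ grad**2 - (cells @ grad) ** 2) / n
            sd = truth * np.sqrt(max(var_log, 0.0))
            assert abs(sample - truth) < 3 * sd + 1e-6

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_relabeling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 2, (30, 7))
        if (m.sum(axis=0) == 0).any():
            return
        base = {(pc.i, pc.j): oe_ratio(pc) for pc in pairwise_counts(m)}
        # permute the five other columns; pair (0,1) must be unchanged
        perm = [0, 1] + list(2 + rng.permutation(5))
        permuted = {(pc.i, pc.j): oe_ratio(pc) for pc in pairwise_counts(m[:, perm])}
        assert permuted[(0, 1)] == base[(0, 1)]


class TestOEConfidenceInterval:
    def test_degenerate_all_both_zero_width(self):
        pc = PairCounts(0, 1, 50, 50, 50, 50)
        lo, hi = oe_confidence_interval(pc, method="bootstrap", B=200, seed=0)
        assert lo == hi == 1.0
        lo, hi = oe_confidence_interval(pc, method="log-delta")
        assert lo == hi == 1.0

    def test_bootstrap_seed_reproducible(self):
        pc = PairCounts(0, 1, 500, 200, 150, 80)
        a = oe_confidence_interval(pc, B=500, seed=9)
        b = oe_confidence_interval(pc, B=500, seed=9)
        assert a == b

    def test_methods_concordant_on_balanced_fixture(self):
        # N=5,000 balanced fixture at independence (n_ij*N == n_i*n_j):
        # the log-delta variance is exact there, so widths agree within 10%
        pc = PairCounts(0, 1, 5000, 2500, 2500, 1250)
        b_lo, b_hi = oe_confidence_interval(pc, method="bootstrap", B=4000, seed=3)
        d_lo, d_hi = oe_confidence_interval(pc, method="log-delta")
        assert (b_hi - b_lo) == pytest.approx(d_hi - d_lo, rel=0.10)

    def test_log_delta_requires_joint(self):
        pc = PairCounts(0, 1, 100, 40, 40, 0)
        with pytest.raises(UndefinedStatisticError):
            oe_confidence_interval(pc, method="log-delta")

    def test_interval_brackets_point(self):
        pc = PairCounts(0, 1, 1000, 400, 300, 150)
        point = oe_ratio(pc)
        for method in ("bootstrap", "log-delta"):
            lo, hi = oe_confidence_interval(pc, method=method, B=2000, seed=1)
            assert lo <= point <= hi


class TestRanking:
    def test_joint_percent_printed_style(self):
        assert joint_percent(1151, 12766) == 9.02
        assert joint_percent(5039, 12766) == 39.47
        # half-up at exact .005
        assert joint_percent(1, 8000) == 0.01  # 0.0125
        assert joint_percent(1, 20000) == 0.01  # exactly 0.005 rounds up

    def test_tie_break_by_n_ij_then_label(self):
        rows = []
        for pair, oe, n_ij in [("B1+B2", 1.5, 10), ("B1+B3", 1.5, 20), ("B2+B3", 1.5, 20)]:
            rows.append(
                {"pair": pair, "oe": oe, "n_ij": n_ij, "undefined": False}
            )
        ranked = rank_combinations(pd.DataFrame(rows), top_k=3)
        assert list(ranked["pair"]) == ["B1+B3", "B2+B3", "B1+B2"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_top_k_clamped(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 2, (200, 7))
        table = oe_table(m, B=50, seed=0)
        ranked = rank_combinations(table, top_k=100)
        assert len(ranked) == 21
        assert list(ranked["rank"]) == list(range(1, 22))

    def test_descending_order(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 2, (300, 7))
        ranked = rank_combinations(oe_table(m, B=50, seed=0), top_k=21)
        assert (np.diff(ranked["oe"].to_numpy()) <= 1e-12).all()


class TestStratifiedOE:
    def test_identical_strata_identical_results(self):
        rng = np.random.default_rng(2)
        m = np.vstack([rng.integers(0, 2, (100, 7))] * 2)
        strata = np.array(["a"] * 100 + ["b"] * 100)
        res = stratified_oe(m, strata, B=100, seed=0, top_k=21)
        a = res["a"].drop(columns=["ci_low", "ci_high"])
        b = res["b"].drop(columns=["ci_low", "ci_high"])
        pd.testing.assert_frame_equal(a, b)

    def test_stratified_equals_subset(self):
        rng = np.random.default_rng(3)
        m = rng.integers(0, 2, (200, 7))
        strata = np.array(["x"] * 120 + ["y"] * 80)
        res = stratified_oe(m, strata, B=100, seed=0, top_k=21)
        direct = rank_combinations(oe_table(m[:120], B=100, seed=0), top_k=21)
        pd.testing.assert_frame_equal(
            res["x"].reset_index(drop=True), direct.reset_index(drop=True)
        )

    def test_single_record_stratum_degenerate_bounds(self):
        m = np.zeros((3, 7), dtype=int)
        m[0] = 1  # the singleton stratum record has every behavior
        strata = np.array(["solo", "rest", "rest"])
        res = stratified_oe(m, strata, B=10, seed=0, top_k=21)
        solo = res["solo"]
        assert set(solo["oe"]).issubset({0.0, 1.0})  # N=1: O/E is n_ij*1/(1*1)

    def test_zero_marginal_stratum_flags_pair(self):
        rng = np.random.default_rng(4)
        m = rng.integers(0, 2, (50, 7))
        m[:, 3] = 0  # behavior 4 absent everywhere
        table = oe_table(m, B=20, seed=0)
        undefined = table[table["undefined"]]
        assert len(undefined) == 6  # every pair with column 3
        assert (table[~table["undefined"]]["oe"].notna()).all()
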