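"""Core solver: interval statistics, SMAWK machinery, optimality."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genozones.wuc import (
    WeightedSequence,
    brute_force_oracle,
    dp_candidate_cost,
    dp_tables,
    fill_row_smawk,
    interval_stats,
    reduce_min_in_place,
    solve_wuc,
    cluster,
)
from conftest import random_sequence


class TestIntervalStats:
    @pytest.mark.parametrize(
        "x, w, j, i, mean, ssq",
        [
            ([1, 2, 3], None, 0, 2, 2.0, 2.0),
            ([1, 2, 3], None, 1, 1, 2.0, 0.0),
            ([0, 10], [3, 1], 0, 1, 2.5, 75.0),
        ],
    )
    def test_weighted_mean_and_ssq(self, x, w, j, i, mean, ssq):
        seq = WeightedSequence(x, w)
        m, s = interval_stats(seq, j, i)
        assert m == pytest.approx(mean)
        assert s == pytest.approx(ssq)

    def test_empty_interval_costs_infinity(self):
        seq = WeightedSequence([1, 2, 3])
        assert interval_stats(seq, 2, 1)[1] == math.inf

    def test_zero_weight_interval_is_free_with_midpoint_mean(self):
        seq = WeightedSequence([0.0, 4.0, 10.0], [0.0, 0.0, 1.0])
        m, s = interval_stats(seq, 0, 1)
        assert s == 0.0
        assert m == 2.0

    def test_out_of_range_rejected(self):
        seq = WeightedSequence([1, 2])
        with pytest.raises(IndexError):
            interval_stats(seq, 0, 5)

    def test_constructor_validates(self):
        with pytest.raises(ValueError):
            WeightedSequence([3, 2, 1])
        with pytest.raises(ValueError):
            WeightedSequence([1, 2], [-1, 1])
        with pytest.raises(ValueError):
            WeightedSequence([1, 2], [0, 0])


class TestCandidateCost:
    def test_padding_left_and_right(self):
        seq = WeightedSequence([0, 1, 9, 10])
        S0 = dp_tables(seq, 1)[0][0]
        assert dp_candidate_cost(S0, seq, 2, 3, 1) == math.inf  # j < q
        assert dp_candidate_cost(S0, seq, 1, 1, 2) == math.inf  # j > i

    def test_interior_value_matches_recurrence(self):
        seq = WeightedSequence([0, 1, 9, 10])
        S0 = dp_tables(seq, 1)[0][0]
        assert dp_candidate_cost(S0, seq, 1, 3, 2) == pytest.approx(1.0)


class TestReduceMinInPlace:
    def test_returns_input_when_no_excess(self):
        cols = np.array([4, 7])
        out = reduce_min_in_place(cols, 3, lambda p, j: 0.0)
        assert list(out) == [4, 7]

    def test_single_row_full_scan(self):
        costs = {0: 3.0, 1: 1.0, 2: 2.0}
        out = reduce_min_in_place(np.array([0, 1, 2]), 1, lambda p, j: costs[j])
        assert list(out) == [1]

    def test_tie_keeps_larger_index(self):
        out = reduce_min_in_place(np.array([0, 1]), 1, lambda p, j: 1.0)
        assert list(out) == [1]

    def test_two_row_hand_trace(self):
        M = [[1, 2, 3], [4, 3, 2]]
        out = reduce_min_in_place(np.array([0, 1, 2]), 2, lambda p, j: M[p][j])
        assert list(out) == [0, 2]

    def test_rejects_non_ascending(self):
        with pytest.raises(ValueError):
            reduce_min_in_place(np.array([3, 1, 2]), 1, lambda p, j: 0.0)

    def test_survivors_preserve_all_row_minima(self, rng):
        """Reduction keeps every row minimum, checked against a full scan."""
        for _ in range(50):
            seq = random_sequence(rng, nmax=30)
            n = seq.n
            q = int(rng.integers(1, n))
            S_prev = dp_tables(seq, q + 1)[0][q - 1]
            rows = np.arange(q, n)
            cols = np.arange(q, n)
            big = 4.0 * (seq.total_weight * (seq.values[-1] - seq.values[0]) ** 2 + 1)

            def cost(p, j, S_prev=S_prev, seq=seq, big=big, rows=rows):
                i = rows[p]
                if j > i:
                    return big * (1.0 + (j - i))
                return S_prev[j - 1] + seq.interval_stats(j, i)[1]

            stats = {}
            surv = reduce_min_in_place(cols.copy(), rows.size, cost, stats)
            assert surv.size <= rows.size
            assert set(surv).issubset(set(cols.tolist()))
            assert stats["iterations"] <= 2 * cols.size  # termination bound
            for p in range(rows.size):
                full = [cost(p, j) for j in cols]
                best = min(full)
                # the largest-index minimum must survive
                arg = cols[max(k for k, v in enumerate(full) if v == best)]
                assert arg in surv


class TestFillRowSmawk:
    def test_all_equal_values_tie_to_max_index(self):
        seq = WeightedSequence([5, 5, 5, 5])
        S0 = dp_tables(seq, 1)[0][0]
        S1, J1 = fill_row_smawk(1, S0, seq)
        assert list(J1[1:]) == [1, 2, 3]
        assert np.all(S1[1:] == 0.0)

    def test_known_row_values(self):
        seq = WeightedSequence([0, 1, 9, 10])
        S0 = dp_tables(seq, 1)[0][0]
        S1, J1 = fill_row_smawk(1, S0, seq)
        assert S1[0] == math.inf
        assert list(S1[1:]) == pytest.approx([0.0, 0.5, 1.0])
        assert list(J1[1:]) == [1, 2, 2]

    def test_empty_rows_is_noop(self):
        seq = WeightedSequence([0, 1, 9, 10])
        S0 = dp_tables(seq, 1)[0][0]
        S1, J1 = fill_row_smawk(1, S0, seq, rows=np.array([], dtype=np.int64))
        assert np.all(np.isinf(S1))

    def test_single_row_equals_linear_scan(self, rng):
        seq = random_sequence(rng, n=10)
        S0 = dp_tables(seq, 1)[0][0]
        S1, J1 = fill_row_smawk(1, S0, seq, rows=np.array([7]))
        costs = [S0[j - 1] + seq.interval_stats(j, 7)[1] for j in range(1, 8)]
        best = min(costs)
        assert S1[7] == best
        assert J1[7] == 1 + max(k for k, v in enumerate(costs) if v == best)


class TestSolveWuc:
    def test_three_cluster_example(self):
        seq = WeightedSequence([-1, 2, 4, 5, 6])
        sol = solve_wuc(seq, 3, 3)[0]
        assert list(sol.boundaries) == [-1, 0, 1, 4]
        assert sol.total_ssq == pytest.approx(2.0)

    def test_k_equals_n_is_free(self):
        seq = WeightedSequence([1, 3, 7, 20])
        sol = solve_wuc(seq, 4, 4)[0]
        assert sol.total_ssq == 0.0
        assert list(sol.assignments) == [0, 1, 2, 3]

    def test_k1_full_interval(self):
        seq = WeightedSequence([1, 2, 3])
        assert solve_wuc(seq, 1, 1)[0].total_ssq == pytest.approx(2.0)

    def test_weights_steer_the_split(self):
        seq = WeightedSequence([0, 1, 10], [1, 1, 8])
        sol = solve_wuc(seq, 2, 2)[0]
        assert list(sol.boundaries) == [-1, 1, 2]
        assert sol.total_ssq == pytest.approx(0.5)

    def test_kmax_clamped_to_distinct_values(self):
        seq = WeightedSequence([5, 5, 5, 5])
        with pytest.warns(UserWarning, match="clamp"):
            sols = solve_wuc(seq, 2, 2)
        assert sols[0].k == 1

    def test_oracle_agreement_small_instances(self, rng):
        for _ in range(40):
            seq = random_sequence(rng)
            k = int(rng.integers(1, min(seq.n, 4) + 1))
            lin = solve_wuc(seq, k, k, "linear")[0]
            quad = solve_wuc(seq, k, k, "quadratic")[0]
            ora = brute_force_oracle(seq, k)
            assert np.array_equal(lin.boundaries, quad.boundaries)
            assert np.array_equal(lin.boundaries, ora.boundaries)
            assert lin.total_ssq == quad.total_ssq
            assert lin.total_ssq == pytest.approx(ora.total_ssq, rel=1e-9, abs=1e-12)

    def test_total_ssq_non_increasing_in_k(self, rng):
        seq = random_sequence(rng, n=40, nmax=40)
        sols = solve_wuc(seq, 1, 10)
        ssqs = [s.total_ssq for s in sols]
        assert all(a >= b - 1e-12 for a, b in zip(ssqs, ssqs[1:]))

    def test_deterministic_repeat(self, rng):
        seq = random_sequence(rng, n=200, nmax=200)
        a = solve_wuc(seq, 1, 8)
        b = solve_wuc(seq, 1, 8)
        for s1, s2 in zip(a, b):
            assert s1.boundaries.tobytes() == s2.boundaries.tobytes()
            assert s1.total_ssq == s2.total_ssq

    def test_solution_invariants(self, rng):
        seq = random_sequence(rng, n=30, nmax=30)
        for sol in solve_wuc(seq, 1, 6):
            b = sol.boundaries
            assert b[0] == -1 and b[-1] == seq.n - 1
            assert np.all(np.diff(b) >= 1)  # contiguous non-empty clusters
            assert sol.total_ssq == pytest.approx(float(np.sum(sol.within_ssq)))
            assert np.all(np.diff(sol.assignments) >= 0)


class TestStructuralProperties:
    def test_concave_quadrangle_inequality(self, rng):
        for _ in range(100):
            seq = random_sequence(rng, nmax=20)
            n = seq.n
            idx = np.sort(rng.integers(0, n, size=4))
            i1, i2, i3, i4 = (int(v) for v in idx)
            s = lambda a, b: seq.interval_stats(a, b)[1] if a <= b else math.inf
            lhs = s(i2, i3) + s(i1, i4)
            rhs = s(i2, i4) + s(i1, i3)
            if math.isinf(rhs):
                continue
            scale = max(abs(lhs), abs(rhs), 1.0)
            assert lhs >= rhs - 1e-9 * scale

    def test_split_indices_row_monotone(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, nmax=40)
            kmax = min(seq.n_distinct(), 6)
            S, J = dp_tables(seq, kmax)
            for q in range(1, kmax):
                row = J[q, q:]
                assert np.all(np.diff(row) >= 0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.floats(-100, 100, allow_nan=False),
            st.floats(0.01, 10, allow_nan=False),
        ),
        min_size=2,
        max_size=10,
    ),
    k=st.integers(1, 4),
)
def test_property_linear_matches_oracle(data, k):
    """The SMAWK solver equals exhaustive enumeration on arbitrary data."""
    xs = sorted(v for v, _ in data)
    ws = [w for _, w in data]
    seq = WeightedSequence(xs, ws)
    k = min(k, seq.n_distinct())
    lin = solve_wuc(seq, k, k, "linear")[0]
    ora = brute_force_oracle(seq, k)
    assert lin.total_ssq == pytest.approx(ora.total_ssq, rel=1e-9, abs=1e-9)


class TestClusterEntryPoint:
    def test_unsorted_input_mapped_back(self):
        res = cluster([10.0, 0.0, 0.2, 9.8], k=2)
        assert list(res.labels) == [1, 0, 0, 1]

    def test_bic_selection_path(self):
        x = np.concatenate([np.zeros(20), np.full(20, 50.0)])
        res = cluster(x + np.linspace(0, 0.1, 40), kmin=1, kmax=5, select="bic")
        assert res.selected_k == 2
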