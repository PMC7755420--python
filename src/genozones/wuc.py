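"""Optimal weighted univariate clustering (WUC) in O(kn) time.

Partitions ``n`` sorted real values with non-negative weights into ``k``
contiguous clusters minimizing the weighted within-cluster sum of squared
distances (SSQ).  Because an optimal clustering of sorted data consists of
intervals, the problem is solved exactly by dynamic programming; each DP row
is filled in linear time with the SMAWK algorithm for totally monotone
matrices, using an in-place candidate-column reduction so that no matrix is
ever materialized.

Three solvers are provided:

* ``method="linear"``  — SMAWK-accelerated DP, O(kn) time, O(kn) space.
* ``method="quadratic"`` — plain row-fill DP, O(kn^2), used as a cross-check.
* :func:`brute_force_oracle` — exhaustive enumeration for tiny inputs, the
  independent test oracle.

All solvers are deterministic and break cost ties by preferring the largest
split index, so repeated runs (and the two DP solvers) produce identical
output.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WeightedSequence",
    "ClusterSolution",
    "interval_stats",
    "dp_candidate_cost",
    "reduce_min_in_place",
    "fill_row_smawk",
    "solve_wuc",
    "brute_force_oracle",
    "cluster",
]


class WeightedSequence:
    """Sorted values with non-negative weights and O(1) interval statistics.

    Prefix sums of ``y``, ``y*x`` and ``y*x**2`` (values shifted by the
    weighted median to limit cancellation) allow the weighted mean and the
    within-interval SSQ of any interval to be computed in constant time.

    Attributes
    ----------
    values, weights : ndarray of shape (n,)
    offset : float
        Stabilization shift (the weighted median of ``values``).
    cum_weight, cum_wx, cum_wx2 : ndarray of shape (n + 1,)
        Prefix sums with a leading zero, so index ``i + 1`` holds the sum
        over points ``0..i`` and index 0 plays the role of the empty prefix.
    """

    __slots__ = ("values", "weights", "offset", "cum_weight", "cum_wx", "cum_wx2")

    def __init__(self, values, weights=None):
        x = np.ascontiguousarray(values, dtype=np.float64)
        if x.ndim != 1 or x.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(np.diff(x) < 0):
            raise ValueError("values must be sorted in ascending order")
        if weights is None:
            y = np.ones_like(x)
        else:
            y = np.ascontiguousarray(weights, dtype=np.float64)
            if y.shape != x.shape:
                raise ValueError("weights must match values in length")
            if np.any(y < 0) or not np.all(np.isfinite(y)):
                raise ValueError("weights must be finite and non-negative")
            if not np.any(y > 0):
                raise ValueError("at least one weight must be positive")
        self.values = x
        self.weights = y
        self.offset = _weighted_median(x, y)
        shifted = x - self.offset
        wx = y * shifted
        self.cum_weight = np.concatenate(([0.0], np.cumsum(y)))
        self.cum_wx = np.concatenate(([0.0], np.cumsum(wx)))
        self.cum_wx2 = np.concatenate(([0.0], np.cumsum(wx * shifted)))

    @property
    def n(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.values.size

    @property
    def total_weight(self) -> float:
        return float(self.cum_weight[-1])

    def n_distinct(self) -> int:
        return int(1 + np.count_nonzero(np.diff(self.values) > 0))

    def interval_stats(self, j: int, i: int) -> tuple[float, float]:
        """Weighted mean and SSQ of points ``j..i`` in O(1).

        Returns ``(mean, inf)`` convention-free for ``j > i`` (empty
        interval); a zero-weight interval has SSQ 0 and the midpoint of its
        value range as mean.
        """
        n = self.values.size
        if not 0 <= i < n:
            raise IndexError(f"point index {i} out of range for n={n}")
        if j > i:
            return (math.nan, math.inf)
        if j < 0:
            raise IndexError("interval start must be >= 0")
        W = self.cum_weight[i + 1] - self.cum_weight[j]
        if W <= 0.0:
            return ((self.values[j] + self.values[i]) / 2.0, 0.0)
        mu = (self.cum_wx[i + 1] - self.cum_wx[j]) / W
        ssq = (self.cum_wx2[i + 1] - self.cum_wx2[j]) - W * mu * mu
        if ssq < 0.0:
            ssq = 0.0
        return (float(mu + self.offset), float(ssq))


def _weighted_median(x: np.ndarray, y: np.ndarray) -> float:
    cw = np.cumsum(y)
    total = cw[-1]
    if total <= 0:
        return float(x[x.size // 2])
    idx = int(np.searchsorted(cw, 0.5 * total))
    idx = min(idx, x.size - 1)
    return float(x[idx])


@dataclass
class ClusterSolution:
    """An optimal k-clustering of a :class:`WeightedSequence`.

    ``boundaries`` holds ``j_0 = -1 < j_1 < ... < j_k = n-1``; cluster ``q``
    covers points ``boundaries[q]+1 .. boundaries[q+1]`` of the sorted input.
    """

    k: int
    boundaries: np.ndarray
    centers: np.ndarray
    within_ssq: np.ndarray
    total_ssq: float
    assignments: np.ndarray = field(repr=False)

    def cluster_slices(self):
        b = self.boundaries
        return [slice(int(b[q]) + 1, int(b[q + 1]) + 1) for q in range(self.k)]


def interval_stats(seq: WeightedSequence, j: int, i: int) -> tuple[float, float]:
    """Module-level alias for :meth:`WeightedSequence.interval_stats`."""
    return seq.interval_stats(j, i)


def dp_candidate_cost(S_prev, seq: WeightedSequence, q: int, i: int, j: int) -> float:
    """Cost of ending cluster ``q`` at point ``i`` having started it at ``j``.

    Returns ``S[q-1, j-1] + s(j, i)`` inside the feasible triangle
    ``q <= j <= i`` and +inf outside it (the DP matrix padding).
    """
    n = seq.n
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError("row/column out of range")
    if j < q or j > i:
        return math.inf
    _, ssq = seq.interval_stats(j, i)
    prev = S_prev[j - 1] if j >= 1 else (0.0 if q == 0 else math.inf)
    return float(prev + ssq)


# ---------------------------------------------------------------------------
# SMAWK machinery
# ---------------------------------------------------------------------------


def reduce_min_in_place(cols, n_rows: int, cost, stats: dict | None = None):
    """Prune candidate columns to at most ``n_rows`` survivors, in place.

    ``cost(p, j)`` evaluates the implied totally monotone matrix at row
    position ``p`` (0-based among the rows) and column index ``j``.  Among
    equal-cost columns the larger index is kept (the tie rule used
    throughout the solver).  Every row minimum of the input candidate set is
    attained within the surviving columns; survivors are returned as a view
    of the (modified) input array.
    """
    cols = np.asarray(cols)
    if cols.ndim != 1:
        raise ValueError("candidate columns must be 1-D")
    if cols.size > 1 and np.any(np.diff(cols) <= 0):
        raise ValueError("candidate columns must be strictly ascending")
    M = int(cols.size)
    N = int(n_rows)
    if M <= N:
        if stats is not None:
            stats["iterations"] = 0
        return cols
    l = -1  # cols[0..l] examined and feasible so far
    r = 0  # cols[r..M-1] still to be examined
    iters = 0
    while (l + 1) + (M - r) > N:
        iters += 1
        p = l + 1
        j = cols[r]
        j_next = cols[r + 1]
        a = cost(p, j)
        b = cost(p, j_next)
        if a < b and p < N - 1:
            l += 1
            cols[l] = j
            r += 1
        elif a < b:  # p == N-1: column j_next can never host a row minimum
            cols[r + 1] = j
            r += 1
        else:  # a >= b: column j is infeasible (tie prefers the larger index)
            if p > 0:
                cols[r] = cols[l]
                l -= 1
            else:
                r += 1
    cols[l + 1 : N] = cols[r:M].copy()
    if stats is not None:
        stats["iterations"] = iters
    return cols[:N]


def _smawk(rows: np.ndarray, cols: np.ndarray, cost, S_row, J_row) -> None:
    """Row minima of a totally monotone matrix, largest-index tie rule.

    Writes results into ``S_row[i]``/``J_row[i]`` for every ``i`` in
    ``rows``.  Recurses on the odd rows, then fills even rows by scanning
    surviving columns between the bracketing odd-row argmins.
    """
    if rows.size == 0:
        return
    surv = reduce_min_in_place(
        cols.copy(), rows.size, lambda p, jj: cost(rows[p], jj)
    )
    if rows.size == 1:
        i = int(rows[0])
        best = math.inf
        best_j = int(surv[0])
        for jj in surv:
            c = cost(i, jj)
            if c <= best:
                best = c
                best_j = int(jj)
        S_row[i] = best
        J_row[i] = best_j
        return
    _smawk(rows[1::2], surv, cost, S_row, J_row)
    m = surv.size
    pos = 0
    for t in range(0, rows.size, 2):
        i = int(rows[t])
        if t + 1 < rows.size:
            stop = int(np.searchsorted(surv, J_row[rows[t + 1]]))
        else:
            stop = m - 1
        best = math.inf
        best_j = int(surv[pos])
        p = pos
        while p <= stop:
            jj = int(surv[p])
            c = cost(i, jj)
            if c <= best:
                best = c
                best_j = jj
            p += 1
        S_row[i] = best
        J_row[i] = best_j
        pos = stop


def _make_row_cost(seq: WeightedSequence, S_prev: np.ndarray, big: float):
    """Scalar cost closure A(q)[i, j] for one DP row.

    Entries with j > i are padded with values strictly increasing in j and
    larger than any attainable cost so the padded matrix stays totally
    monotone under the largest-index tie rule.  Plain-Python lists are used
    for fast scalar indexing.
    """
    Y = seq.cum_weight.tolist()
    wx = seq.cum_wx.tolist()
    wx2 = seq.cum_wx2.tolist()
    Sp = S_prev.tolist()

    def cost(i: int, j: int) -> float:
        if j > i:
            return big * (1.0 + (j - i))
        W = Y[i + 1] - Y[j]
        if W <= 0.0:
            s = 0.0
        else:
            mu = (wx[i + 1] - wx[j]) / W
            s = (wx2[i + 1] - wx2[j]) - W * mu * mu
            if s < 0.0:
                s = 0.0
        return Sp[j - 1] + s

    return cost


def fill_row_smawk(q: int, S_prev, seq: WeightedSequence, rows=None, cands=None):
    """Fill DP row ``q`` (all S[q, i], J[q, i]) via SMAWK in O(n).

    ``rows``/``cands`` default to ``q..n-1``; entries with ``i < q`` are
    infeasible and left at +inf.
    """
    n = seq.n
    S_row = np.full(n, np.inf)
    J_row = np.zeros(n, dtype=np.int64)
    if rows is None:
        rows = np.arange(q, n)
    else:
        rows = np.asarray(rows, dtype=np.int64)
    if cands is None:
        cands = np.arange(q, n)
    else:
        cands = np.asarray(cands, dtype=np.int64)
    if rows.size == 0:
        return S_row, J_row
    big = _padding_base(seq)
    cost = _make_row_cost(seq, np.asarray(S_prev, dtype=np.float64), big)
    _smawk(rows, cands, cost, S_row, J_row)
    return S_row, J_row


def _padding_base(seq: WeightedSequence) -> float:
    span = float(seq.values[-1] - seq.values[0])
    return 4.0 * (seq.total_weight * span * span + 1.0)


# ---------------------------------------------------------------------------
# DP drivers
# ---------------------------------------------------------------------------


def _fill_row0(seq: WeightedSequence) -> np.ndarray:
    Y, wx, wx2 = seq.cum_weight, seq.cum_wx, seq.cum_wx2
    W = Y[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = wx[1:] / W
        s = wx2[1:] - W * mu * mu
    s[W <= 0.0] = 0.0
    np.maximum(s, 0.0, out=s)
    return s


def _fill_row_quadratic(q: int, S_prev: np.ndarray, seq: WeightedSequence):
    """Reference O(n^2) row fill; arithmetic identical to the SMAWK path."""
    n = seq.n
    Y, wx, wx2 = seq.cum_weight, seq.cum_wx, seq.cum_wx2
    S_row = np.full(n, np.inf)
    J_row = np.zeros(n, dtype=np.int64)
    for i in range(q, n):
        js = np.arange(q, i + 1)
        W = Y[i + 1] - Y[js]
        with np.errstate(divide="ignore", invalid="ignore"):
            mu = (wx[i + 1] - wx[js]) / W
            s = (wx2[i + 1] - wx2[js]) - W * mu * mu
        s[W <= 0.0] = 0.0
        np.maximum(s, 0.0, out=s)
        costs = S_prev[js - 1] + s
        # last occurrence of the minimum implements the max-index tie rule
        jb = costs.size - 1 - int(np.argmin(costs[::-1]))
        S_row[i] = costs[jb]
        J_row[i] = js[jb]
    return S_row, J_row


def dp_tables(seq: WeightedSequence, kmax: int, method: str = "linear"):
    """Compute the full DP cost/split tables S and J (kmax rows)."""
    n = seq.n
    if not 1 <= kmax <= n:
        raise ValueError("kmax must be in [1, n]")
    if method not in ("linear", "quadratic"):
        raise ValueError(f"unknown method {method!r}")
    S = np.full((kmax, n), np.inf)
    J = np.zeros((kmax, n), dtype=np.int64)
    S[0] = _fill_row0(seq)
    for q in range(1, kmax):
        if method == "linear":
            S[q], J[q] = fill_row_smawk(q, S[q - 1], seq)
        else:
            S[q], J[q] = _fill_row_quadratic(q, S[q - 1], seq)
    return S, J


def _backtrack(J: np.ndarray, k: int, n: int) -> np.ndarray:
    b = np.empty(k + 1, dtype=np.int64)
    b[0] = -1
    b[k] = n - 1
    i = n - 1
    for q in range(k - 1, 0, -1):
        start = int(J[q, i])
        b[q] = start - 1
        i = start - 1
    return b


def _solution_from_boundaries(seq: WeightedSequence, b: np.ndarray) -> ClusterSolution:
    k = b.size - 1
    centers = np.empty(k)
    within = np.empty(k)
    assignments = np.empty(seq.n, dtype=np.int64)
    for q in range(k):
        j, i = int(b[q]) + 1, int(b[q + 1])
        centers[q], within[q] = seq.interval_stats(j, i)
        assignments[j : i + 1] = q
    total = 0.0
    for q in range(k):  # left-to-right accumulation matches the DP recurrence
        total += within[q]
    return ClusterSolution(
        k=k,
        boundaries=b,
        centers=centers,
        within_ssq=within,
        total_ssq=float(total),
        assignments=assignments,
    )


def solve_wuc(
    seq: WeightedSequence,
    kmin: int = 1,
    kmax: int | None = None,
    method: str = "linear",
) -> list[ClusterSolution]:
    """Globally optimal clusterings for every k in ``[kmin, kmax]``.

    Solving at ``kmax`` yields the solutions for all smaller k from the same
    DP tables.  ``kmax`` is clamped to the number of distinct values (extra
    clusters cannot reduce the SSQ below zero).
    """
    if kmax is None:
        kmax = kmin
    if not 1 <= kmin <= kmax:
        raise ValueError("need 1 <= kmin <= kmax")
    d = seq.n_distinct()
    if kmax > d:
        warnings.warn(
            f"kmax={kmax} exceeds the {d} distinct values; clamping", stacklevel=2
        )
        kmax = d
        kmin = min(kmin, kmax)
    S, J = dp_tables(seq, kmax, method=method)
    return [
        _solution_from_boundaries(seq, _backtrack(J, k, seq.n))
        for k in range(kmin, kmax + 1)
    ]


def brute_force_oracle(seq: WeightedSequence, k: int) -> ClusterSolution:
    """Exhaustive-enumeration solver for tiny inputs (the test oracle).

    Enumerates all C(n-1, k-1) boundary placements; among SSQ-minimal
    clusterings the one whose split indices are lexicographically largest
    from the last cluster backwards is returned, matching the DP tie rule.
    """
    n = seq.n
    if n > 16:
        raise ValueError("brute force restricted to n <= 16")
    if not 1 <= k <= n:
        raise ValueError("k out of range")
    best_total = math.inf
    best_b = None
    for splits in itertools.combinations(range(n - 1), k - 1):
        b = (-1, *splits, n - 1)
        total = 0.0
        for q in range(k):
            total += seq.interval_stats(b[q] + 1, b[q + 1])[1]
        key = tuple(reversed(b[1:-1]))
        if total < best_total or (
            total == best_total and key > tuple(reversed(best_b[1:-1]))
        ):
            best_total = total
            best_b = b
    return _solution_from_boundaries(seq, np.asarray(best_b, dtype=np.int64))


# ---------------------------------------------------------------------------
# public convenience entry point (handles unsorted input)
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Clustering of possibly-unsorted input, reported in original order."""

    solution: ClusterSolution
    order: np.ndarray
    labels: np.ndarray  # cluster index per input point, original order
    selected_k: int
    bic_table: "object | None" = None


def cluster(
    values,
    weights=None,
    k: int | None = None,
    kmin: int = 1,
    kmax: int | None = None,
    method: str = "linear",
    select: str = "bic",
) -> ClusterResult:
    """Cluster 1-D data, sorting internally and mapping labels back.

    With ``k`` given, solves exactly that size; otherwise searches
    ``[kmin, kmax]`` (default ``kmax = min(9, n)``) and, when
    ``select="bic"``, picks k by the Gaussian-mixture BIC.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("values must be 1-D")
    w = None if weights is None else np.asarray(weights, dtype=np.float64)
    order = np.argsort(x, kind="stable")
    seq = WeightedSequence(x[order], None if w is None else w[order])
    if k is not None:
        kmin = kmax = k
    elif kmax is None:
        kmax = min(9, seq.n)
    bic_table = None
    if select == "bic" and kmin < kmax:
        from .model_selection import select_k

        selected, bic_table, sol = select_k(seq, kmin, kmax, method=method)
    elif select in ("bic", "none"):
        sols = solve_wuc(seq, kmin, kmax, method=method)
        sol = sols[-1]
        selected = sol.k
        if select == "bic":
            from .model_selection import evaluate_bic_table

            bic_table = evaluate_bic_table(seq, sols)
    else:
        raise ValueError(f"unknown select mode {select!r}")
    labels = np.empty(seq.n, dtype=np.int64)
    labels[order] = sol.assignments
    return ClusterResult(
        solution=sol, order=order, labels=labels, selected_k=selected,
        bic_table=bic_table,
    )
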