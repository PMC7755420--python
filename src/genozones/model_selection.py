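"""Choosing the number of clusters by a Gaussian-mixture BIC.

Each cluster of an optimal weighted clustering parameterizes one component
of a Gaussian mixture: mixing proportion = cluster weight share, mean =
cluster center, variance = within-cluster weighted SSQ over cluster weight
(with a positive floor for degenerate clusters).  The weighted
log-likelihood of the full mixture density — not the hard-assignment
classification likelihood, which systematically over-splits overlapping
components — is penalized by the ``3k - 1`` free parameters; the k
maximizing the BIC wins, with ties going to the smallest k.

Weights are normalized to sum to the number of points before the
likelihood/penalty are computed, which makes the selection invariant to a
positive rescaling of all weights and reduces to the standard BIC for
unweighted data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .wuc import ClusterSolution, WeightedSequence, dp_tables, _backtrack, \
    _solution_from_boundaries

__all__ = ["BICResult", "gaussian_mixture_bic", "select_k", "evaluate_bic_table"]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class BICResult:
    """Per-k likelihoods/BIC values and the selected number of clusters."""

    per_k: dict  # k -> (log_likelihood, n_params, bic)
    selected_k: int

    def as_rows(self):
        return [
            {"k": k, "loglik": v[0], "n_params": v[1], "bic": v[2]}
            for k, v in sorted(self.per_k.items())
        ]


def _variance_floor(values: np.ndarray) -> float:
    """Variance of a uniform on one grid cell of the data's finest spacing."""
    gaps = np.diff(np.unique(values))
    if gaps.size == 0:
        scale = max(abs(float(values[0])), 1.0)
        return (1e-8 * scale) ** 2 / 12.0
    return float(gaps.min()) ** 2 / 12.0


def gaussian_mixture_bic(
    seq: WeightedSequence, sol: ClusterSolution
) -> tuple[float, int, float]:
    """(log-likelihood, n_params, bic) of the cluster-parameterized mixture.

    Zero-weight clusters contribute nothing to the likelihood (their mixing
    proportion is zero) and are reported with a warning.
    """
    x = seq.values
    y = seq.weights
    scale = seq.n / seq.total_weight  # normalize weights to sum to n
    floor = _variance_floor(x)
    n_eff = float(seq.n)
    comps = []
    for q, sl in enumerate(sol.cluster_slices()):
        W_c = float(np.sum(y[sl])) * scale
        if W_c <= 0.0:
            warnings.warn(f"cluster {q} has zero total weight; excluded from BIC")
            continue
        ssq_c = float(sol.within_ssq[q]) * scale
        comps.append((W_c / n_eff, float(sol.centers[q]), max(ssq_c / W_c, floor)))
    # weighted log-likelihood of the mixture density, via log-sum-exp
    log_terms = np.stack(
        [
            math.log(p) - 0.5 * (_LOG_2PI + math.log(var))
            - (x - mu) ** 2 / (2.0 * var)
            for p, mu, var in comps
        ]
    )
    loglik = float(np.sum(y * scale * logsumexp(log_terms, axis=0)))
    n_params = 3 * sol.k - 1
    bic = loglik - 0.5 * n_params * math.log(n_eff)
    return (float(loglik), int(n_params), float(bic))


def evaluate_bic_table(seq: WeightedSequence, solutions: list[ClusterSolution]) -> BICResult:
    per_k = {}
    for sol in solutions:
        per_k[sol.k] = gaussian_mixture_bic(seq, sol)
    best_k = None
    best_bic = -math.inf
    for k in sorted(per_k):
        b = per_k[k][2]
        if b > best_bic:  # strict: ties keep the smallest k
            best_bic = b
            best_k = k
    return BICResult(per_k=per_k, selected_k=best_k)


def select_k(
    seq: WeightedSequence,
    kmin: int,
    kmax: int,
    method: str = "linear",
) -> tuple[int, BICResult, ClusterSolution]:
    """Solve once at ``kmax`` and pick k in ``[kmin, kmax]`` by BIC."""
    if not 1 <= kmin <= kmax:
        raise ValueError("need 1 <= kmin <= kmax")
    d = seq.n_distinct()
    if kmax > d:
        warnings.warn(f"kmax={kmax} exceeds the {d} distinct values; clamping")
        kmax = d
        kmin = min(kmin, kmax)
    S, J = dp_tables(seq, kmax, method=method)
    solutions = [
        _solution_from_boundaries(seq, _backtrack(J, k, seq.n))
        for k in range(kmin, kmax + 1)
    ]
    result = evaluate_bic_table(seq, solutions)
    best = solutions[result.selected_k - kmin]
    return (result.selected_k, result, best)
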