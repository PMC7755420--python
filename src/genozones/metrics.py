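"""Cluster-quality measures used for validation.

Average silhouette width (ASW) is an internal measure: for each point,
``(b - a) / max(a, b)`` with ``a`` the mean distance to its own cluster and
``b`` the smallest mean distance to another cluster; values near 1 indicate
compact, well-separated clusters.  On the line the metric is the absolute
difference.  The adjusted Rand index (ARI) is an external measure comparing
a clustering against ground truth, adjusted for chance agreement.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

__all__ = ["average_silhouette_width", "adjusted_rand_index"]


def average_silhouette_width(values, labels) -> float:
    """ASW with the absolute-difference metric; singleton clusters
    contribute 0; undefined (error) for fewer than two clusters."""
    x = np.asarray(values, dtype=np.float64)
    lab = np.asarray(labels)
    if x.shape != lab.shape or x.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D arrays")
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    D = np.abs(x[:, None] - x[None, :])
    s = np.zeros(x.size)
    masks = {c: lab == c for c in uniq}
    for i in range(x.size):
        own = masks[lab[i]]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton: s = 0
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, masks[c]].mean() for c in uniq if c != lab[i])
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Pair-counting ARI; 1 for identical partitions up to relabeling."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label arrays must have equal length")
    if a.size < 2:
        raise ValueError("need at least two points")
    return float(adjusted_rand_score(a, b))
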