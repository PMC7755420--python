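"""Cross-cancer-type loci: zone-map intersection and polarity conservation.

Because zone boundaries differ between cancer types, cross-type comparison
uses *loci* — the intervals between consecutive breakpoints of the union of
all zone boundaries on a chromosome.  Each locus lies inside exactly one
zone of every contributing map and inherits that zone's polarity call.  A
locus is *conserved* when at least 80% (``ceil(0.8 * T)`` of ``T`` types,
so 14 of 17) of cancer types share one polarity sign; by default only
outstanding (significant) calls count toward conservation.  A permutation
test shuffling each type's zone labels gives the chance level of the
conserved-locus count.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "intersect_zone_maps",
    "conserved_loci",
    "conservation_permutation_test",
]

LOCUS_BASE_COLUMNS = ["chrom", "start", "end"]


def _zone_intervals(calls: pd.DataFrame, chrom: str):
    sub = calls[calls["chrom"] == chrom].sort_values("start")
    return (
        sub["start"].to_numpy(dtype=np.float64),
        sub["end"].to_numpy(dtype=np.float64),
        sub["polarity"].to_numpy(),
        sub["outstanding"].to_numpy(dtype=bool),
    )


def intersect_zone_maps(calls_by_type: dict) -> pd.DataFrame:
    """Loci from the breakpoint union of per-type zone calls.

    ``calls_by_type`` maps cancer type -> per-zone call frame (columns
    chrom/start/end/polarity/outstanding, as produced by
    ``call_zone_polarity``).  Returns one row per locus with a
    ``polarity_<type>`` and ``outstanding_<type>`` column per type.
    Chromosome sets are intersected with a warning when they differ.
    """
    if not calls_by_type:
        raise ValueError("need at least one zone map")
    types = sorted(calls_by_type)
    chrom_sets = [set(calls_by_type[t]["chrom"].unique()) for t in types]
    common = set.intersection(*chrom_sets)
    if any(cs != common for cs in chrom_sets):
        warnings.warn("chromosome sets differ between maps; using intersection")
    rows = []
    for chrom in sorted(common, key=_chrom_sort_key):
        bnds = []
        per_type = {}
        for t in types:
            starts, ends, pol, outs = _zone_intervals(calls_by_type[t], chrom)
            per_type[t] = (starts, ends, pol, outs)
            bnds.append(starts)
            bnds.append(ends[-1:])
        cuts = np.unique(np.concatenate(bnds))
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            row = {"chrom": chrom, "start": float(lo), "end": float(hi)}
            for t in types:
                starts, ends, pol, outs = per_type[t]
                zi = int(np.searchsorted(starts, lo, side="right")) - 1
                if zi < 0 or lo >= ends[zi]:
                    row[f"polarity_{t}"] = "none"
                    row[f"outstanding_{t}"] = False
                else:
                    row[f"polarity_{t}"] = pol[zi]
                    row[f"outstanding_{t}"] = bool(outs[zi])
            rows.append(row)
    cols = LOCUS_BASE_COLUMNS + [f"polarity_{t}" for t in types] + [
        f"outstanding_{t}" for t in types
    ]
    return pd.DataFrame(rows, columns=cols)


def _chrom_sort_key(c: str):
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


def conserved_loci(
    loci: pd.DataFrame,
    min_fraction: float = 0.8,
    require_outstanding: bool = True,
) -> pd.DataFrame:
    """Flag loci whose polarity sign is shared by >= ceil(min_fraction*T)
    cancer types (counting only outstanding calls unless disabled)."""
    types = [c.removeprefix("polarity_") for c in loci.columns
             if c.startswith("polarity_")]
    T = len(types)
    if T == 0:
        raise ValueError("no cancer-type polarity columns present")
    need = math.ceil(min_fraction * T)
    out = loci.copy()
    pol = np.stack([out[f"polarity_{t}"].to_numpy() for t in types], axis=1)
    if require_outstanding:
        outs = np.stack(
            [out[f"outstanding_{t}"].to_numpy(dtype=bool) for t in types], axis=1
        )
        pol = np.where(outs, pol, "none")
    n_pos = (pol == "+").sum(axis=1)
    n_neg = (pol == "-").sum(axis=1)
    out["n_pos_types"] = n_pos
    out["n_neg_types"] = n_neg
    out["conserved"] = np.maximum(n_pos, n_neg) >= need
    out["conserved_sign"] = np.where(
        ~out["conserved"], "none", np.where(n_pos >= n_neg, "+", "-")
    )
    return out


def _conserved_count(loci_zone_idx, labels_by_type, need):
    """Count conserved loci given per-type zone labels.

    ``loci_zone_idx``: T x n_loci int matrix (zone index per locus, -1 for
    uncovered); ``labels_by_type``: list of (polarity array, outstanding
    array) per type.
    """
    T, n_loci = loci_zone_idx.shape
    n_pos = np.zeros(n_loci, dtype=np.int64)
    n_neg = np.zeros(n_loci, dtype=np.int64)
    for t in range(T):
        pol, outs = labels_by_type[t]
        zi = loci_zone_idx[t]
        covered = zi >= 0
        eff = np.where(covered & outs[np.clip(zi, 0, None)], pol[np.clip(zi, 0, None)], "none")
        n_pos += eff == "+"
        n_neg += eff == "-"
    return int(np.sum(np.maximum(n_pos, n_neg) >= need))


def conservation_permutation_test(
    calls_by_type: dict,
    B: int = 999,
    seed: int = 0,
    min_fraction: float = 0.8,
) -> dict:
    """Permutation p-value for the conserved-locus count.

    Within each cancer type the (polarity, outstanding) labels are permuted
    across that type's zones, preserving the type's polarity composition;
    ``p = (1 + #{perm >= observed}) / (B + 1)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    types = sorted(calls_by_type)
    T = len(types)
    need = math.ceil(min_fraction * T)
    loci = intersect_zone_maps(calls_by_type)
    n_loci = len(loci)
    # per type: zone label arrays plus the locus -> zone index map
    labels = []
    zone_idx = np.full((T, n_loci), -1, dtype=np.int64)
    lo = loci["start"].to_numpy()
    chroms = loci["chrom"].to_numpy()
    for ti, t in enumerate(types):
        calls = calls_by_type[t]
        pol_all = []
        out_all = []
        offset = 0
        for chrom in calls["chrom"].unique():
            starts, ends, pol, outs = _zone_intervals(calls, chrom)
            sel = chroms == chrom
            zi = np.searchsorted(starts, lo[sel], side="right") - 1
            inside = (zi >= 0) & (lo[sel] < ends[np.clip(zi, 0, None)])
            zi = np.where(inside, zi + offset, -1)
            zone_idx[ti, sel] = zi
            pol_all.append(pol)
            out_all.append(outs)
            offset += starts.size
        labels.append((np.concatenate(pol_all), np.concatenate(out_all)))
    observed = _conserved_count(zone_idx, labels, need)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(B):
        perm_labels = []
        for pol, outs in labels:
            order = rng.permutation(pol.size)
            perm_labels.append((pol[order], outs[order]))
        if _conserved_count(zone_idx, perm_labels, need) >= observed:
            ge += 1
    return {
        "observed_conserved": observed,
        "p": (1 + ge) / (B + 1),
        "permutations": B,
    }
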