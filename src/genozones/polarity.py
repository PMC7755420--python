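"""Matched-pair polarity calls and per-zone contingency statistics.

A gene (or a zone, for copy-number data) is *positive* in a matched
tumor-normal pair when its activity rises by more than 5%:
``log((tumor+1)/(normal+1)) > log(1.05)``, *negative* below ``-log(1.05)``
and *none* otherwise.  A zone's polarity is the sign of the difference
between its positive and negative (gene, patient-pair) observation counts.
Significance is a Pearson chi-squared test (1 df, no continuity correction)
contrasting the in-zone positive/negative split against the rest of the
genome, Benjamini-Hochberg adjusted across all testable zones of the cancer
type; a polarized zone with adjusted p <= 0.05 is called *outstanding*.

For somatic copy-number data the same machinery runs on zone-level copy
numbers (segment-length-weighted averages), with (zone, patient) as the
observation unit.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pair_polarity",
    "zone_polarity_call",
    "zone_chi2",
    "bh_adjust",
    "matched_pairs",
    "gene_pair_polarities",
    "call_zone_polarity",
    "scna_zone_value",
    "call_scna_polarity",
    "outstanding_count_permutation_test",
]

DEFAULT_RATIO = 1.05
DEFAULT_ALPHA = 0.05

CALL_COLUMNS = [
    "zone_id", "chrom", "start", "end", "n_pos", "n_neg",
    "polarity", "chi2", "p", "p_adj", "outstanding",
]


def pair_polarity(tumor: float, normal: float, threshold: float = DEFAULT_RATIO) -> str:
    """Polarity of one matched pair: '+', '-' or 'none' (strict 5% rule)."""
    if tumor < 0 or normal < 0:
        raise ValueError("activity levels must be non-negative")
    lr = math.log((tumor + 1.0) / (normal + 1.0))
    t = math.log(threshold)
    if lr > t:
        return "+"
    if lr < -t:
        return "-"
    return "none"


def _pair_polarity_vec(tumor: np.ndarray, normal: np.ndarray,
                       threshold: float = DEFAULT_RATIO) -> np.ndarray:
    """Vectorized pair polarity as +1 / -1 / 0."""
    if np.any(tumor < 0) or np.any(normal < 0):
        raise ValueError("activity levels must be non-negative")
    lr = np.log((tumor + 1.0) / (normal + 1.0))
    t = math.log(threshold)
    return np.where(lr > t, 1, np.where(lr < -t, -1, 0)).astype(np.int8)


def zone_polarity_call(n_pos: int, n_neg: int) -> str:
    """Zone polarity: the sign of ``n_pos - n_neg`` ('none' on a tie)."""
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    if n_pos > n_neg:
        return "+"
    if n_pos < n_neg:
        return "-"
    return "none"


def zone_chi2(in_pos: int, in_neg: int, out_pos: int, out_neg: int):
    """Pearson chi-squared (1 df, no continuity correction) on the 2x2
    table rows=(positive, negative) x cols=(in zone, outside zone).

    Returns ``(chi2, p)``; ``(nan, nan)`` when any marginal is zero (the
    zone is untestable and excluded from multiple-testing adjustment).
    """
    counts = np.array([[in_pos, out_pos], [in_neg, out_neg]], dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        return (math.nan, math.nan)
    chi2, p, _, _ = sps.chi2_contingency(counts, correction=False)
    return (float(chi2), float(p))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN entries, i.e.
    untestable zones, are passed through and excluded from m)."""
    p = np.asarray(pvalues, dtype=np.float64)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def matched_pairs(samples: pd.DataFrame) -> pd.DataFrame:
    """One (tumor, normal) sample pair per patient.

    Patients lacking either condition are dropped; when a patient has
    several profiles of one condition the lexicographically smallest
    sample id is used, so the choice is deterministic.
    """
    req = {"sample_id", "patient_id", "condition"}
    if not req.issubset(samples.columns):
        raise ValueError(f"sample sheet needs columns {sorted(req)}")
    bad = set(samples["condition"]) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    rows = []
    for patient, grp in samples.groupby("patient_id"):
        t = sorted(grp.loc[grp["condition"] == "tumor", "sample_id"])
        n = sorted(grp.loc[grp["condition"] == "normal", "sample_id"])
        if t and n:
            rows.append({"patient_id": patient, "tumor_sample": t[0],
                         "normal_sample": n[0]})
    return pd.DataFrame(rows, columns=["patient_id", "tumor_sample", "normal_sample"])


def gene_pair_polarities(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    threshold: float = DEFAULT_RATIO,
) -> pd.DataFrame:
    """Per-gene per-patient polarity observations (+1/-1/0).

    Returns a genes x patients integer frame; only one matched pair per
    patient enters, regardless of how many profiles the patient has.
    """
    pairs = matched_pairs(samples)
    if pairs.empty:
        raise ValueError("no patient with both tumor and normal samples")
    out = {}
    for _, row in pairs.iterrows():
        t = expr[row["tumor_sample"]].to_numpy(dtype=np.float64)
        n = expr[row["normal_sample"]].to_numpy(dtype=np.float64)
        out[row["patient_id"]] = _pair_polarity_vec(t, n, threshold)
    return pd.DataFrame(out, index=expr.index)


def _counts_per_unit(polarities: pd.DataFrame) -> pd.DataFrame:
    arr = polarities.to_numpy()
    return pd.DataFrame(
        {
            "n_pos": (arr == 1).sum(axis=1),
            "n_neg": (arr == -1).sum(axis=1),
        },
        index=polarities.index,
    )


def call_zone_polarity(
    zone_map,
    polarities: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-zone polarity calls for one cancer type.

    ``polarities`` is the genes x patients +1/-1/0 frame from
    :func:`gene_pair_polarities`.  Counts are (gene, patient-pair)
    observations; the background of each zone is the genome-wide total over
    all zones minus the zone itself.
    """
    zframe = zone_map.to_frame()
    gene_zone = zone_map.gene_to_zone()
    per_gene = _counts_per_unit(polarities)
    unassigned = per_gene.index.difference(list(gene_zone))
    if len(unassigned):
        warnings.warn(
            f"{len(unassigned)} observed gene(s) fall in no zone; "
            "they count toward the background only"
        )
    zone_of = per_gene.index.to_series().map(gene_zone)
    grouped = per_gene.groupby(zone_of).sum()
    tot_pos = int(per_gene["n_pos"].sum())
    tot_neg = int(per_gene["n_neg"].sum())
    rows = []
    for _, z in zframe.iterrows():
        zid = z["zone_id"]
        n_pos = int(grouped["n_pos"].get(zid, 0))
        n_neg = int(grouped["n_neg"].get(zid, 0))
        pol = zone_polarity_call(n_pos, n_neg)
        if n_pos + n_neg == 0:
            chi2 = p = math.nan
        else:
            chi2, p = zone_chi2(n_pos, n_neg, tot_pos - n_pos, tot_neg - n_neg)
        rows.append(
            {
                "zone_id": zid, "chrom": z["chrom"], "start": z["start"],
                "end": z["end"], "n_pos": n_pos, "n_neg": n_neg,
                "polarity": pol, "chi2": chi2, "p": p,
            }
        )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS[:-2])
    calls["p_adj"] = bh_adjust(calls["p"])
    calls["outstanding"] = (calls["p_adj"] <= alpha) & (calls["polarity"] != "none")
    return calls


# ---------------------------------------------------------------------------
# somatic copy number
# ---------------------------------------------------------------------------


def scna_zone_value(segments: pd.DataFrame, zone) -> float:
    """Segment-length-weighted average copy number of one sample in a zone.

    ``segments`` rows (one sample, columns chrom/start/end/value in linear
    copy number) are clipped to the zone; NaN when nothing overlaps.
    """
    seg = segments[segments["chrom"] == zone.chrom]
    if len(seg):
        s = seg.sort_values("start")
        if np.any(s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]):
            raise ValueError("overlapping segments within one sample")
    lo = np.maximum(seg["start"].to_numpy(dtype=np.float64), zone.lower)
    hi = np.minimum(seg["end"].to_numpy(dtype=np.float64), zone.upper)
    olap = np.maximum(hi - lo, 0.0)
    total = olap.sum()
    if total <= 0:
        return math.nan
    return float(np.sum(olap * seg["value"].to_numpy(dtype=np.float64)) / total)


def zone_copy_numbers(zone_map, segments: pd.DataFrame) -> pd.DataFrame:
    """Zones x samples matrix of zone copy numbers."""
    zframe = zone_map.to_frame()
    sample_ids = sorted(segments["sample_id"].unique())
    data = {}
    for sid in sample_ids:
        seg = segments[segments["sample_id"] == sid]
        vals = []
        for chrom in zframe["chrom"].unique():
            sub = zframe[zframe["chrom"] == chrom]
            for _, z in sub.iterrows():
                vals.append(
                    scna_zone_value(
                        seg,
                        _ZoneView(chrom, float(z["start"]), float(z["end"])),
                    )
                )
        data[sid] = vals
    return pd.DataFrame(data, index=zframe["zone_id"])


class _ZoneView:
    __slots__ = ("chrom", "lower", "upper")

    def __init__(self, chrom, lower, upper):
        self.chrom = chrom
        self.lower = lower
        self.upper = upper


def call_scna_polarity(
    zone_map,
    segments: pd.DataFrame,
    samples: pd.DataFrame,
    threshold: float = DEFAULT_RATIO,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Zone SCNA polarity calls; observation unit is (zone, patient).

    Zone copy numbers of each patient's tumor/normal pair go through the
    same 5% polarity rule; the contingency background is all zones of the
    map.
    """
    zcn = zone_copy_numbers(zone_map, segments)
    pairs = matched_pairs(samples)
    pol = {}
    for _, row in pairs.iterrows():
        ts, ns = row["tumor_sample"], row["normal_sample"]
        if ts not in zcn.columns or ns not in zcn.columns:
            continue
        t = zcn[ts].to_numpy(dtype=np.float64)
        n = zcn[ns].to_numpy(dtype=np.float64)
        ok = ~(np.isnan(t) | np.isnan(n))
        v = np.zeros(t.shape, dtype=np.int8)
        v[ok] = _pair_polarity_vec(t[ok], n[ok], threshold)
        pol[row["patient_id"]] = v
    if not pol:
        raise ValueError("no matched pair with copy-number profiles")
    polf = pd.DataFrame(pol, index=zcn.index)
    per_zone = _counts_per_unit(polf)
    tot_pos = int(per_zone["n_pos"].sum())
    tot_neg = int(per_zone["n_neg"].sum())
    zframe = zone_map.to_frame().set_index("zone_id")
    rows = []
    for zid, cnt in per_zone.iterrows():
        n_pos, n_neg = int(cnt["n_pos"]), int(cnt["n_neg"])
        polcall = zone_polarity_call(n_pos, n_neg)
        if n_pos + n_neg == 0:
            chi2 = p = math.nan
        else:
            chi2, p = zone_chi2(n_pos, n_neg, tot_pos - n_pos, tot_neg - n_neg)
        z = zframe.loc[zid]
        rows.append(
            {
                "zone_id": zid, "chrom": z["chrom"], "start": z["start"],
                "end": z["end"], "n_pos": n_pos, "n_neg": n_neg,
                "polarity": polcall, "chi2": chi2, "p": p,
            }
        )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS[:-2])
    calls["p_adj"] = bh_adjust(calls["p"])
    calls["outstanding"] = (calls["p_adj"] <= alpha) & (calls["polarity"] != "none")
    return calls


# ---------------------------------------------------------------------------
# permutation test on the outstanding-zone count
# ---------------------------------------------------------------------------


def _chi2_vec(n_pos, n_neg, tot_pos, tot_neg):
    """Closed-form 2x2 Pearson statistic and p, vectorized over zones."""
    a = n_pos.astype(np.float64)
    c = n_neg.astype(np.float64)
    b = tot_pos - a
    d = tot_neg - c
    N = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = N * (a * d - b * c) ** 2 / denom
    ok = denom > 0
    p = np.full(a.shape, np.nan)
    p[ok] = sps.chi2.sf(chi2[ok], 1)
    chi2[~ok] = np.nan
    return chi2, p


def _outstanding_count(pos, neg, tot_pos, tot_neg, alpha):
    _, p = _chi2_vec(pos, neg, tot_pos, tot_neg)
    p_adj = bh_adjust(p)
    polarized = pos != neg
    return int(np.sum((p_adj <= alpha) & polarized))


def outstanding_count_permutation_test(
    zone_map,
    polarities: pd.DataFrame,
    B: int = 199,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> dict:
    """Permutation p-value for the observed number of outstanding zones.

    The gene-to-zone assignment is shuffled uniformly (zone sizes in genes
    and each gene's own observation profile are preserved); the outstanding
    count is recomputed for each permutation and
    ``p = (1 + #{perm >= observed}) / (B + 1)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    gene_zone = zone_map.gene_to_zone()
    per_gene = _counts_per_unit(polarities)
    per_gene = per_gene.loc[per_gene.index.intersection(list(gene_zone))]
    zone_ids = sorted({gene_zone[g] for g in per_gene.index})
    zidx = {z: i for i, z in enumerate(zone_ids)}
    assign = np.array([zidx[gene_zone[g]] for g in per_gene.index])
    pos = per_gene["n_pos"].to_numpy(dtype=np.int64)
    neg = per_gene["n_neg"].to_numpy(dtype=np.int64)
    nz = len(zone_ids)
    tot_pos = float(pos.sum())
    tot_neg = float(neg.sum())

    def count(assignment):
        zp = np.bincount(assignment, weights=pos, minlength=nz)
        zn = np.bincount(assignment, weights=neg, minlength=nz)
        return _outstanding_count(zp, zn, tot_pos, tot_neg, alpha)

    observed = count(assign)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(B):
        perm = rng.permutation(assign)
        if count(perm) >= observed:
            ge += 1
    return {
        "observed_outstanding": observed,
        "p": (1 + ge) / (B + 1),
        "permutations": B,
    }
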