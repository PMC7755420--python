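"""Expression-weighted genomic zone mapping.

Transcription start sites (TSS) on each chromosome are clustered with the
weighted univariate solver, weighting every gene by its pooled expression
over all tumor and matched-normal profiles.  Clusters are then converted to
genomic *zones* by adaptive-histogram boundary rules: a cluster's zone may
extend beyond its outermost TSS by at most the largest gap between
consecutive member TSS, adjacent zones shrink to their midpoint when their
tentative extents reach it, and any remaining gene-free stretch (e.g. a
centromere) becomes its own empty zone.  Zones therefore tile the
chromosome and may outnumber clusters.

Coordinates are 0-based half-open throughout; zone boundaries are
real-valued (midpoints may fall between bases).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_selection import select_k
from .wuc import ClusterSolution, WeightedSequence

__all__ = [
    "GeneRecord",
    "Zone",
    "ZoneMap",
    "tss_position",
    "compute_kmax",
    "cluster_chromosome",
    "adaptive_zones",
    "build_zone_map",
    "bootstrap_zone_stability",
]

DEFAULT_RESOLUTION = 1_000_000  # 1 Mb, the typical size of a TAD


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval (0-based half-open) with strand and derived TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return tss_position(self)


def tss_position(gene: GeneRecord) -> int:
    """Transcription start: the start coordinate on the forward strand,
    otherwise the last covered base (``end - 1`` in half-open coordinates)."""
    if gene.strand == "+":
        return gene.start
    if gene.strand == "-":
        return gene.end - 1
    raise ValueError(f"{gene.gene_id}: unknown strand {gene.strand!r}")


def add_tss(genes: pd.DataFrame) -> pd.DataFrame:
    """Vectorized TSS column for an annotation frame (gene_id, chrom,
    start, end, strand); genes with unknown strand are dropped with a
    warning."""
    bad = ~genes["strand"].isin(["+", "-"])
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} gene(s) with unknown strand")
        genes = genes[~bad]
    out = genes.copy()
    out["tss"] = np.where(out["strand"] == "+", out["start"], out["end"] - 1)
    return out


def compute_kmax(L: float, G: int, r: float = DEFAULT_RESOLUTION) -> int:
    """Upper bound on clusters per chromosome: at least 20, at least 5
    genes per cluster on average, average cluster width at least ``r``."""
    if L <= 0 or G < 1 or r <= 0:
        raise ValueError("need L > 0, G >= 1, r > 0")
    return max(20, min(G // 5, math.ceil(L / r)))


@dataclass
class Zone:
    chrom: str
    lower: float
    upper: float
    member_genes: list = field(default_factory=list)
    is_empty: bool = True
    cluster_index: int | None = None

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"zone on {self.chrom}: lower must be < upper")
        self.is_empty = len(self.member_genes) == 0

    @property
    def length(self) -> float:
        return self.upper - self.lower


@dataclass
class ZoneMap:
    """Ordered, tiling zone lists per chromosome plus run metadata."""

    zones: dict  # chrom -> list[Zone]
    meta: dict = field(default_factory=dict)  # chrom -> {k, kmax, resolution, ...}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.zones, key=_chrom_sort_key):
            for idx, z in enumerate(self.zones[chrom]):
                rows.append(
                    {
                        "chrom": chrom,
                        "start": z.lower,
                        "end": z.upper,
                        "zone_id": f"{chrom}_{idx:04d}",
                        "n_genes": len(z.member_genes),
                        "is_empty": z.is_empty,
                    }
                )
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "zone_id", "n_genes", "is_empty"]
        )

    def gene_to_zone(self) -> dict:
        out = {}
        for chrom in self.zones:
            for idx, z in enumerate(self.zones[chrom]):
                for g in z.member_genes:
                    out[g] = f"{chrom}_{idx:04d}"
        return out

    def n_zones(self) -> int:
        return sum(len(v) for v in self.zones.values())


def _chrom_sort_key(c: str):
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


def cluster_chromosome(
    genes: pd.DataFrame,
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    r: float = DEFAULT_RESOLUTION,
    chrom_length: float | None = None,
    method: str = "linear",
):
    """Cluster one chromosome's TSS weighted by pooled expression.

    ``genes`` must carry a ``tss`` column and be restricted to one
    chromosome; ``expr`` is a genes x samples CPM table.  All tumor and
    normal profiles of every patient are pooled for the weights.  Returns
    ``(solution, order, info)`` where ``order`` sorts genes by TSS and
    ``info`` carries k, kmax and the BIC table.
    """
    pooled = [s for s in samples["sample_id"] if s in expr.columns]
    if not pooled:
        raise ValueError("no sample sheet sample found in the expression table")
    sub = expr.reindex(genes["gene_id"]).fillna(0.0)
    weights = sub[pooled].sum(axis=1).to_numpy(dtype=np.float64)
    positions = genes["tss"].to_numpy(dtype=np.float64)
    order = np.argsort(positions, kind="stable")
    pos_sorted = positions[order]
    w_sorted = weights[order]
    L = float(chrom_length) if chrom_length is not None else float(genes["end"].max())
    G = len(genes)
    kmax = compute_kmax(L, G, r)
    n_distinct = int(1 + np.count_nonzero(np.diff(pos_sorted) > 0))
    if n_distinct < 2:
        warnings.warn("fewer than 2 distinct TSS; falling back to a single cluster")
        seq = WeightedSequence(pos_sorted, np.maximum(w_sorted, 0.0))
        from .wuc import solve_wuc

        sol = solve_wuc(seq, 1, 1)[0]
        return sol, order, {"k": 1, "kmax": kmax, "resolution": r, "L": L, "bic": None}
    kmax_eff = min(kmax, n_distinct)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seq = WeightedSequence(pos_sorted, w_sorted)
        selected, bic, sol = select_k(seq, 2, kmax_eff, method=method)
    return sol, order, {
        "k": selected,
        "kmax": kmax,
        "resolution": r,
        "L": L,
        "bic": bic,
    }


def adaptive_zones(
    sol: ClusterSolution, positions: np.ndarray, chrom_length: float
) -> list[tuple[float, float, int | None]]:
    """Convert ordered clusters into tiling ``(lower, upper, cluster)`` zones.

    Gene-free residual stretches get ``cluster=None`` (empty zones).  A
    cluster whose member positions are all identical has no internal gap and
    extends to the midpoints with its neighbors (or the chromosome ends).
    """
    k = sol.k
    spans = []
    gaps = []
    for sl in sol.cluster_slices():
        p = positions[sl]
        spans.append((float(p[0]), float(p[-1])))
        d = np.diff(p)
        g = float(d.max()) if d.size and d.max() > 0 else math.inf
        gaps.append(g)
    lo = [a - g for (a, _), g in zip(spans, gaps)]
    hi = [b + g for (_, b), g in zip(spans, gaps)]
    for c in range(k - 1):
        m = (spans[c][1] + spans[c + 1][0]) / 2.0
        if hi[c] >= m:
            hi[c] = m
        if lo[c + 1] <= m:
            lo[c + 1] = m
    lo = [max(v, 0.0) for v in lo]
    hi = [min(v, float(chrom_length)) for v in hi]
    zones: list[tuple[float, float, int | None]] = []
    cursor = 0.0
    for c in range(k):
        if lo[c] > cursor:
            zones.append((cursor, lo[c], None))
        assert hi[c] > lo[c], "adjacent tentative zones cannot overlap"
        zones.append((lo[c], hi[c], c))
        cursor = hi[c]
    if cursor < chrom_length:
        zones.append((cursor, float(chrom_length), None))
    return zones


def build_zone_map(
    genes: pd.DataFrame,
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    resolution: float = DEFAULT_RESOLUTION,
    chrom_sizes: dict | None = None,
    method: str = "linear",
) -> ZoneMap:
    """Full zone map over every chromosome present in the annotation."""
    if "tss" not in genes.columns:
        genes = add_tss(genes)
    zones: dict[str, list[Zone]] = {}
    meta: dict[str, dict] = {}
    for chrom in sorted(genes["chrom"].unique(), key=_chrom_sort_key):
        sub = genes[genes["chrom"] == chrom].reset_index(drop=True)
        if chrom_sizes and chrom in chrom_sizes:
            L = float(chrom_sizes[chrom])
        else:
            L = float(sub["end"].max())
            if chrom_sizes is not None:
                warnings.warn(f"no size for chromosome {chrom}; using max gene end")
        sol, order, info = cluster_chromosome(
            sub, expr, samples, r=resolution, chrom_length=L, method=method
        )
        pos_sorted = sub["tss"].to_numpy(dtype=np.float64)[order]
        ids_sorted = sub["gene_id"].to_numpy()[order]
        zlist = []
        for lower, upper, cidx in adaptive_zones(sol, pos_sorted, L):
            if cidx is None:
                members = []
            else:
                sl = sol.cluster_slices()[cidx]
                members = list(ids_sorted[sl])
            zlist.append(
                Zone(chrom=chrom, lower=lower, upper=upper, member_genes=members,
                     cluster_index=cidx)
            )
        zones[chrom] = zlist
        info = dict(info)
        info["n_zones"] = len(zlist)
        meta[chrom] = info
    return ZoneMap(zones=zones, meta=meta)


def _internal_boundaries(zm: ZoneMap) -> dict:
    out = {}
    for chrom, zl in zm.zones.items():
        out[chrom] = np.array([z.upper for z in zl[:-1]], dtype=np.float64)
    return out


def bootstrap_zone_stability(
    genes: pd.DataFrame,
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    B: int = 20,
    seed: int = 0,
    tolerance: float = 100_000.0,
    resolution: float = DEFAULT_RESOLUTION,
    chrom_sizes: dict | None = None,
) -> dict:
    """Patient-level bootstrap of the zone map.

    Resamples patients with replacement ``B`` times, rebuilds the zone map
    on each replicate (sample weights multiplied by the patient's resampling
    multiplicity) and reports the range of zone counts plus the mean
    fraction of original internal boundaries matched within ``tolerance``
    base pairs.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    patients = sorted(samples["patient_id"].unique())
    if len(patients) < 2:
        raise ValueError("bootstrap needs at least 2 patients")
    rng = np.random.default_rng(seed)
    if "tss" not in genes.columns:
        genes = add_tss(genes)
    base = build_zone_map(genes, expr, samples, resolution=resolution,
                          chrom_sizes=chrom_sizes)
    base_bnds = _internal_boundaries(base)
    counts = []
    fracs = []
    for _ in range(B):
        draw = rng.choice(len(patients), size=len(patients), replace=True)
        mult = np.bincount(draw, minlength=len(patients))
        pat_mult = dict(zip(patients, mult))
        keep = samples[samples["patient_id"].map(pat_mult) > 0]
        expr_b = expr.copy()
        for _, row in keep.iterrows():
            m = pat_mult[row["patient_id"]]
            if m != 1 and row["sample_id"] in expr_b.columns:
                expr_b[row["sample_id"]] = expr_b[row["sample_id"]] * m
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            zm = build_zone_map(genes, expr_b, keep, resolution=resolution,
                                chrom_sizes=chrom_sizes)
        counts.append(zm.n_zones())
        boot_bnds = _internal_boundaries(zm)
        matched = 0
        total = 0
        for chrom, orig in base_bnds.items():
            total += orig.size
            bb = boot_bnds.get(chrom, np.empty(0))
            for b in orig:
                if bb.size and np.min(np.abs(bb - b)) <= tolerance:
                    matched += 1
        fracs.append(matched / total if total else 1.0)
    return {
        "n_zones_original": base.n_zones(),
        "zone_count_min": int(min(counts)),
        "zone_count_max": int(max(counts)),
        "boundary_identity_fraction": float(np.mean(fracs)),
        "replicates": B,
        "tolerance": tolerance,
    }
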