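"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators are provided:

* :func:`simulate_gmm` — a univariate Gaussian mixture (defaults: five
  well-separated components, n = 251) used to exercise BIC model selection
  and cluster-quality metrics.

* :func:`simulate_cancer_dataset` — a miniature matched tumor-normal
  cohort: genes laid out in TSS groups along chromosomes (with a gene-free
  centromere stretch), CPM-scale expression with log-normal multiplicative
  noise, planted polarized zones in which each gene is up- (or down-)
  regulated with probability ``p_up`` by a factor well past the 5% polarity
  threshold, and copy-number segments with gains/losses matching the
  planted zones.  Truth tables record the planted spans and signs.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GMMConfig",
    "CancerSimConfig",
    "simulate_gmm",
    "simulate_cancer_dataset",
    "CancerDataset",
]


@dataclass
class GMMConfig:
    """Mixture parameters; defaults give five components separated by 6
    standard deviations (n = 251)."""

    means: tuple = (0.0, 6.0, 12.0, 18.0, 24.0)
    sds: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)
    weights: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    n: int = 251

    def validate(self):
        w = np.asarray(self.weights, dtype=float)
        if len(self.means) != len(self.sds) or len(self.means) != len(w):
            raise ValueError("means, sds and weights must have equal length")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("mixture weights must be non-negative and sum to 1")
        if self.n < 1:
            raise ValueError("n must be positive")


def simulate_gmm(config: GMMConfig | None = None, seed: int = 0):
    """Draw a weighted sample from the mixture.

    Returns ``(values, weights, labels)`` — unit weights, with the true
    component labels for external validation (ARI).
    """
    config = config or GMMConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(config.means), size=config.n, p=np.asarray(config.weights))
    x = rng.normal(np.asarray(config.means)[comp], np.asarray(config.sds)[comp])
    return x, np.ones_like(x), comp


# ---------------------------------------------------------------------------
# matched tumor-normal cohort
# ---------------------------------------------------------------------------


@dataclass
class CancerSimConfig:
    """Layout and effect sizes of the synthetic cohort.

    Defaults: two 60 Mb chromosomes, 20 TSS groups of 15 genes each
    (300 genes per chromosome) with a 10 Mb gene-free centromere stretch,
    20 patients, planted effect factor 1.5 with per-gene up-probability
    0.8, and log-normal expression noise with sigma 0.2.
    """

    chrom_lengths: dict = field(default_factory=lambda: {"1": 60_000_000,
                                                         "2": 60_000_000})
    groups_per_chrom: int = 20
    genes_per_group: int = 15
    group_halfwidth: float = 150_000.0
    centromere: tuple = (25_000_000.0, 35_000_000.0)
    patients: int = 20
    # planted zones: (chrom, group index, sign); empty tuple = global null
    planted: tuple = (("1", 3, "+"), ("1", 14, "-"), ("2", 5, "+"), ("2", 16, "-"))
    p_up: float = 0.8
    effect_factor: float = 1.5
    noise_sigma: float = 0.2
    baseline_log_mean: float = np.log(30.0)
    baseline_log_sd: float = 1.0
    cn_gain: float = 3.0
    cn_loss: float = 1.0
    cn_noise_sd: float = 0.05

    def validate(self):
        if not 0 <= self.p_up <= 1:
            raise ValueError("p_up must be in [0, 1]")
        if self.effect_factor <= 1.05:
            raise ValueError("effect factor must exceed the 5% threshold")
        if self.patients < 1 or self.groups_per_chrom < 1:
            raise ValueError("sizes must be positive")
        seen = set()
        for chrom, g, sign in self.planted:
            if sign not in ("+", "-"):
                raise ValueError("planted sign must be + or -")
            if chrom not in self.chrom_lengths or not 0 <= g < self.groups_per_chrom:
                raise ValueError(f"planted zone ({chrom}, {g}) outside the layout")
            if (chrom, g) in seen:
                raise ValueError("planted zones must be disjoint")
            seen.add((chrom, g))


@dataclass
class CancerDataset:
    """In-memory synthetic cohort plus plain-text writers."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    expression: pd.DataFrame  # genes x samples, CPM scale
    samples: pd.DataFrame  # sample_id, patient_id, condition
    segments: pd.DataFrame  # sample_id, chrom, start, end, value (linear CN)
    truth_zones: pd.DataFrame  # chrom, start, end, sign
    truth_genes: pd.DataFrame  # gene_id, effect: planted zone sign per gene

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genes.gtf", "w") as fh:
            for _, g in self.genes.iterrows():
                fh.write(
                    f"chr{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tgene_id \"{g.gene_id}\";\n"
                )
        self.expression.to_csv(outdir / "expression.tsv", sep="\t",
                               index_label="gene_id")
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        self.segments.to_csv(outdir / "segments.tsv", sep="\t", index=False)
        self.truth_zones.to_csv(outdir / "truth_zones.tsv", sep="\t", index=False)
        self.truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)


def _group_centers(cfg: CancerSimConfig, L: float) -> np.ndarray:
    """Evenly spaced group centers avoiding the centromere stretch."""
    lo, hi = cfg.centromere
    usable = []
    step = (L - (hi - lo) - 4e6) / cfg.groups_per_chrom
    pos = 2e6
    while len(usable) < cfg.groups_per_chrom:
        if pos + step / 2 >= lo and pos <= hi:
            pos = hi + step / 2
        usable.append(pos + step / 2)
        pos += step
    return np.asarray(usable[: cfg.groups_per_chrom])


def simulate_cancer_dataset(
    config: CancerSimConfig | None = None, seed: int = 0
) -> CancerDataset:
    cfg = config or CancerSimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    gene_rows = []
    truth_zone_rows = []
    gene_effect_sign = []
    planted_lookup = {(c, g): s for c, g, s in cfg.planted}
    for chrom in sorted(cfg.chrom_lengths):
        L = float(cfg.chrom_lengths[chrom])
        centers = _group_centers(cfg, L)
        for gi, center in enumerate(centers):
            tss = np.sort(
                rng.uniform(center - cfg.group_halfwidth,
                            center + cfg.group_halfwidth,
                            size=cfg.genes_per_group)
            )
            sign = planted_lookup.get((chrom, gi), "none")
            if sign != "none":
                truth_zone_rows.append(
                    {"chrom": chrom, "start": float(tss[0]),
                     "end": float(tss[-1]) + 1.0, "sign": sign}
                )
            for t in tss:
                gid = f"g{chrom}_{gi:02d}_{len(gene_rows):05d}"
                strand = "+" if rng.random() < 0.5 else "-"
                length = int(rng.integers(1_000, 10_000))
                t = float(np.floor(t))
                if strand == "+":
                    start, end = int(t), int(t) + length
                else:
                    start, end = int(t) + 1 - length, int(t) + 1
                    if start < 0:
                        start, end = 0, length
                gene_rows.append(
                    {"gene_id": gid, "chrom": chrom, "start": start,
                     "end": end, "strand": strand}
                )
                gene_effect_sign.append(sign)
    genes = pd.DataFrame(gene_rows)
    n_genes = len(genes)

    # planted dysregulation: in each matched pair, a planted-zone gene moves
    # in the zone's direction with probability p_up (against it otherwise),
    # independently per (gene, patient); background genes are null
    f = cfg.effect_factor
    sign_arr = np.array([{"+": 1, "-": -1}.get(s, 0) for s in gene_effect_sign],
                        dtype=np.int8)
    signal = sign_arr != 0
    effect_label = np.where(signal, np.asarray(gene_effect_sign, dtype=object),
                            "none")
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                             size=n_genes)

    sample_rows = []
    expr = {}
    for p in range(cfg.patients):
        pid = f"P{p:03d}"
        ts, ns = f"{pid}_T", f"{pid}_N"
        sample_rows.append({"sample_id": ts, "patient_id": pid,
                            "condition": "tumor"})
        sample_rows.append({"sample_id": ns, "patient_id": pid,
                            "condition": "normal"})
        mult = np.ones(n_genes)
        if signal.any():
            with_zone = rng.random(int(signal.sum())) < cfg.p_up
            dirn = np.where(with_zone, sign_arr[signal], -sign_arr[signal])
            mult[signal] = np.where(dirn > 0, f, 1.0 / f)
        noise_t = rng.lognormal(0.0, cfg.noise_sigma, size=n_genes)
        noise_n = rng.lognormal(0.0, cfg.noise_sigma, size=n_genes)
        expr[ts] = baseline * mult * noise_t
        expr[ns] = baseline * noise_n
    samples = pd.DataFrame(sample_rows)
    expression = pd.DataFrame(expr, index=genes["gene_id"])

    # copy-number segments: one segment per inter-group span, gains/losses
    # where a planted zone sits (tumor only); normals hover around CN 2
    seg_rows = []
    for chrom in sorted(cfg.chrom_lengths):
        L = float(cfg.chrom_lengths[chrom])
        centers = _group_centers(cfg, L)
        edges = [0.0]
        for a, b in zip(centers[:-1], centers[1:]):
            edges.append(float((a + b) / 2))
        edges.append(L)
        for p in range(cfg.patients):
            pid = f"P{p:03d}"
            for gi in range(len(centers)):
                sign = planted_lookup.get((chrom, gi), "none")
                cn_t = {"+": cfg.cn_gain, "-": cfg.cn_loss}.get(sign, 2.0)
                seg_rows.append(
                    {"sample_id": f"{pid}_T", "chrom": chrom,
                     "start": int(edges[gi]), "end": int(edges[gi + 1]),
                     "value": max(cn_t + rng.normal(0, cfg.cn_noise_sd), 0.0)}
                )
                seg_rows.append(
                    {"sample_id": f"{pid}_N", "chrom": chrom,
                     "start": int(edges[gi]), "end": int(edges[gi + 1]),
                     "value": max(2.0 + rng.normal(0, cfg.cn_noise_sd), 0.0)}
                )
    segments = pd.DataFrame(seg_rows)
    truth_zones = pd.DataFrame(
        truth_zone_rows, columns=["chrom", "start", "end", "sign"]
    )
    truth_genes = pd.DataFrame(
        {"gene_id": genes["gene_id"], "effect": effect_label}
    )
    return CancerDataset(
        genes=genes, expression=expression, samples=samples,
        segments=segments, truth_zones=truth_zones, truth_genes=truth_genes,
    )
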