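"""Readers/writers for the formats the pipeline touches.

Coordinates are 0-based half-open at every module boundary; reading GTF
(1-based inclusive) is the single place where coordinates are shifted.
Chromosome names are normalized by stripping a leading ``chr`` on input and
restoring it on output.  All writers order rows deterministically (natural
chromosome order, then start) so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .zones import Zone, ZoneMap, _chrom_sort_key

__all__ = [
    "read_annotation",
    "read_expression",
    "read_sample_sheet",
    "read_segments",
    "cpm_scale",
    "filter_low_depth",
    "write_zones_bed",
    "read_zones_bed",
    "write_calls",
    "read_calls",
    "write_manifest",
]

_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def norm_chrom(c: str) -> str:
    return c[3:] if c.lower().startswith("chr") else c


def _denorm_chrom(c: str) -> str:
    return c if c.startswith("chr") else f"chr{c}"


def read_annotation(path, fmt: str = "gtf") -> pd.DataFrame:
    """Gene annotation as a frame (gene_id, chrom, start, end, strand),
    0-based half-open.

    GTF rows with feature type ``gene`` are parsed (1-based inclusive
    converted here, and only here); BED is taken as-is.  Genes with strand
    '.' are skipped with a warning; duplicate gene ids are rejected.
    """
    path = Path(path)
    rows = []
    skipped = 0
    if fmt == "gtf":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise ValueError(f"{path}:{ln}: malformed GTF row")
                if parts[2] != "gene":
                    continue
                strand = parts[6]
                if strand not in ("+", "-"):
                    skipped += 1
                    continue
                m = _GTF_GENE_ID.search(parts[8])
                if m is None:
                    raise ValueError(f"{path}:{ln}: missing gene_id attribute")
                try:
                    start = int(parts[3]) - 1  # 1-based inclusive -> 0-based
                    end = int(parts[4])
                except ValueError as e:
                    raise ValueError(f"{path}:{ln}: bad coordinates") from e
                if start < 0 or start >= end:
                    raise ValueError(f"{path}:{ln}: bad coordinates")
                rows.append((m.group(1), norm_chrom(parts[0]), start, end, strand))
    elif fmt == "bed":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}:{ln}: BED needs 6 columns (strand)")
                strand = parts[5]
                if strand not in ("+", "-"):
                    skipped += 1
                    continue
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as e:
                    raise ValueError(f"{path}:{ln}: bad coordinates") from e
                if start < 0 or start >= end:
                    raise ValueError(f"{path}:{ln}: bad coordinates")
                rows.append((parts[3], norm_chrom(parts[0]), start, end, strand))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    if skipped:
        warnings.warn(f"skipped {skipped} gene(s) without usable strand")
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate gene ids: {sorted(df.loc[dup, 'gene_id'])[:5]}")
    return df


def read_expression(path) -> pd.DataFrame:
    """Genes x samples expression table (TSV, first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression table")
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    req = {"sample_id", "patient_id", "condition"}
    if not req.issubset(df.columns):
        raise ValueError(f"sample sheet needs columns {sorted(req)}")
    bad = set(df["condition"]) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    return df


def cpm_scale(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample column to counts per million (no gene-length
    normalization: read density, not abundance, is the weighting signal)."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-sum sample(s): {list(zero.index)}")
    return counts * (1e6 / totals)


def filter_low_depth(counts: pd.DataFrame, min_total: float = 8e6):
    """Drop samples sequenced below ``min_total`` raw reads (outlier rule).

    Returns ``(filtered, report)`` where the report lists dropped samples.
    """
    totals = counts.sum(axis=0)
    dropped = list(totals.index[totals < min_total])
    kept = counts.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise ValueError("all samples fall below the depth threshold")
    return kept, {"dropped": dropped, "min_total": min_total}


def read_segments(path, value_scale: str = "linear_cn") -> pd.DataFrame:
    """SEG-style copy-number table (sample, chrom, start, end, value).

    ``log2_ratio`` values are converted to linear copy number as
    ``2 * 2**value``.  Overlapping segments within a sample are rejected.
    """
    if value_scale not in ("linear_cn", "log2_ratio"):
        raise ValueError(f"unknown value scale {value_scale!r}")
    df = pd.read_csv(path, sep="\t")
    req = {"sample_id", "chrom", "start", "end", "value"}
    if not req.issubset(df.columns):
        raise ValueError(f"segment table needs columns {sorted(req)}")
    df["chrom"] = df["chrom"].astype(str).map(norm_chrom)
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]]
        raise ValueError(f"bad segment coordinates at rows {list(bad.index[:5])}")
    for (sid, chrom), grp in df.groupby(["sample_id", "chrom"]):
        g = grp.sort_values("start")
        if np.any(g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]):
            raise ValueError(f"overlapping segments for sample {sid} on {chrom}")
    if value_scale == "log2_ratio":
        df["value"] = 2.0 * np.power(2.0, df["value"].astype(float))
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# zone map round-trip
# ---------------------------------------------------------------------------


def _fmt_coord(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_zones_bed(zone_map: ZoneMap, path, meta_path=None) -> None:
    """Zones as BED-like TSV (chrom, start, end, zone_id, n_genes,
    is_empty, genes).  Boundaries may be fractional (cluster midpoints) and
    are written as decimal text so the round-trip is exact; a JSON sidecar
    stores per-chromosome k/kmax metadata."""
    with open(path, "w") as fh:
        for chrom in sorted(zone_map.zones, key=_chrom_sort_key):
            for idx, z in enumerate(zone_map.zones[chrom]):
                genes = ",".join(z.member_genes) if z.member_genes else "."
                fh.write(
                    "\t".join(
                        [
                            _denorm_chrom(chrom),
                            _fmt_coord(z.lower),
                            _fmt_coord(z.upper),
                            f"{chrom}_{idx:04d}",
                            str(len(z.member_genes)),
                            "1" if z.is_empty else "0",
                            genes,
                        ]
                    )
                    + "\n"
                )
    if meta_path is not None:
        meta = {}
        for chrom, info in zone_map.meta.items():
            info = dict(info)
            bic = info.pop("bic", None)
            if bic is not None:
                info["bic"] = bic.as_rows() if hasattr(bic, "as_rows") else bic
            meta[chrom] = info
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True, default=float)
            fh.write("\n")


def read_zones_bed(path) -> ZoneMap:
    zones: dict[str, list[Zone]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{ln}: expected 7 columns")
            chrom = norm_chrom(parts[0])
            lower, upper = float(parts[1]), float(parts[2])
            members = [] if parts[6] == "." else parts[6].split(",")
            zones.setdefault(chrom, []).append(
                Zone(chrom=chrom, lower=lower, upper=upper, member_genes=members)
            )
    for chrom, zl in zones.items():
        cidx = 0
        for z in zl:
            if not z.is_empty:
                z.cluster_index = cidx
                cidx += 1
    return ZoneMap(zones=zones)


def write_calls(calls: pd.DataFrame, path) -> None:
    """Polarity-call / locus tables as TSV, deterministically ordered."""
    out = calls.copy()
    if {"chrom", "start"}.issubset(out.columns):
        out["_ck"] = out["chrom"].map(_chrom_sort_key)
        out = out.sort_values(["_ck", "start"], kind="stable").drop(columns="_ck")
        out["chrom"] = out["chrom"].map(_denorm_chrom)
    out.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str).map(norm_chrom)
    return df


def write_manifest(path, parameters: dict, seed=None) -> None:
    from . import __version__

    doc = {"tool": "genozones", "version": __version__, "seed": seed,
           "parameters": parameters}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
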