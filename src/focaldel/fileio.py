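"""File formats: depth tracks, VCF het sites, TSV tables, run config.

Coordinate conventions: every on-disk and user-facing coordinate is
1-based inclusive (samtools-depth style); bedGraph input (0-based
half-open, detected by column count) is converted on read. Internally
bin indices are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coverage import Region

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- depth

def read_depth(path) -> pd.DataFrame:
    """Read a per-base depth track as (chrom, pos, depth), 1-based.

    Three columns are taken as samtools-depth TSV (chrom, 1-based pos,
    depth); four as bedGraph (chrom, 0-based half-open start/end, depth),
    whose intervals are expanded to per-base rows. The detected dialect
    is logged.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 3:
        logger.info("%s: samtools-depth dialect", path)
        df.columns = ["chrom", "pos", "depth"]
        return df.astype({"pos": np.int64})
    if df.shape[1] == 4:
        logger.info("%s: bedGraph dialect", path)
        df.columns = ["chrom", "start", "end", "depth"]
        chroms, poss, deps = [], [], []
        for row in df.itertuples():
            span = np.arange(row.start + 1, row.end + 1, dtype=np.int64)
            chroms.append(np.repeat(row.chrom, len(span)))
            poss.append(span)
            deps.append(np.repeat(row.depth, len(span)))
        return pd.DataFrame({"chrom": np.concatenate(chroms),
                             "pos": np.concatenate(poss),
                             "depth": np.concatenate(deps)})
    raise ValueError(f"{path}: expected 3 (depth TSV) or 4 (bedGraph) columns")


def write_depth(path, chrom: str, start: int, depths) -> None:
    """Write per-base depths as samtools-depth TSV starting at ``start``."""
    depths = np.asarray(depths)
    pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(start, start + len(depths), dtype=np.int64),
        "depth": depths,
    }).to_csv(path, sep="\t", header=False, index=False)


def bins_to_per_base(bin_values, bin_width: int, region_length: int) -> np.ndarray:
    """Expand per-bin depths to a constant-within-bin per-base track."""
    per_base = np.repeat(np.asarray(bin_values, dtype=float), bin_width)
    return per_base[:region_length]


# ---------------------------------------------------------------- VCF

VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR
"""


def write_het_vcf(path, chrom: str, snps: pd.DataFrame, offset: int = 0) -> None:
    """Write simulated het-SNP tumor allele counts as a 2-sample VCF.

    The normal sample is written 0/1 with balanced AD; the tumor carries
    the simulated ref/alt counts in its AD field.
    """
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for row in snps.itertuples():
            pos = int(row.position) + offset
            n_half = max(int(row.depth) // 2, 1)
            fh.write(f"{chrom}\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT:AD\t"
                     f"0/1:{n_half},{n_half}\t"
                     f"0/1:{int(row.ref_count)},{int(row.alt_count)}\n")


def read_vcf_het_sites(path, region: Region | str | None = None,
                       normal_sample: int = 0, tumor_sample: int = 1) -> pd.DataFrame:
    """Germline-het sites with tumor allele depths from a VCF.

    Sites where the normal genotype is 0/1 are kept; the tumor AD field
    supplies (ref_count, alt_count). Rows with malformed AD are skipped
    with a warning (count logged).
    """
    from cyvcf2 import VCF

    if isinstance(region, str):
        region = Region.parse(region)
    vcf = VCF(str(path))
    rows, n_skipped = [], 0
    for var in vcf:
        if region is not None and not (
                var.CHROM == region.chrom and region.start <= var.POS <= region.end):
            continue
        gt = var.genotypes[normal_sample]
        if sorted(gt[:2]) != [0, 1]:  # germline het only
            continue
        try:
            ad = var.format("AD")[tumor_sample]
            ref_count, alt_count = int(ad[0]), int(ad[1])
            if ref_count < 0 or alt_count < 0:
                raise ValueError
        except (TypeError, ValueError, IndexError):
            n_skipped += 1
            continue
        rows.append({"position": var.POS, "ref_count": ref_count,
                     "alt_count": alt_count, "depth": ref_count + alt_count})
    if n_skipped:
        logger.warning("%s: skipped %d rows with malformed AD", path, n_skipped)
    return pd.DataFrame(rows, columns=["position", "ref_count", "alt_count", "depth"])


# ---------------------------------------------------------------- tables

def read_segments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_segments(path, segments: pd.DataFrame) -> None:
    segments.to_csv(path, sep="\t", index=False)


def read_karyotype(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_karyotype(path, karyotype: pd.DataFrame) -> None:
    karyotype.to_csv(path, sep="\t", index=False)


def read_signature_matrix(path) -> pd.DataFrame:
    """COSMIC-layout signature TSV: channel rows x signature columns."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_genotypes(path):
    """Genotype TSV (samples x SNPs, header of SNP ids, first column of
    sample ids, optional 'declared' label column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    declared = None
    if "declared" in df.columns:
        declared = df.pop("declared").to_numpy()
    return df.to_numpy(dtype=float), list(df.index), declared


def read_cellularity_grid(path) -> tuple[np.ndarray, np.ndarray]:
    """Sequenza-contour-style TSV (cellularity, ploidy, posterior),
    marginalized over ploidy."""
    df = pd.read_csv(path, sep="\t")
    marg = df.groupby("cellularity")["posterior"].sum()
    return marg.index.to_numpy(dtype=float), marg.to_numpy(dtype=float)


def read_bed_regions(path) -> list[Region]:
    """3-column BED (0-based half-open) to 1-based inclusive Regions."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [Region(str(r[0]), int(r[1]) + 1, int(r[2])) for r in df.itertuples(index=False)]


# ---------------------------------------------------------------- config

@dataclass
class RunConfig:
    """Flat run configuration; every random operation takes an explicit
    seed defaulting from here, and seeds are recorded in every output."""

    region: str = "chr5:98190408-98262740"
    bin_width: int = 50
    p_threshold: float = 0.05
    loss_threshold: float = 0.05
    bf_indeterminate_band: float = 0.5
    n_draws: int = 10_000
    n_zygosity_draws: int = 2000
    seed: int = 0
    n_housekeeping: int = 14
    scenario: str | None = None
    tumor_depth: str | None = None
    normal_depth: str | None = None
    vcf: str | None = None
    cellularity_grid: str | None = None
    housekeeping_bed: str | None = None
    karyotype: str | None = None
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extras = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs, extras=extras)
        for key in ("tumor_depth", "normal_depth", "vcf", "cellularity_grid",
                    "housekeeping_bed", "karyotype"):
            val = getattr(cfg, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"config {key}: {val} not found")
        return cfg
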