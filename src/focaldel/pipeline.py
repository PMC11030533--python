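"""End-to-end per-sample pipeline: depths -> deletion call -> zygosity.

Stages: bin and normalize the paired depths over the gene window, fit
the paired slope, build the housekeeping null, fit the cellularity Beta,
propagate slope x cellularity uncertainty into the loss distribution,
make the deletion call, restrict to the most-lost subregion and test
heterozygous vs homozygous. Works either from files (depth TSVs, VCF,
cellularity grid) or from a named simulator scenario with known truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clonality, coverage, fileio, simulate, zygosity

logger = logging.getLogger(__name__)

SCENARIOS: dict[str, simulate.SimTruth] = {
    "no-del": simulate.SimTruth(cellularity=0.8, subclonal_fraction=0.0, zygosity="none"),
    "clonal-hom-del": simulate.SimTruth(cellularity=0.9, subclonal_fraction=1.0,
                                        zygosity=zygosity.HOM),
    "clonal-het-del": simulate.SimTruth(cellularity=0.9, subclonal_fraction=1.0,
                                        zygosity=zygosity.HET),
    "subclonal-het-del": simulate.SimTruth(cellularity=0.8, subclonal_fraction=0.6,
                                           zygosity=zygosity.HET),
    "subclonal-hom-del": simulate.SimTruth(cellularity=0.8, subclonal_fraction=0.6,
                                           zygosity=zygosity.HOM),
}


@dataclass
class SampleReport:
    sample_id: str
    deletion_call: str
    zygosity_call: str
    loss_point: float
    interval66: tuple[float, float]
    interval95: tuple[float, float]
    audit: dict

    def to_json(self) -> str:
        return json.dumps({
            "sample_id": self.sample_id,
            "deletion_call": self.deletion_call,
            "zygosity_call": self.zygosity_call,
            "loss_point": self.loss_point,
            "interval66": list(self.interval66),
            "interval95": list(self.interval95),
            "audit": self.audit,
        }, indent=2, sort_keys=True, default=float)

    def to_row(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "sample_id": self.sample_id,
            "deletion_call": self.deletion_call,
            "zygosity": self.zygosity_call,
            "loss_point": self.loss_point,
            "loss_lo66": self.interval66[0], "loss_hi66": self.interval66[1],
            "loss_lo95": self.interval95[0], "loss_hi95": self.interval95[1],
        }])


def call_sample(pair: coverage.NormalizedCoveragePair,
                housekeeping: list[coverage.NormalizedCoveragePair],
                grid: np.ndarray, densities: np.ndarray,
                snps: pd.DataFrame | None,
                config: fileio.RunConfig,
                sample_id: str = "sample") -> SampleReport:
    """Run the calling chain on prepared inputs."""
    reg = coverage.fit_paired_slope(pair)
    null = coverage.fit_housekeeping_null(housekeeping)
    post = clonality.fit_beta_posterior(grid, densities)
    loss = clonality.propagate_loss(reg.beta0, reg.sigma, post.s1, post.s2,
                                    n_draws=config.n_draws, seed=config.seed)
    call = clonality.call_loss(reg, null, loss,
                               p_threshold=config.p_threshold,
                               loss_threshold=config.loss_threshold)

    zyg_call = "not_assessed"
    zyg_audit: dict = {}
    if call.call == "deleted" and snps is not None and len(snps):
        sel = zygosity.select_lost_subregion(pair)
        # SNP positions are window-relative 1-based; keep those in the
        # selected bin range
        lo_bp = sel.start * pair.bin_width + 1
        hi_bp = sel.end * pair.bin_width
        used = snps[(snps["position"] >= lo_bp) & (snps["position"] <= hi_bp)]
        if len(used) == 0:
            used = snps
        z = zygosity.call_zygosity(used, loss, posterior=post,
                                   n_draws=config.n_zygosity_draws,
                                   seed=config.seed,
                                   indeterminate_band=config.bf_indeterminate_band)
        zyg_call = z.call
        zyg_audit = {"log10_bayes_factor": z.log10_bayes_factor,
                     "n_snps_used": z.n_snps_used,
                     "subregion_bins": [sel.start, sel.end],
                     "no_loss_signal": sel.no_loss_signal}

    audit = dict(call.audit)
    audit["zygosity"] = zyg_audit
    audit["config"] = {"bin_width": config.bin_width, "seed": config.seed,
                       "n_draws": config.n_draws,
                       "p_threshold": config.p_threshold,
                       "loss_threshold": config.loss_threshold}
    return SampleReport(sample_id=sample_id, deletion_call=call.call,
                        zygosity_call=zyg_call, loss_point=call.loss_point,
                        interval66=call.interval66,
                        interval95=loss.interval95, audit=audit)


def _simulated_inputs(config: fileio.RunConfig):
    truth = SCENARIOS[config.scenario]
    truth = simulate.with_seed(truth, config.seed)
    region = coverage.Region.parse(config.region)

    normal, tumor, truth = simulate.simulate_paired_coverage(
        truth, window_length=region.length, bin_width=config.bin_width)
    pair = coverage.normalize_pair(
        coverage.BinnedCoverage("normal", region, config.bin_width, normal,
                                truth.mean_depth_normal),
        coverage.BinnedCoverage("tumor", region, config.bin_width, tumor,
                                truth.mean_depth_tumor),
    )

    housekeeping = []
    neutral = simulate.SimTruth(cellularity=truth.cellularity, subclonal_fraction=0.0,
                                zygosity="none", mean_depth_normal=truth.mean_depth_normal,
                                mean_depth_tumor=truth.mean_depth_tumor,
                                dispersion=truth.dispersion)
    hk_region = coverage.Region(region.chrom, 1, 25_000)
    for g in range(config.n_housekeeping):
        t = simulate.with_seed(neutral, config.seed * 1000 + g + 1)
        hn, ht, _ = simulate.simulate_paired_coverage(t, window_length=hk_region.length,
                                                      bin_width=config.bin_width)
        housekeeping.append(coverage.normalize_pair(
            coverage.BinnedCoverage("normal", hk_region, config.bin_width, hn,
                                    t.mean_depth_normal),
            coverage.BinnedCoverage("tumor", hk_region, config.bin_width, ht,
                                    t.mean_depth_tumor)))

    grid_df = simulate.simulate_cellularity_grid(truth)
    snps = simulate.simulate_het_snps(truth, n_snps=30, depth=60.0,
                                      seed=config.seed + 17)
    return pair, housekeeping, grid_df["cellularity"].to_numpy(), \
        grid_df["posterior"].to_numpy(), snps, truth


def _file_inputs(config: fileio.RunConfig):
    region = coverage.Region.parse(config.region)
    normal_df = fileio.read_depth(config.normal_depth)
    tumor_df = fileio.read_depth(config.tumor_depth)
    # track-wide mean depth as the genome-mean proxy for normalization
    mean_n = float(normal_df["depth"].mean())
    mean_t = float(tumor_df["depth"].mean())
    n_binned = coverage.bin_coverage(normal_df, region, config.bin_width,
                                     mean_depth=mean_n, sample_id="normal")
    t_binned = coverage.bin_coverage(tumor_df, region, config.bin_width,
                                     mean_depth=mean_t, sample_id="tumor")
    pair = coverage.normalize_pair(n_binned, t_binned)

    housekeeping = []
    for hk in fileio.read_bed_regions(config.housekeeping_bed):
        hn = coverage.bin_coverage(normal_df, hk, config.bin_width, mean_depth=mean_n)
        ht = coverage.bin_coverage(tumor_df, hk, config.bin_width, mean_depth=mean_t)
        housekeeping.append(coverage.normalize_pair(hn, ht))

    grid, densities = fileio.read_cellularity_grid(config.cellularity_grid)
    snps = None
    if config.vcf:
        snps = fileio.read_vcf_het_sites(config.vcf, region)
        snps = snps.assign(position=snps["position"] - region.start + 1)
    return pair, housekeeping, grid, densities, snps


def run_pipeline(config: fileio.RunConfig, sample_id: str | None = None) -> SampleReport:
    """Run end to end from a scenario name or from configured files."""
    if config.scenario is not None:
        if config.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {config.scenario!r}; "
                             f"choose from {sorted(SCENARIOS)}")
        pair, hk, grid, dens, snps, truth = _simulated_inputs(config)
        sid = sample_id or config.scenario
        report = call_sample(pair, hk, grid, dens, snps, config, sample_id=sid)
        report.audit["truth"] = {
            "cellularity": truth.cellularity,
            "subclonal_fraction": truth.subclonal_fraction,
            "zygosity": truth.zygosity,
            "expected_ratio": truth.expected_ratio,
        }
        return report
    if not (config.tumor_depth and config.normal_depth and config.cellularity_grid
            and config.housekeeping_bed):
        raise ValueError("file-based run needs tumor_depth, normal_depth, "
                         "cellularity_grid and housekeeping_bed")
    pair, hk, grid, dens, snps = _file_inputs(config)
    return call_sample(pair, hk, grid, dens, snps, config,
                       sample_id=sample_id or "sample")
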