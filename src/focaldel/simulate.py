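"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is seeded and bit-reproducible, and its defaults match
the study conditions the pipeline targets: exome/genome-scale mean
depths (~60x), a 72 kb gene window in 50 bp bins, het-SNP panels of a
few dozen sites, three-population SNP panels of 3000 markers, and
catalogs of thousands of mutations.

The paired-coverage model draws each bin's total sequenced bases from a
negative binomial whose mean carries a per-bin lognormal bias factor
SHARED between tumor and normal. The shared factor mimics mappability
and GC structure — the dominant source of bin-to-bin coverage variation
in capture and genome data — and is what makes the paired tumor-on-
normal regression informative: the shared structure spans a wide dynamic
range while the independent sampling noise per bin is small (thousands
of bases per 50 bp bin at study depths), so the slope recovers the
copy-number ratio with little attenuation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import scars
from .signatures import MutationCatalog
from .zygosity import HET, HOM, expected_vaf

logger = logging.getLogger(__name__)

POPULATIONS = ("AFR", "EUR", "EAS")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated tumor-normal pair.

    cellularity c: fraction of sampled cells that are tumor;
    subclonal_fraction f: fraction of TUMOR cells carrying the deletion;
    dispersion: negative-binomial overdispersion of the per-bin total
    base count (variance = mu + dispersion * mu^2; 0 means noiseless).
    The default 1e-3 gives a per-bin depth coefficient of variation of a
    few percent at 60x in 50 bp bins, typical of modern libraries.
    """

    cellularity: float = 0.8
    subclonal_fraction: float = 0.5
    zygosity: str = HET  # heterozygous | homozygous | none
    mean_depth_normal: float = 60.0
    mean_depth_tumor: float = 60.0
    dispersion: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cellularity <= 1.0:
            raise ValueError("cellularity must be in (0, 1]")
        if not 0.0 <= self.subclonal_fraction <= 1.0:
            raise ValueError("subclonal_fraction must be in [0, 1]")
        if self.zygosity not in (HET, HOM, "none"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.mean_depth_normal <= 0 or self.mean_depth_tumor <= 0:
            raise ValueError("mean depths must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")

    @property
    def expected_ratio(self) -> float:
        """Expected tumor/normal coverage ratio over the deleted region:
        1 - c*f/2 (het), 1 - c*f (hom), 1 (none)."""
        cf = self.cellularity * self.subclonal_fraction
        if self.zygosity == HET:
            return 1.0 - cf / 2.0
        if self.zygosity == HOM:
            return 1.0 - cf
        return 1.0

    @property
    def copy_loss_fraction(self) -> float:
        """Fraction of tumor-cell gene copies deleted: f/2 het, f hom."""
        if self.zygosity == HET:
            return self.subclonal_fraction / 2.0
        if self.zygosity == HOM:
            return self.subclonal_fraction
        return 0.0


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu, variance mu + dispersion*mu^2;
    dispersion 0 is the deterministic (noiseless) limit."""
    if dispersion == 0:
        return mu.astype(float)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p).astype(float)


def simulate_paired_coverage(
    truth: SimTruth,
    window_length: int = 72_333,
    bin_width: int = 50,
    deleted_subinterval: tuple[float, float] = (0.0, 1.0),
    bias_sigma: float = 0.4,
):
    """Per-bin mean depths for tumor and normal over a gene window.

    Each bin's total base count is negative binomial around
    mean_depth * bin_width * bias, the lognormal ``bias`` (sigma 0.4 by
    default, emulating mappability/GC structure) shared between the two
    tracks; the per-bin mean depth returned is count / bin_width.
    ``deleted_subinterval`` is a fraction range of the window carrying
    the deletion (default: the whole window), enabling partial-gene loss.
    Returns (normal_depths, tumor_depths, truth); the normal track is
    drawn before and independently of any deletion parameter, so the
    same seed yields the identical normal track for any truth zygosity.
    """
    if window_length < 2 * bin_width:
        raise ValueError("window must span at least two bins")
    lo, hi = deleted_subinterval
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"invalid deleted subinterval {deleted_subinterval}")

    n = -(-window_length // bin_width)
    widths = np.full(n, float(bin_width))
    widths[-1] = window_length - (n - 1) * bin_width  # partial final bin
    rng = np.random.default_rng(truth.seed)
    bias = rng.lognormal(mean=-bias_sigma**2 / 2.0, sigma=bias_sigma, size=n)

    normal = _nb_draw(rng, truth.mean_depth_normal * widths * bias,
                      truth.dispersion) / widths

    ratio = np.ones(n)
    ratio[int(np.floor(lo * n)):int(np.ceil(hi * n))] = truth.expected_ratio
    tumor = _nb_draw(rng, truth.mean_depth_tumor * widths * bias * ratio,
                     truth.dispersion) / widths
    return normal, tumor, truth


def simulate_het_snps(truth: SimTruth, n_snps: int = 30, depth: float = 60.0,
                      seed: int | None = None) -> pd.DataFrame:
    """Tumor allele counts at germline-het SNPs inside the deleted region.

    The lost haplotype is chosen uniformly per SNP; alt counts are
    binomial with the success probability given by the same dosage model
    the zygosity caller uses (single source of truth), and site depths
    are Poisson around ``depth`` scaled by the truth coverage ratio.
    """
    if n_snps < 1:
        raise ValueError("need at least one SNP")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    zyg = truth.zygosity if truth.zygosity != "none" else HET
    f = truth.subclonal_fraction if truth.zygosity != "none" else 0.0
    v_ret, v_lost = expected_vaf(truth.cellularity, f, zyg)

    alt_retained = rng.random(n_snps) < 0.5  # which haplotype carries alt
    p_alt = np.where(alt_retained, v_ret, v_lost)
    depths = rng.poisson(depth * truth.expected_ratio, size=n_snps)
    depths = np.maximum(depths, 1)
    alt = rng.binomial(depths, p_alt)
    return pd.DataFrame({
        "position": np.arange(1, n_snps + 1) * 1000,
        "ref_count": depths - alt,
        "alt_count": alt,
        "depth": depths,
    })


def simulate_genotypes(n_per_pop: int = 100, n_snps: int = 3000,
                       divergence: float = 0.15, seed: int | None = None):
    """Balding-Nichols three-population genotype matrix.

    Ancestral allele frequencies are uniform on (0.1, 0.9); each
    population draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F)
    with divergence F, and dosages are Binomial(2, p_pop). Returns
    (samples x SNPs float matrix, population label array).
    """
    if not 0.0 < divergence < 1.0:
        raise ValueError("divergence must be in (0, 1)")
    if n_per_pop < 1 or n_snps < 2:
        raise ValueError("need n_per_pop >= 1 and n_snps >= 2")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, size=n_snps)
    a = p_anc * (1.0 - divergence) / divergence
    b = (1.0 - p_anc) * (1.0 - divergence) / divergence

    blocks, labels = [], []
    for pop in POPULATIONS:
        p_pop = rng.beta(a, b)
        blocks.append(rng.binomial(2, p_pop, size=(n_per_pop, n_snps)).astype(float))
        labels += [pop] * n_per_pop
    return np.vstack(blocks), np.array(labels)


def random_signature_library(n_signatures: int = 5, n_channels: int = 96,
                             concentration: float = 0.2,
                             seed: int | None = None) -> pd.DataFrame:
    """Seeded sparse Dirichlet signature matrix in COSMIC layout.

    Low concentration gives peaked, well-separated probability vectors,
    the regime where refitting is identifiable; columns sum to 1.
    """
    from .signatures import sbs96_labels

    rng = np.random.default_rng(seed)
    mat = rng.dirichlet([concentration] * n_channels, size=n_signatures).T
    labels = (sbs96_labels() if n_channels == 96
              else [f"ch{i}" for i in range(n_channels)])
    cols = [f"SIG{i + 1}" for i in range(n_signatures)]
    return pd.DataFrame(mat, index=labels, columns=cols)


def simulate_catalog(weights: dict[str, int], signature_matrix: pd.DataFrame,
                     seed: int | None = None) -> MutationCatalog:
    """Multinomial catalog from known per-signature mutation counts."""
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(signature_matrix.index))
    for name, n in weights.items():
        if n < 0:
            raise ValueError("negative signature count")
        if n == 0:
            continue
        counts += rng.multinomial(int(n), signature_matrix[name].to_numpy())
    if counts.sum() == 0:
        logger.warning("all signature weights zero: empty catalog")
    return MutationCatalog(list(signature_matrix.index), counts,
                           channel_set="SBS96" if len(counts) == 96 else "custom")


def simulate_segments(profile="diploid-balanced",
                      karyotype: pd.DataFrame | None = None,
                      seed: int | None = None) -> pd.DataFrame:
    """Allele-specific segment tables tiling the toy karyotype.

    Profiles: ``diploid-balanced`` (one A=B=1 segment per chromosome, all
    scar scores 0), ``hrd-like`` (telomeric imbalances, long interstitial
    LOH and >= 10 Mb state switches on every chromosome, boundaries
    jittered by the seed), or a custom DataFrame passed through after
    validation.
    """
    if karyotype is None:
        karyotype = scars.toy_karyotype()
    if isinstance(profile, pd.DataFrame):
        return scars.validate_segments(profile, karyotype)

    rows = []
    if profile == "diploid-balanced":
        for row in karyotype.itertuples():
            rows.append((row.chrom, 1, row.length, 1, 1))
    elif profile == "hrd-like":
        rng = np.random.default_rng(seed)
        for row in karyotype.itertuples():
            j = rng.integers(-2_000_000, 2_000_001, size=3)
            # p arm: telomeric AI then a long interstitial LOH block
            t1 = 18_000_000 + j[0]
            t2 = min(t1 + 22_000_000 + j[1], row.cen_start - 1_000_000)
            rows.append((row.chrom, 1, t1, 2, 1))               # ntAI
            rows.append((row.chrom, t1 + 1, t2, 1, 0))          # HRD-LOH (>15 Mb)
            rows.append((row.chrom, t2 + 1, row.cen_end, 1, 1))
            # q arm: two >= 10 Mb states switching mid-arm -> one LST
            q_mid = (row.cen_end + row.length) // 2 + j[2]
            rows.append((row.chrom, row.cen_end + 1, q_mid, 2, 2))
            rows.append((row.chrom, q_mid + 1, row.length, 1, 1))
    else:
        raise ValueError(f"unknown segment profile {profile!r}")
    seg = pd.DataFrame(rows, columns=scars.SEGMENT_COLUMNS)
    return scars.validate_segments(seg, karyotype)


def simulate_cellularity_grid(truth: SimTruth, n_points: int = 99,
                              sd: float = 0.05, seed: int | None = None) -> pd.DataFrame:
    """Sequenza-style (cellularity, ploidy, posterior) grid centered on
    the truth cellularity with the stated posterior spread."""
    # keep the grid mean inside (0,1): sequenza grids never put mass at 1
    m = float(np.clip(truth.cellularity, 0.02, 0.98))
    v = min(sd**2, m * (1 - m) * 0.5)
    k = m * (1.0 - m) / v - 1.0
    from scipy.stats import beta as beta_dist

    grid = np.linspace(0.01, 0.99, n_points)
    dens = beta_dist.pdf(grid, m * k, (1 - m) * k)
    dens /= dens.sum()
    return pd.DataFrame({"cellularity": grid, "ploidy": 2.0, "posterior": dens})


def with_seed(truth: SimTruth, seed: int) -> SimTruth:
    return replace(truth, seed=seed)
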