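"""Heterozygous vs homozygous classification of a subclonal deletion.

A deletion that removes one allele skews the variant allele frequencies
(VAFs) of germline-heterozygous SNPs inside the lost region: at
cellularity c and deleted-cell fraction f, the retained allele is read at
1/(2 - c*f) and the lost allele at (1 - c*f)/(2 - c*f). A homozygous
deletion removes both alleles equally, so VAFs stay at 1/2 while the
total depth drops. The test compares marginal likelihoods of the two
dosage patterns over a binomial read-count model, averaging over the
joint (cellularity, loss) uncertainty produced upstream; it is the
package's pinned form of a subclonal-LOH statistic whose published
description leaves the likelihood unspecified.

The analysis is restricted to the maximally lost subregion of the gene
first (partial deletions would otherwise dilute the VAF pattern with
copy-neutral SNPs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .clonality import CellularityPosterior, LossDistribution
from .coverage import NormalizedCoveragePair

logger = logging.getLogger(__name__)

HET = "heterozygous"
HOM = "homozygous"
INDETERMINATE = "indeterminate"


@dataclass
class SubregionSelection:
    """Bin index range [start, end) of the most-lost segment."""

    start: int
    end: int
    no_loss_signal: bool
    segment_bounds: list[int]  # changepoints incl. 0 and n


@dataclass
class ZygosityCall:
    call: str
    log10_bayes_factor: float
    logL_het: float
    logL_hom: float
    n_snps_used: int
    subregion: tuple[int, int] | None = None
    reason: str = ""


def expected_vaf(c: float, f: float, zygosity: str) -> tuple[float, float]:
    """Expected VAFs (retained allele, lost allele) of a germline-het SNP.

    Under a heterozygous deletion in a fraction f of tumor cells at
    cellularity c, the bulk carries 2 - c*f copies of the locus per cell
    on average: 1 retained-allele copy everywhere and 1 - c*f lost-allele
    copies. A homozygous deletion removes both alleles symmetrically, so
    the pair is (1/2, 1/2) for any (c, f). The pair always sums to 1.
    """
    if not 0.0 < c <= 1.0:
        raise ValueError("cellularity must be in (0, 1]")
    if not 0.0 <= f <= 1.0:
        raise ValueError("deleted-cell fraction must be in [0, 1]")
    if zygosity == HOM:
        return 0.5, 0.5
    if zygosity == HET:
        cf = c * f
        return 1.0 / (2.0 - cf), (1.0 - cf) / (2.0 - cf)
    if zygosity == "none":
        return 0.5, 0.5
    raise ValueError(f"unknown zygosity {zygosity!r}")


def _sse(x: np.ndarray) -> float:
    return float(np.sum((x - x.mean()) ** 2))


def _best_split(x: np.ndarray, min_size: int) -> tuple[int | None, float]:
    """Best single changepoint by residual sum of squares; exhaustive scan."""
    n = len(x)
    best_k, best_cost = None, _sse(x)
    csum = np.cumsum(x)
    csq = np.cumsum(x**2)
    for k in range(min_size, n - min_size + 1):
        left = csq[k - 1] - csum[k - 1] ** 2 / k
        right = (csq[-1] - csq[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
        cost = left + right
        if cost < best_cost - 1e-12:
            best_cost, best_k = cost, k
    return best_k, best_cost


def select_lost_subregion(
    pair: NormalizedCoveragePair,
    min_segment: int = 20,
    min_split: int = 5,
    no_loss_ratio: float = 0.95,
) -> SubregionSelection:
    """Locate the most-lost part of the window by binary segmentation.

    The per-bin log coverage ratio is segmented recursively; a split is
    accepted when it lowers the Gaussian BIC (two extra parameters per
    changepoint). Among the resulting segments of length >= min_segment,
    the one with the lowest mean log-ratio is returned; with no accepted
    changepoint the whole window is returned, flagged "no loss signal"
    when its mean ratio is above ``no_loss_ratio``.
    """
    n = len(pair.c_n)
    if n < min_segment:
        raise ValueError(f"window of {n} bins shorter than minimum segment {min_segment}")
    eps = 1e-6
    x = np.log((pair.c_t + eps) / (pair.c_n + eps))

    bounds = [0, n]

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        m = len(seg)
        if m < 2 * min_split:
            return
        k, split_cost = _best_split(seg, min_split)
        if k is None:
            return
        full_cost = _sse(seg)
        # Gaussian BIC: m*log(rss/m) + n_params*log(m); the split adds a
        # mean and a changepoint location.
        sig_full = max(full_cost / m, 1e-12)
        sig_split = max(split_cost / m, 1e-12)
        bic_full = m * np.log(sig_full)
        bic_split = m * np.log(sig_split) + 2.0 * np.log(m)
        if bic_split < bic_full:
            bounds.append(lo + k)
            recurse(lo, lo + k)
            recurse(lo + k, hi)

    recurse(0, n)
    bounds = sorted(set(bounds))

    segments = list(zip(bounds[:-1], bounds[1:]))
    eligible = [(lo, hi) for lo, hi in segments if hi - lo >= min_segment]
    if not eligible:
        eligible = [(0, n)]
    lo, hi = min(eligible, key=lambda s: x[s[0]:s[1]].mean())
    mean_ratio = float(np.exp(x[lo:hi].mean()))
    flagged = mean_ratio > no_loss_ratio
    if flagged:
        logger.info("no loss signal: best segment mean ratio %.3f", mean_ratio)
    return SubregionSelection(start=lo, end=hi, no_loss_signal=flagged,
                              segment_bounds=bounds)


def call_zygosity(
    snps: pd.DataFrame,
    loss: LossDistribution,
    posterior: CellularityPosterior | None = None,
    n_draws: int = 2000,
    seed: int | None = None,
    indeterminate_band: float = 0.5,
) -> ZygosityCall:
    """Bayes-factor comparison of heterozygous vs homozygous deletion.

    ``snps`` must carry tumor allele counts of germline-het sites inside
    the selected subregion, with columns ``ref_count``, ``alt_count`` and
    ``depth``. For each joint (c, loss) draw, the deleted-cell fraction
    is solved per hypothesis (f = 2*loss for het since a het deletion
    removes half the copies; f = loss for hom), clipped to [0, 1]. The
    het likelihood is a symmetric 50/50 mixture over which allele was
    lost; the hom likelihood is Binomial(alt | depth, 1/2). Marginal
    log-likelihoods average the per-draw likelihoods; calls inside
    |log10 BF| < ``indeterminate_band`` are indeterminate.
    """
    if snps is None or len(snps) == 0:
        return ZygosityCall(call=INDETERMINATE, log10_bayes_factor=0.0,
                            logL_het=np.nan, logL_hom=np.nan, n_snps_used=0,
                            reason="no usable SNPs")
    alt = snps["alt_count"].to_numpy(dtype=np.int64)
    depth = snps["depth"].to_numpy(dtype=np.int64)
    if np.any(snps["ref_count"].to_numpy(dtype=np.int64) + alt > depth):
        raise ValueError("ref + alt counts exceed depth")

    rng = np.random.default_rng(seed)
    if loss.c_draws is not None and len(loss.c_draws):
        idx = rng.integers(0, len(loss.loss_draws), size=n_draws)
        c = loss.c_draws[idx]
        lvl = loss.loss_draws[idx]
    elif posterior is not None:
        c = rng.beta(posterior.s1, posterior.s2, size=n_draws)
        lvl = rng.choice(loss.loss_draws, size=n_draws)
    else:
        raise ValueError("need cellularity draws or a posterior")
    lvl = np.clip(lvl, 0.0, 1.0)

    # het: f = 2 * loss (loss is the copy fraction, a het deletion removes
    # one of two copies per affected cell)
    cf_het = np.clip(c * np.clip(2.0 * lvl, 0.0, 1.0), 0.0, 1.0 - 1e-12)
    v_ret = 1.0 / (2.0 - cf_het)  # (n_draws,)
    v_lost = (1.0 - cf_het) / (2.0 - cf_het)

    # per-draw x per-snp log-likelihood matrices
    lp_ret = binom.logpmf(alt[None, :], depth[None, :], v_ret[:, None])
    lp_lost = binom.logpmf(alt[None, :], depth[None, :], v_lost[:, None])
    lp_mix = np.logaddexp(lp_ret, lp_lost) - np.log(2.0)
    per_draw_het = lp_mix.sum(axis=1)
    logL_het = float(logsumexp(per_draw_het) - np.log(n_draws))

    # hom: VAF stays 1/2 for every (c, f); likelihood has no draw dependence
    logL_hom = float(binom.logpmf(alt, depth, 0.5).sum())

    log10_bf = (logL_het - logL_hom) / np.log(10.0)
    if not np.isfinite(log10_bf):
        raise ValueError("non-finite Bayes factor")
    if abs(log10_bf) < indeterminate_band:
        call = INDETERMINATE
    else:
        call = HET if log10_bf > 0 else HOM
    return ZygosityCall(call=call, log10_bayes_factor=float(log10_bf),
                        logL_het=logL_het, logL_hom=logL_hom,
                        n_snps_used=len(snps))
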