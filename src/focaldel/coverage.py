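"""Paired tumor-normal coverage modelling over a single gene window.

The caller works at the scale of one gene: per-base depths from the tumor
and its matched normal are collected into fixed-width bins (50 bp by
default), each track is normalized by its own mean sequencing depth, and
the normalized tumor bins are regressed on the normalized normal bins.
The fitted slope ``beta0`` estimates the tumor/normal coverage ratio over
the window: 1 for a copy-neutral gene, 1 - c*f/2 for a heterozygous
deletion present in a fraction ``f`` of tumor cells at cellularity ``c``,
and 1 - c*f for a homozygous deletion.

Significance of an observed slope is judged against an empirical null
built from slopes of presumed copy-neutral housekeeping genes fitted on
the same sample pair, which absorbs sample-specific technical variation
(library complexity, batch) that a parametric null would miss.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True)
class Region:
    """Genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def parse(cls, text: str) -> "Region":
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse region string {text!r}")
        chrom, start, end = m.groups()
        return cls(chrom, int(start.replace(",", "")), int(end.replace(",", "")))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class BinnedCoverage:
    """Per-bin mean depth over a region, plus the depth used to normalize."""

    sample_id: str
    region: Region
    bin_width: int
    values: np.ndarray
    mean_depth: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = n_bins(self.region.length, self.bin_width)
        if len(self.values) != expected:
            raise ValueError(
                f"{len(self.values)} bins but region of {self.region.length} bp "
                f"at {self.bin_width} bp/bin implies {expected}"
            )
        if np.any(self.values < 0):
            raise ValueError("negative bin depths")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass
class NormalizedCoveragePair:
    """Tumor and normal bin vectors on one grid, each scaled by its mean depth."""

    c_n: np.ndarray
    c_t: np.ndarray
    region: Region
    bin_width: int

    def __post_init__(self) -> None:
        self.c_n = np.asarray(self.c_n, dtype=float)
        self.c_t = np.asarray(self.c_t, dtype=float)
        if self.c_n.shape != self.c_t.shape:
            raise ValueError("normal and tumor bin vectors differ in length")


@dataclass
class LossRegression:
    """OLS fit of normalized tumor bins on normal bins.

    ``beta0`` is the slope (tumor/normal ratio estimate), ``sigma`` its
    standard error, ``alpha`` the intercept used as an outlier diagnostic.
    """

    alpha: float
    beta0: float
    sigma: float
    r2: float
    n_bins_used: int
    outlier_mask: np.ndarray
    suspect_alpha: bool = False


@dataclass
class HousekeepingNull:
    """Empirical slope null from a panel of copy-neutral genes (same pair)."""

    slopes: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        if len(self.slopes) < 3:
            raise ValueError("housekeeping panel needs at least 3 genes")
        self.mean = float(np.mean(self.slopes))
        self.sd = float(np.std(self.slopes, ddof=1))


def n_bins(region_length: int, bin_width: int) -> int:
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    return -(-region_length // bin_width)


def bin_coverage(
    depth,
    region: Region | str,
    bin_width: int = 50,
    mean_depth: float | None = None,
    sample_id: str = "",
) -> BinnedCoverage:
    """Collect per-base depths into fixed-width bins of mean depth.

    Parameters
    ----------
    depth : pandas.DataFrame or mapping
        Per-base depths with columns (chrom, pos, depth), 1-based
        positions, or any mapping/Series position -> depth for the
        region's chromosome.
    region : Region or str
        Target window, 1-based inclusive.
    bin_width : int
        Bin width in bp; the final bin may be partial and its mean is
        taken over its actual span, so a constant-depth input yields a
        constant bin vector.
    mean_depth : float, optional
        Genome- or panel-wide mean depth used downstream for
        normalization. Defaults to the mean depth over the region
        (logged), which is only appropriate when the region is known to
        be copy-neutral in the sample.

    Positions absent from ``depth`` count as depth 0 (logged).
    """
    if isinstance(region, str):
        region = Region.parse(region)
    if region.length < 1:
        raise ValueError("empty region")
    d = n_bins(region.length, bin_width)

    if hasattr(depth, "columns"):  # DataFrame in (chrom, pos, depth) layout
        cols = list(depth.columns)
        sub = depth[depth[cols[0]].astype(str) == region.chrom]
        pos = sub[cols[1]].to_numpy(dtype=np.int64)
        val = sub[cols[2]].to_numpy(dtype=float)
    else:  # mapping / Series
        pos = np.fromiter(depth.keys(), dtype=np.int64, count=len(depth))
        val = np.fromiter(depth.values(), dtype=float, count=len(depth))

    inside = (pos >= region.start) & (pos <= region.end)
    pos, val = pos[inside], val[inside]
    n_missing = region.length - len(np.unique(pos))
    if n_missing > 0:
        logger.info("region %s: %d positions without depth treated as 0", region, n_missing)

    idx = (pos - region.start) // bin_width
    sums = np.bincount(idx, weights=val, minlength=d)
    spans = np.full(d, bin_width, dtype=float)
    spans[-1] = region.length - (d - 1) * bin_width  # partial final bin
    values = sums / spans

    if mean_depth is None:
        mean_depth = float(val.sum() / region.length) if len(val) else 0.0
        logger.info("mean_depth not supplied; using region mean %.3f", mean_depth)
    return BinnedCoverage(sample_id, region, bin_width, values, mean_depth)


def normalize_pair(normal: BinnedCoverage, tumor: BinnedCoverage) -> NormalizedCoveragePair:
    """Divide each bin vector by its sample's own mean sequencing depth."""
    if normal.region != tumor.region or normal.bin_width != tumor.bin_width:
        raise ValueError("normal and tumor are on different bin grids")
    if normal.mean_depth <= 0 or tumor.mean_depth <= 0:
        raise ValueError("zero mean depth")
    return NormalizedCoveragePair(
        c_n=normal.values / normal.mean_depth,
        c_t=tumor.values / tumor.mean_depth,
        region=normal.region,
        bin_width=normal.bin_width,
    )


class PairedLossRegressor(BaseEstimator, RegressorMixin):
    """OLS of normalized tumor bins on normal bins with outlier trimming.

    The slope is the raw estimate of the tumor/normal coverage ratio over
    the window. Bins whose standardized residual exceeds ``resid_z`` are
    removed iteratively (at most ``max_rounds`` rounds). Bins with zero
    normal coverage never enter the fit. Fits with |intercept| >
    ``alpha_suspect`` are flagged: a large intercept indicates residual
    structure (unremoved outliers or normalization failure) rather than a
    pure proportional loss.

    Attributes
    ----------
    beta0_ : float            slope (tumor/normal ratio estimate)
    alpha_ : float            intercept
    sigma_ : float            standard error of the slope
    r2_ : float               coefficient of determination on kept bins
    outlier_mask_ : ndarray   True where a bin was excluded
    n_bins_used_ : int
    """

    def __init__(self, resid_z: float = 3.0, max_rounds: int = 5,
                 min_bins: int = 10, alpha_suspect: float = 0.1):
        self.resid_z = resid_z
        self.max_rounds = max_rounds
        self.min_bins = min_bins
        self.alpha_suspect = alpha_suspect

    def fit(self, X, y=None):
        """Fit on a NormalizedCoveragePair (or anything with c_n/c_t), or
        on (c_n, c_t) arrays."""
        if hasattr(X, "c_n"):
            c_n, c_t = X.c_n, X.c_t
        else:
            c_n = np.asarray(X, dtype=float).ravel()
            c_t = np.asarray(y, dtype=float).ravel()
        if c_n.shape != c_t.shape:
            raise ValueError("c_n and c_t differ in length")

        keep = c_n > 0  # zero-normal bins carry no ratio information
        for _ in range(self.max_rounds + 1):
            if keep.sum() < self.min_bins:
                raise ValueError(f"fewer than {self.min_bins} usable bins")
            if np.var(c_n[keep]) == 0:
                raise ValueError("degenerate fit: constant normal coverage")
            res = stats.linregress(c_n[keep], c_t[keep])
            resid = c_t - (res.intercept + res.slope * c_n)
            s = resid[keep].std(ddof=2)
            if s == 0:
                break  # exact fit, nothing to trim
            new_out = keep & (np.abs(resid) > self.resid_z * s)
            if not new_out.any():
                break
            keep &= ~new_out

        self.alpha_ = float(res.intercept)
        self.beta0_ = float(res.slope)
        self.sigma_ = float(res.stderr)
        self.r2_ = float(res.rvalue**2)
        self.outlier_mask_ = ~keep
        self.n_bins_used_ = int(keep.sum())
        if abs(self.alpha_) > self.alpha_suspect:
            logger.warning("intercept %.3f exceeds %.2f; fit flagged suspect",
                           self.alpha_, self.alpha_suspect)
        return self

    def predict(self, X):
        check_is_fitted(self, "beta0_")
        return self.alpha_ + self.beta0_ * np.asarray(X, dtype=float).ravel()

    def result_(self) -> LossRegression:
        check_is_fitted(self, "beta0_")
        return LossRegression(
            alpha=self.alpha_, beta0=self.beta0_, sigma=self.sigma_, r2=self.r2_,
            n_bins_used=self.n_bins_used_, outlier_mask=self.outlier_mask_,
            suspect_alpha=abs(self.alpha_) > self.alpha_suspect,
        )


def fit_paired_slope(pair: NormalizedCoveragePair, **kwargs) -> LossRegression:
    """Fit the paired regression; thin wrapper over PairedLossRegressor."""
    return PairedLossRegressor(**kwargs).fit(pair).result_()


def fit_housekeeping_null(pairs: list[NormalizedCoveragePair], **kwargs) -> HousekeepingNull:
    """Fit one slope per housekeeping gene on the same sample pair."""
    slopes = [fit_paired_slope(p, **kwargs).beta0 for p in pairs]
    return HousekeepingNull(np.array(slopes))


def significance_vs_housekeeping(beta0_target: float, null: HousekeepingNull):
    """One-sided z-test of the target slope against the housekeeping null.

    Returns ``(z, p)`` where p is the lower-tail normal probability: small
    p means the target slope sits far below the copy-neutral panel, i.e.
    evidence of loss. With a degenerate panel (sd = 0) p is NaN and a
    warning is logged.
    """
    if null.sd == 0:
        logger.warning("housekeeping panel has zero slope variance; p undefined")
        return np.nan, np.nan
    z = (beta0_target - null.mean) / null.sd
    return float(z), float(stats.norm.cdf(z))
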