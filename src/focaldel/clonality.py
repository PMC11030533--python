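"""Uncertainty propagation from slope and cellularity to the level of loss.

The raw slope beta0 measures the tumor/normal coverage ratio in the bulk
sample, which dilutes the true per-tumor-cell signal by the normal-cell
admixture. With cellularity c, the cellularity-adjusted slope is

    beta_t = (beta - 1 + c) / c,

and the level of loss (fraction of tumor-cell gene copies deleted) is
distributed as 1 - beta_t = (1 - beta) / c. Both slope uncertainty
(beta ~ Normal(beta0, sigma)) and cellularity uncertainty (c ~ Beta(s1, s2),
moment-matched to a gridded posterior such as sequenza emits) are
propagated by Monte Carlo; the reported point estimate is the median of
the loss draws, with 66% and 95% percentile intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .coverage import HousekeepingNull, LossRegression, significance_vs_housekeeping

logger = logging.getLogger(__name__)

MIN_CELLULARITY = 0.05  # draws below this are rejected: loss = (1-beta)/c blows up
VARIANCE_FLOOR = 1e-6


@dataclass
class CellularityPosterior:
    """Gridded marginal posterior of cellularity with fitted Beta shapes."""

    grid: np.ndarray
    densities: np.ndarray
    s1: float
    s2: float
    ploidy: float | None = None  # carried metadata, not modelled

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.s1 <= 0 or self.s2 <= 0:
            raise ValueError("Beta shape parameters must be positive")


@dataclass
class LossDistribution:
    """Monte-Carlo distribution of the level of loss, 1 - beta_t."""

    beta_draws: np.ndarray
    c_draws: np.ndarray
    n_draws: int
    seed: int | None
    n_rejected: int = 0
    loss_draws: np.ndarray = field(init=False)
    betat_draws: np.ndarray = field(init=False)
    point_estimate: float = field(init=False)
    interval66: tuple[float, float] = field(init=False)
    interval95: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.betat_draws = (self.beta_draws - 1.0 + self.c_draws) / self.c_draws
        self.loss_draws = 1.0 - self.betat_draws  # == (1 - beta) / c
        self.point_estimate = float(np.clip(np.median(self.loss_draws), 0.0, 1.0))
        lo66, hi66 = np.percentile(self.loss_draws, [17.0, 83.0])
        lo95, hi95 = np.percentile(self.loss_draws, [2.5, 97.5])
        self.interval66 = (float(lo66), float(hi66))
        self.interval95 = (float(lo95), float(hi95))


@dataclass
class DeletionCall:
    call: str  # "deleted" | "intact"
    z: float
    p: float
    loss_point: float
    interval66: tuple[float, float]
    audit: dict


def fit_beta_posterior(grid, densities, ploidy: float | None = None) -> CellularityPosterior:
    """Moment-match a Beta distribution to a gridded cellularity posterior.

    With grid mean m and variance v, the shapes are
    s1 = m * (m(1-m)/v - 1) and s2 = (1-m) * (m(1-m)/v - 1).
    A variance floor of 1e-6 handles near-degenerate grids (all mass on
    one point), which would otherwise give infinite concentration.
    """
    grid = np.asarray(grid, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if grid.shape != densities.shape:
        raise ValueError("grid and densities differ in length")
    if np.any(densities < 0):
        raise ValueError("negative posterior density")
    if (densities > 0).sum() < 3 and len(np.unique(grid[densities > 0])) > 1:
        raise ValueError("need at least 3 grid points with positive density")
    total = densities.sum()
    if total <= 0:
        raise ValueError("posterior densities sum to zero")
    w = densities / total

    m = float(np.sum(w * grid))
    v = float(np.sum(w * (grid - m) ** 2))
    if not 0.0 < m < 1.0:
        raise ValueError(f"grid mean cellularity {m:.3f} outside (0, 1)")
    if v < VARIANCE_FLOOR:
        logger.info("grid variance %.2e below floor; clamped to %.0e", v, VARIANCE_FLOOR)
        v = VARIANCE_FLOOR
    k = m * (1.0 - m) / v - 1.0
    if k <= 0:
        raise ValueError("grid variance too large for a Beta fit")
    return CellularityPosterior(grid, w, s1=m * k, s2=(1.0 - m) * k, ploidy=ploidy)


def propagate_loss(
    beta0: float,
    sigma: float,
    s1: float,
    s2: float,
    n_draws: int = 10_000,
    seed: int | None = None,
    min_cellularity: float = MIN_CELLULARITY,
) -> LossDistribution:
    """Draw (beta, c) pairs and form the loss distribution (1 - beta)/c.

    Cellularity draws below ``min_cellularity`` are rejected and resampled
    (count logged); if the Beta posterior puts more than half its mass
    below the cutoff the propagation is refused rather than silently
    returning an extrapolation-dominated distribution.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000 for stable intervals")
    rng = np.random.default_rng(seed)

    from scipy.stats import beta as beta_dist

    if beta_dist.cdf(min_cellularity, s1, s2) > 0.5:
        raise ValueError("more than 50% of cellularity mass below cutoff; "
                         "posterior too close to zero purity")

    beta_draws = rng.normal(beta0, sigma, size=n_draws)
    c_draws = rng.beta(s1, s2, size=n_draws)
    n_rejected = 0
    bad = c_draws < min_cellularity
    while bad.any():
        n_rejected += int(bad.sum())
        c_draws[bad] = rng.beta(s1, s2, size=int(bad.sum()))
        bad = c_draws < min_cellularity
    if n_rejected:
        logger.info("rejected and resampled %d low-cellularity draws", n_rejected)

    return LossDistribution(beta_draws=beta_draws, c_draws=c_draws,
                            n_draws=n_draws, seed=seed, n_rejected=n_rejected)


def call_loss(
    regression: LossRegression,
    null: HousekeepingNull,
    loss: LossDistribution,
    p_threshold: float = 0.05,
    loss_threshold: float = 0.05,
) -> DeletionCall:
    """Binary deletion call: significant vs the housekeeping null AND a
    66%-interval lower bound clear of ``loss_threshold``.

    Both conditions are required: the z-test guards against technical
    slope wobble, the interval bound guards against significant-but-tiny
    losses within measurement noise of zero.
    """
    z, p = significance_vs_housekeeping(regression.beta0, null)
    significant = bool(np.isfinite(p) and p < p_threshold)
    material = bool(loss.interval66[0] > loss_threshold)
    call = "deleted" if (significant and material) else "intact"
    audit = {
        "beta0": regression.beta0, "sigma": regression.sigma,
        "alpha": regression.alpha, "suspect_alpha": regression.suspect_alpha,
        "z": z, "p": p, "p_threshold": p_threshold,
        "loss_point": loss.point_estimate,
        "interval66": list(loss.interval66), "interval95": list(loss.interval95),
        "loss_threshold": loss_threshold, "n_draws": loss.n_draws,
        "seed": loss.seed, "n_rejected_draws": loss.n_rejected,
        "housekeeping_slopes": list(map(float, null.slopes)),
    }
    return DeletionCall(call=call, z=z, p=p, loss_point=loss.point_estimate,
                        interval66=loss.interval66, audit=audit)
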