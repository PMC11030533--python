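"""Binning, normalization, the paired regression and the housekeeping null."""

import numpy as np
import pandas as pd
import pytest

from focaldel import simulate
from focaldel.coverage import (
    BinnedCoverage,
    HousekeepingNull,
    PairedLossRegressor,
    Region,
    bin_coverage,
    fit_housekeeping_null,
    fit_paired_slope,
    n_bins,
    normalize_pair,
    significance_vs_housekeeping,
)
from tests.conftest import GRCH37_WINDOW, GRCH38_WINDOW, make_pair


def depth_frame(chrom, start, depths):
    return pd.DataFrame({"chrom": chrom,
                         "pos": np.arange(start, start + len(depths)),
                         "depth": depths})


class TestBinning:
    @pytest.mark.parametrize("window,expected", [(GRCH37_WINDOW, 1447),
                                                 (GRCH38_WINDOW, 1536)])
    def test_gene_window_bin_counts(self, window, expected):
        region = Region.parse(window)
        assert n_bins(region.length, 50) == expected

    def test_constant_depth_two_bins(self):
        df = depth_frame("chr1", 101, np.full(100, 30.0))
        bc = bin_coverage(df, Region("chr1", 101, 200), bin_width=50)
        np.testing.assert_allclose(bc.values, [30.0, 30.0])

    def test_partial_final_bin_keeps_constant_exact(self):
        region = Region.parse(GRCH37_WINDOW)  # 72,333 bp: final bin is 33 bp
        df = depth_frame(region.chrom, region.start, np.full(region.length, 17.0))
        bc = bin_coverage(df, region, bin_width=50)
        assert len(bc.values) == 1447
        np.testing.assert_allclose(bc.values, 17.0)

    def test_missing_positions_count_as_zero(self):
        df = depth_frame("chr1", 1, np.full(50, 10.0))  # second bin absent
        bc = bin_coverage(df, Region("chr1", 1, 100), bin_width=50)
        np.testing.assert_allclose(bc.values, [10.0, 0.0])

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            bin_coverage(depth_frame("chr1", 1, [1.0]), Region("chr1", 1, 1), 0)


class TestNormalization:
    def test_constant_at_mean_depth_gives_ones(self):
        region = Region("chr1", 1, 500)
        bc = BinnedCoverage("s", region, 50, np.full(10, 42.0), mean_depth=42.0)
        pair = normalize_pair(bc, bc)
        np.testing.assert_allclose(pair.c_n, 1.0)
        np.testing.assert_allclose(pair.c_t, 1.0)

    def test_scale_invariance(self):
        region = Region("chr1", 1, 500)
        vals = np.linspace(10, 50, 10)
        a = normalize_pair(BinnedCoverage("n", region, 50, vals, 30.0),
                           BinnedCoverage("t", region, 50, vals, 30.0))
        b = normalize_pair(BinnedCoverage("n", region, 50, 2 * vals, 60.0),
                           BinnedCoverage("t", region, 50, 2 * vals, 60.0))
        np.testing.assert_allclose(a.c_n, b.c_n)

    def test_normalized_tumor_mean_tracks_truth_ratio(self, het_pair_08_075):
        pair, truth = het_pair_08_075
        assert abs(pair.c_t.mean() / pair.c_n.mean() - truth.expected_ratio) < 0.01

    def test_grid_mismatch_rejected(self):
        a = BinnedCoverage("n", Region("chr1", 1, 500), 50, np.ones(10), 1.0)
        b = BinnedCoverage("t", Region("chr1", 1, 450), 50, np.ones(9), 1.0)
        with pytest.raises(ValueError):
            normalize_pair(a, b)


class TestPairedRegression:
    def test_identical_tracks_give_unit_slope(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.5, 1.5, 200)
        reg = PairedLossRegressor().fit(x, x)
        assert reg.beta0_ == pytest.approx(1.0, abs=1e-10)
        assert reg.alpha_ == pytest.approx(0.0, abs=1e-10)

    def test_exact_half_coverage(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.5, 1.5, 200)
        res = fit_paired_slope(
            type("P", (), {"c_n": x, "c_t": 0.5 * x})())
        assert res.beta0 == pytest.approx(0.5, abs=1e-10)
        assert res.alpha == pytest.approx(0.0, abs=1e-10)

    def test_orientation_exact_on_proportional_data(self):
        # the proportionality constant is recovered exactly whichever
        # vector would be noisier in a stochastic setting
        rng = np.random.default_rng(2)
        x = rng.uniform(0.2, 2.0, 100)
        for k in (0.3, 0.7, 1.0):
            assert fit_paired_slope(
                type("P", (), {"c_n": x, "c_t": k * x})()
            ).beta0 == pytest.approx(k, abs=1e-10)

    def test_simulated_het_loss_slope(self, het_pair_08_075):
        pair, truth = het_pair_08_075
        res = fit_paired_slope(pair)
        assert abs(res.beta0 - truth.expected_ratio) <= 2 * res.sigma + 0.01
        assert res.sigma > 0

    def test_outlier_bins_are_trimmed(self, region37):
        truth = simulate.SimTruth(zygosity="none", seed=21)
        pair, _ = make_pair(truth, region37)
        clean = fit_paired_slope(pair)
        pair.c_t[7] += 5.0  # an amplified artifact bin
        res = fit_paired_slope(pair)
        assert res.outlier_mask[7]
        assert res.beta0 == pytest.approx(clean.beta0, abs=0.01)

    def test_constant_normal_coverage_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_paired_slope(type("P", (), {"c_n": np.ones(50),
                                            "c_t": np.ones(50)})())

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            fit_paired_slope(type("P", (), {"c_n": np.arange(5.0),
                                            "c_t": np.arange(5.0)})())

    def test_increasing_loss_decreases_slope(self, region37):
        slopes = []
        for cf, (c, f) in zip([0.2, 0.45, 0.72],
                              [(0.5, 0.4), (0.9, 0.5), (0.9, 0.8)]):
            vals = []
            for seed in (1, 2, 3):
                truth = simulate.SimTruth(cellularity=c, subclonal_fraction=f,
                                          zygosity="heterozygous", seed=seed)
                pair, _ = make_pair(truth, region37)
                vals.append(fit_paired_slope(pair).beta0)
            slopes.append(np.mean(vals))
        assert slopes[0] > slopes[1] > slopes[2]


class TestHousekeepingNull:
    def test_target_at_panel_mean(self):
        null = HousekeepingNull(np.array([0.98, 1.0, 1.02, 1.0]))
        z, p = significance_vs_housekeeping(null.mean, null)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_seeded_panel_z_matches_direct_formula(self):
        rng = np.random.default_rng(12)
        slopes = rng.normal(1.0, 0.02, size=14)
        null = HousekeepingNull(slopes)
        z, p = significance_vs_housekeeping(0.9, null)
        expected_z = (0.9 - slopes.mean()) / slopes.std(ddof=1)
        assert z == pytest.approx(expected_z)
        assert z < -4 and p < 1e-4

    def test_slope_above_mean_is_not_loss(self):
        null = HousekeepingNull(np.array([0.99, 1.0, 1.01]))
        _, p = significance_vs_housekeeping(1.05, null)
        assert p > 0.5

    def test_zero_sd_panel_returns_nan(self):
        null = HousekeepingNull(np.array([1.0, 1.0, 1.0]))
        z, p = significance_vs_housekeeping(0.9, null)
        assert np.isnan(p)

    def test_panel_size_floor(self):
        with pytest.raises(ValueError):
            HousekeepingNull(np.array([1.0, 1.0]))

    def test_fit_on_simulated_panel(self, region37):
        pairs = []
        for g in range(5):
            truth = simulate.SimTruth(zygosity="none", seed=100 + g)
            pair, _ = make_pair(truth, Region("chr1", 1, 25_000))
            pairs.append(pair)
        null = fit_housekeeping_null(pairs)
        assert abs(null.mean - 1.0) < 0.02
        assert null.sd > 0
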