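"""Dosage model, lost-subregion selection and the het/hom Bayes test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from focaldel import simulate
from focaldel.clonality import fit_beta_posterior, propagate_loss
from focaldel.coverage import Region
from focaldel.zygosity import (
    HET,
    HOM,
    INDETERMINATE,
    call_zygosity,
    expected_vaf,
    select_lost_subregion,
)
from tests.conftest import make_pair


class TestExpectedVaf:
    def test_no_loss_is_balanced(self):
        assert expected_vaf(0.7, 0.0, HET) == (0.5, 0.5)

    def test_clonal_het_deletion_fixes_retained_allele(self):
        v_ret, v_lost = expected_vaf(1.0, 1.0, HET)
        assert v_ret == pytest.approx(1.0)
        assert v_lost == pytest.approx(0.0)

    def test_subclonal_het_dosage(self):
        # c=0.5, f=0.8: 1/(2-0.4)=0.625 and 0.6/1.6=0.375
        v_ret, v_lost = expected_vaf(0.5, 0.8, HET)
        assert v_ret == pytest.approx(0.625)
        assert v_lost == pytest.approx(0.375)

    def test_homozygous_stays_balanced(self):
        assert expected_vaf(0.9, 0.9, HOM) == (0.5, 0.5)

    @given(c=st.floats(0.01, 1.0), f=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_pair_sums_to_one(self, c, f):
        v_ret, v_lost = expected_vaf(c, f, HET)
        assert v_ret + v_lost == pytest.approx(1.0)
        assert v_ret >= v_lost

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            expected_vaf(0.0, 0.5, HET)
        with pytest.raises(ValueError):
            expected_vaf(0.5, 1.5, HET)


class TestSelectLostSubregion:
    def test_uniform_loss_returns_whole_region(self):
        region = Region("chr5", 1, 50_000)
        truth = simulate.SimTruth(cellularity=0.9, subclonal_fraction=0.8, seed=31)
        pair, _ = make_pair(truth, region)
        sel = select_lost_subregion(pair)
        assert (sel.start, sel.end) == (0, len(pair.c_n))
        assert not sel.no_loss_signal

    def test_step_loss_boundary_matches_exhaustive_oracle(self):
        region = Region("chr5", 1, 50_000)
        truth = simulate.SimTruth(cellularity=1.0, subclonal_fraction=1.0,
                                  zygosity=HOM, seed=32)
        pair, _ = make_pair(truth, region, deleted_subinterval=(0.0, 0.5))
        n = len(pair.c_n)
        sel = select_lost_subregion(pair)

        # oracle: exhaustive single-changepoint least-squares search
        x = np.log((pair.c_t + 1e-6) / (pair.c_n + 1e-6))
        costs = [np.var(x[:k]) * k + np.var(x[k:]) * (n - k)
                 for k in range(5, n - 5)]
        k_star = int(np.argmin(costs)) + 5
        assert sel.start == 0
        assert abs(sel.end - k_star) <= 3
        assert abs(sel.end - n // 2) <= 3  # truth boundary

    def test_no_loss_flagged(self):
        region = Region("chr5", 1, 50_000)
        truth = simulate.SimTruth(zygosity="none", seed=33)
        pair, _ = make_pair(truth, region)
        sel = select_lost_subregion(pair)
        assert (sel.start, sel.end) == (0, len(pair.c_n))
        assert sel.no_loss_signal

    def test_region_shorter_than_minimum_rejected(self):
        region = Region("chr5", 1, 500)
        truth = simulate.SimTruth(seed=34)
        pair, _ = make_pair(truth, region)
        with pytest.raises(ValueError):
            select_lost_subregion(pair)


def truth_loss_distribution(truth: simulate.SimTruth, sigma=0.005, seed=0):
    """Loss distribution consistent with a simulation truth."""
    grid = simulate.simulate_cellularity_grid(truth)
    post = fit_beta_posterior(grid["cellularity"], grid["posterior"])
    return propagate_loss(truth.expected_ratio, sigma, post.s1, post.s2,
                          seed=seed), post


class TestCallZygosity:
    def test_near_zero_loss_is_indeterminate(self):
        truth = simulate.SimTruth(cellularity=0.8, subclonal_fraction=0.01,
                                  zygosity=HET, seed=41)
        loss, post = truth_loss_distribution(truth, seed=41)
        snps = simulate.simulate_het_snps(truth, n_snps=30, depth=60, seed=41)
        call = call_zygosity(snps, loss, posterior=post, seed=41)
        assert call.call == INDETERMINATE

    def test_strong_het_deletion_called_het(self):
        truth = simulate.SimTruth(cellularity=0.9, subclonal_fraction=0.9,
                                  zygosity=HET, seed=5)
        loss, post = truth_loss_distribution(truth, seed=5)
        snps = simulate.simulate_het_snps(truth, n_snps=30, depth=60, seed=5)
        call = call_zygosity(snps, loss, posterior=post, seed=5)
        assert call.call == HET
        assert call.log10_bayes_factor > 2

    def test_subclonal_hom_deletion_called_hom(self):
        truth = simulate.SimTruth(cellularity=0.9, subclonal_fraction=0.6,
                                  zygosity=HOM, seed=5)
        loss, post = truth_loss_distribution(truth, seed=5)
        snps = simulate.simulate_het_snps(truth, n_snps=30, depth=60, seed=5)
        call = call_zygosity(snps, loss, posterior=post, seed=5)
        assert call.call == HOM

    def test_allele_relabeling_symmetry(self):
        truth = simulate.SimTruth(cellularity=0.8, subclonal_fraction=0.7,
                                  zygosity=HET, seed=6)
        loss, post = truth_loss_distribution(truth, seed=6)
        snps = simulate.simulate_het_snps(truth, n_snps=20, depth=60, seed=6)
        flipped = snps.rename(columns={"ref_count": "alt_count",
                                       "alt_count": "ref_count"})
        a = call_zygosity(snps, loss, posterior=post, seed=7)
        b = call_zygosity(flipped, loss, posterior=post, seed=7)
        assert a.logL_het == pytest.approx(b.logL_het, rel=1e-12)
        assert a.logL_hom == pytest.approx(b.logL_hom, rel=1e-12)

    def test_no_snps_indeterminate_with_reason(self):
        truth = simulate.SimTruth(seed=8)
        loss, post = truth_loss_distribution(truth, seed=8)
        call = call_zygosity(pd.DataFrame(), loss, posterior=post)
        assert call.call == INDETERMINATE
        assert call.n_snps_used == 0
        assert call.reason

    def test_counts_exceeding_depth_rejected(self):
        truth = simulate.SimTruth(seed=9)
        loss, post = truth_loss_distribution(truth, seed=9)
        bad = pd.DataFrame({"position": [1], "ref_count": [40],
                            "alt_count": [40], "depth": [60]})
        with pytest.raises(ValueError):
            call_zygosity(bad, loss, posterior=post)

    def test_calibration_on_het_grid(self):
        # truth het with c*f >= 0.3: the vast majority must be called het
        correct = total = 0
        for c in (0.6, 0.8, 1.0):
            for f in (0.5, 0.75, 1.0):
                for rep in range(3):
                    seed = 1000 + int(c * 10) * 100 + int(f * 100) + rep
                    truth = simulate.SimTruth(cellularity=c, subclonal_fraction=f,
                                              zygosity=HET, seed=seed)
                    loss, post = truth_loss_distribution(truth, seed=seed)
                    snps = simulate.simulate_het_snps(truth, n_snps=30, depth=60,
                                                      seed=seed)
                    call = call_zygosity(snps, loss, posterior=post, seed=seed)
                    correct += call.call == HET
                    total += 1
        assert correct / total >= 0.9
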