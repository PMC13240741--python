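import numpy as np
import pytest

from alleleauto.filtering import (
    FilterConfig,
    identify_alleles,
    sigma_mask,
    slope_filter,
    tukey_mask,
)
from alleleauto.models import Anchor, SyntenyBlock
from alleleauto.simulate import SimConfig, simulate_diploid


class TestSigmaMask:
    def test_constant_vector_no_outliers(self):
        assert not sigma_mask([2.0] * 10).any()

    def test_masking_effect_small_sample(self):
        # nine 1.0's + one 100.0: mu = 10.9, s = 31.31, upper fence
        # 104.8 -> the extreme value masks itself
        vals = [1.0] * 9 + [100.0]
        mu, s = np.mean(vals), np.std(vals, ddof=1)
        assert mu + 3 * s > 100.0  # direct recomputation
        assert not sigma_mask(vals, 3).any()

    def test_large_sample_flags_extreme(self):
        vals = [1.0] * 1000 + [100.0]
        mask = sigma_mask(vals, 3)
        assert mask.sum() == 1 and mask[-1]

    def test_nan_never_flagged(self):
        mask = sigma_mask([1.0] * 1000 + [np.nan, 100.0], 3)
        assert not mask[-2] and mask[-1]

    def test_needs_two_finite(self):
        with pytest.raises(ValueError):
            sigma_mask([1.0])


class TestTukeyMask:
    def test_hand_quantiles(self):
        # [1..9, 100]: Q1 = 3.25, Q3 = 7.75 under the 1 + (n-1)p
        # convention, fences [-3.5, 14.5]
        vals = list(range(1, 10)) + [100]
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        assert (q1, q3) == (3.25, 7.75)
        mask = tukey_mask(vals, 1.5)
        assert mask.sum() == 1 and mask[-1]

    def test_wider_i_sweep(self):
        vals = list(range(1, 10)) + [100]
        assert tukey_mask(vals, 8).sum() == 1      # fences [-32.75, 43.75]
        assert tukey_mask(vals, 25).sum() == 0

    def test_constant_vector(self):
        assert not tukey_mask([5.0] * 8).any()

    def test_degenerate_iqr_flags_off_values(self):
        vals = [5.0] * 10 + [6.0]
        mask = tukey_mask(vals, 1.5)
        assert mask.sum() == 1 and mask[-1]

    def test_monotone_in_i(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(0, 1, size=300)
        prev = None
        for i in (1.5, 2.0, 4.0, 8.0):
            flagged = frozenset(np.flatnonzero(tukey_mask(vals, i)))
            if prev is not None:
                assert flagged <= prev
            prev = flagged


def _block(bid, slope, n=6):
    anchors = [
        Anchor(f"a{bid}_{i}", f"b{bid}_{i}", i, i, i * 1e3, i * 1e3)
        for i in range(1, n + 1)
    ]
    return SyntenyBlock(bid, "cA", "cB", anchors, "forward", slope)


class TestSlopeFilter:
    def test_uniform_slopes_kept(self):
        blocks = [_block(i, 1.0) for i in range(10)]
        kept, removed = slope_filter(blocks, FilterConfig(method="tukey"))
        assert len(kept) == 10 and not removed

    def test_aberrant_slope_removed(self):
        slopes = [1.0, 0.98, 1.02, 1.0, 0.99, 1.01, 1.0, 1.0, 0.97, 12.0]
        blocks = [_block(i, s) for i, s in enumerate(slopes)]
        kept, removed = slope_filter(blocks, FilterConfig(method="tukey"))
        assert [b.slope for b in removed] == [12.0]
        # agrees with the mask applied directly to the slope vector
        assert tukey_mask(slopes, 1.5).sum() == 1

    def test_too_few_blocks_no_removal(self):
        blocks = [_block(i, s) for i, s in enumerate([1.0, 1.0, 9.0])]
        kept, removed = slope_filter(blocks, FilterConfig(method="tukey"))
        assert len(kept) == 3 and not removed


class TestIdentifyAlleles:
    def test_no_paralogs_structural_stages_clean(self):
        sim = simulate_diploid(SimConfig(
            n_chrom_pairs=1, genes_per_chrom=200, n_paralogs=0,
            n_inversions=0, rng_seed=3,
        ))
        res = identify_alleles(sim.genes_a, sim.genes_b, sim.chromosome_map)
        r = res.report
        assert r.n_rbh == 200
        assert r.n_same_chrom == r.n_rbh
        assert r.n_colinear == r.n_same_chrom
        assert r.n_saturated_removed == 0 and r.n_slope_removed == 0
        # the Ks layer may trim extreme-tail true pairs, nothing more
        assert r.n_alleles >= 0.99 * r.n_rbh
        assert set(res.table["status"]) <= {"allele", "rejected_ks_outlier"}

    def test_statuses_partition_pairs(self, default_identify):
        table = default_identify.table
        assert table["status"].notna().all()
        assert not table.duplicated(["gene_a", "gene_b"]).any()
        assert not table["gene_a"].duplicated().any()
        assert not table["gene_b"].duplicated().any()

    def test_report_counts_telescope(self, default_identify):
        r = default_identify.report
        assert r.n_rbh >= r.n_same_chrom >= r.n_colinear >= r.n_after_ks >= r.n_alleles
        assert r.n_after_ks == r.n_colinear - r.n_saturated_removed - r.n_ks_removed
        assert r.n_alleles == r.n_after_ks - r.n_slope_removed
        counts = default_identify.table["status"].value_counts()
        assert counts.get("allele", 0) == r.n_alleles
        assert counts.get("rejected_cross_chrom", 0) == r.n_rbh - r.n_same_chrom
        assert counts.get("rejected_ks_outlier", 0) == r.n_ks_removed

    def test_paralog_decoys_removed(self, default_sim, default_identify):
        truth = {
            (a, b): l for a, b, l in default_sim.truth.itertuples(index=False)
        }
        called = {
            tuple(x) for x in default_identify.alleles[["gene_a", "gene_b"]].values
        }
        true_allelic = {k for k, v in truth.items() if v == "allelic"}
        tp = sum(1 for c in called if truth.get(c) == "allelic")
        assert tp / len(called) >= 0.99       # precision
        assert tp / len(true_allelic) >= 0.95  # recall

    def test_tukey_retained_subset_of_sigma(self, default_sim):
        """With near-normal Ks, the i = 1.5 inner fences sit at about
        +/- 2.7 sigma, inside the 3-sigma fences, so the tukey-retained
        set nests within the sigma-retained set."""
        res_s = identify_alleles(
            default_sim.genes_a, default_sim.genes_b,
            default_sim.chromosome_map, config=FilterConfig(method="sigma"),
        )
        res_t = identify_alleles(
            default_sim.genes_a, default_sim.genes_b,
            default_sim.chromosome_map, config=FilterConfig(method="tukey"),
        )
        kept_s = {tuple(x) for x in res_s.alleles[["gene_a", "gene_b"]].values}
        kept_t = {tuple(x) for x in res_t.alleles[["gene_a", "gene_b"]].values}
        assert kept_t <= kept_s

    def test_empty_survivors_is_valid(self):
        sim = simulate_diploid(SimConfig(
            n_chrom_pairs=1, genes_per_chrom=12, n_paralogs=0,
            n_inversions=0, rng_seed=5,
        ))
        # an impossible block size leaves nothing colinear
        res = identify_alleles(
            sim.genes_a, sim.genes_b, sim.chromosome_map,
            config=FilterConfig(min_block_size=50),
        )
        assert res.report.n_alleles == 0
        assert (res.table["status"] == "rejected_non_colinear").all()


def test_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(method="mad")
    with pytest.raises(ValueError):
        FilterConfig(tukey_i=-1)
    with pytest.raises(ValueError):
        FilterConfig(fence="middle")
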