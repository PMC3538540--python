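"""Solid-spine block detection and within-block haplotype EM."""

import numpy as np
import pytest

from catld.blocks import (
    block_haplotype_freqs,
    classify_haplotypes,
    diversity_summary,
    dprime_matrix,
    solid_spine_blocks,
    spine_intervals,
)
from catld.genotype_io import MISSING
from catld.simulate import simulate_panel

from conftest import make_dataset, small_breed_config
from oracles import brute_force_spine


def _sym(entries, m):
    dp = np.full((m, m), 0.0)
    np.fill_diagonal(dp, 1.0)
    for (i, j), v in entries.items():
        dp[i, j] = dp[j, i] = v
    return dp


class TestSpineIntervals:
    def test_worked_example_two_blocks(self):
        # (1,2)=0.9 (1,3)=0.85 (2,3)=0.4 (3,4)=0.95 (2,4)=0.9 (1,4)=0.3
        # (1-based); [1..3] fails because marker 2 is not in LD with end 3
        dp = _sym({(0, 1): 0.9, (0, 2): 0.85, (1, 2): 0.4,
                   (2, 3): 0.95, (1, 3): 0.9, (0, 3): 0.3}, 4)
        assert spine_intervals(dp) == [(0, 1), (2, 3)]

    def test_full_ld_single_block(self):
        assert spine_intervals(np.ones((5, 5))) == [(0, 4)]

    def test_no_ld_no_blocks(self):
        assert spine_intervals(_sym({}, 5)) == []

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(21)
        for _ in range(150):
            m = int(rng.integers(2, 13))
            dp = np.round(rng.random((m, m)), 2)
            dp = np.triu(dp, 1)
            dp = dp + dp.T
            np.fill_diagonal(dp, 1.0)
            if rng.random() < 0.3:  # sprinkle undefined pairs
                i, j = rng.integers(0, m, size=2)
                if i != j:
                    dp[i, j] = dp[j, i] = np.nan
            assert spine_intervals(dp, 0.8) == brute_force_spine(dp, 0.8)

    def test_raising_threshold_never_blocks_more_markers(self):
        rng = np.random.default_rng(22)
        for _ in range(30):
            m = int(rng.integers(4, 12))
            dp = np.round(rng.random((m, m)), 2)
            dp = np.triu(dp, 1)
            dp = dp + dp.T
            np.fill_diagonal(dp, 1.0)
            covered_lo = sum(j - i + 1 for i, j in spine_intervals(dp, 0.6))
            covered_hi = sum(j - i + 1 for i, j in spine_intervals(dp, 0.9))
            assert covered_hi <= covered_lo


class TestBlockHaplotypes:
    def test_unambiguous_two_marker_block(self):
        ds = make_dataset([[2, 2], [2, 2], [0, 0], [0, 0]])
        haps = block_haplotype_freqs(ds)
        assert dict(haps) == pytest.approx({"11": 0.5, "00": 0.5})

    def test_monomorphic_block_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            block_haplotype_freqs(make_dataset([[0, 2], [0, 2]]))

    def test_classification_thresholds(self):
        haps = [("a", 0.55), ("b", 0.25), ("c", 0.12), ("d", 0.05), ("e", 0.03)]
        labelled, rare = classify_haplotypes(haps)
        assert [c for _, _, c in labelled] == [
            "major", "intermediate", "intermediate", "rare", "rare"
        ]
        assert rare == pytest.approx(0.08)

    def test_em_frequencies_match_phased_truth(self, small_panel):
        """Six-marker block EM vs true haplotype counts: TVD < 0.05."""
        import collections

        from catld.genotype_io import apply_qc

        ds, truth = small_panel
        sub, _ = apply_qc(ds, "B", maf_min=0.05)
        blk = sub.take_snps(np.arange(6))
        est = dict(block_haplotype_freqs(blk))
        snp_idx = {s: i for i, s in enumerate(ds.snps.snp_id)}
        cols = [snp_idx[s] for s in blk.snps.snp_id]
        counts = collections.Counter(
            "".join(map(str, h)) for h in truth.haplotypes[:, cols].astype(int)
        )
        n = sum(counts.values())
        tvd = 0.5 * sum(
            abs(est.get(k, 0.0) - counts.get(k, 0) / n)
            for k in set(est) | set(counts)
        )
        assert tvd < 0.05

    def test_partition_ligation_matches_truth_on_long_block(self, small_panel):
        """Blocks beyond the direct-EM width go through partition–ligation."""
        import collections

        from catld.genotype_io import apply_qc

        ds, truth = small_panel
        sub, _ = apply_qc(ds, "B", maf_min=0.05)
        blk = sub.take_snps(np.arange(12))
        est = dict(block_haplotype_freqs(blk))
        assert est  # produced something
        snp_idx = {s: i for i, s in enumerate(ds.snps.snp_id)}
        cols = [snp_idx[s] for s in blk.snps.snp_id]
        counts = collections.Counter(
            "".join(map(str, h)) for h in truth.haplotypes[:, cols].astype(int)
        )
        n = sum(counts.values())
        tvd = 0.5 * sum(
            abs(est.get(k, 0.0) - counts.get(k, 0) / n)
            for k in set(est) | set(counts)
        )
        assert tvd < 0.10

    def test_frequencies_normalised(self, small_panel):
        ds, _ = small_panel
        blocks = solid_spine_blocks(ds, "B", maf_min=0.05)
        assert blocks
        for b in blocks:
            freqs = [f for _, f, _ in b.haplotypes]
            assert all(f >= 0 for f in freqs)
            shown = sum(f for _, f, c in b.haplotypes if c != "rare")
            assert shown + b.rare_pooled_freq <= 1 + 1e-6


class TestRegionDrivers:
    def test_blocks_never_overlap_and_stay_in_region(self, small_panel):
        ds, _ = small_panel
        blocks = solid_spine_blocks(ds, "B", with_haplotypes=False)
        by_region = {}
        for b in blocks:
            by_region.setdefault(b.region, []).append(b)
        for region, blist in by_region.items():
            blist.sort(key=lambda b: b.start_bp)
            for prev, nxt in zip(blist, blist[1:]):
                assert prev.end_bp < nxt.start_bp
            pos = ds.snps[ds.snps.region == region].pos
            assert all(pos.min() <= b.start_bp <= b.end_bp <= pos.max() for b in blist)

    def test_diversity_summary_totals(self):
        from catld.blocks import HaplotypeBlock

        blocks = [
            HaplotypeBlock("P", region, "c", 0, 1, 1, 2, 2,
                           haplotypes=[("00", 0.5, "major"), ("11", 0.4, "intermediate"),
                                       ("01", 0.05, "rare")])
            for region in ["r1"] * 2 + ["r2"] * 2
        ]
        df = diversity_summary(blocks)
        total = df[df.region == "TOTAL"].iloc[0]
        assert total.n_blocks == 4
        assert total.n_haplotypes == 12
        per_region = df[df.region != "TOTAL"]
        assert per_region.n_blocks.sum() == total.n_blocks

    def test_dprime_matrix_symmetric_with_nan_for_undefined(self):
        calls = [[0, 1, 0], [1, 1, 0], [2, 1, 0], [1, 0, 0]]
        ds = make_dataset(calls)
        dp = dprime_matrix(ds)
        assert dp.shape == (3, 3)
        assert np.isnan(dp[0, 2])  # locus 3 monomorphic
        assert np.allclose(dp, dp.T, equal_nan=True)
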