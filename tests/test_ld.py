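"""Two-locus EM, LD measures, all-pairs tables and background LD."""

import numpy as np
import pytest

from catld.genotype_io import MISSING
from catld.ld import (
    HaplotypeFreqs2,
    MonomorphicError,
    background_ld,
    em_loglik_trace,
    ld_measures,
    pairwise_ld_region,
    two_locus_em,
)

from conftest import make_dataset
from oracles import grid_em_mle, random_genotype_table


class TestTwoLocusEM:
    def test_no_double_hets_equals_direct_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            counts = rng.integers(0, 5, size=(3, 3)).astype(float)
            counts[1, 1] = 0
            two_n = 2 * counts.sum()
            alt_a = 2 * counts[2].sum() + counts[1].sum()
            alt_b = 2 * counts[:, 2].sum() + counts[:, 1].sum()
            if not (0 < alt_a < two_n and 0 < alt_b < two_n):
                continue
            h = two_locus_em(counts)
            k_AB = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
            k_Ab = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
            k_aB = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
            k_ab = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
            np.testing.assert_allclose(
                [h.f_AB, h.f_Ab, h.f_aB, h.f_ab],
                np.array([k_AB, k_Ab, k_aB, k_ab]) / two_n,
                atol=1e-12,
            )
            assert h.n_iter == 0

    def test_coupling_resolution(self):
        # 2×(AABB), 1×(AaBb), 2×(aabb): the double het resolves to coupling
        counts = np.array([[2, 0, 0], [0, 1, 0], [0, 0, 2]])
        h = two_locus_em(counts)
        assert h.f_AB == pytest.approx(0.5, abs=1e-6)
        assert h.f_ab == pytest.approx(0.5, abs=1e-6)
        assert h.f_Ab == pytest.approx(0.0, abs=1e-6)

    def test_double_hets_only_reaches_a_global_maximum(self):
        # the likelihood 2(f_AB f_ab + f_Ab f_aB) has two symmetric maxima at
        # perfect coupling/repulsion; the balanced start is a saddle that the
        # biased restarts escape
        h = two_locus_em(np.array([[0, 0, 0], [0, 4, 0], [0, 0, 0]]))
        assert "degenerate" in h.note
        _, best_ll = grid_em_mle(np.array([[0, 0, 0], [0, 4, 0], [0, 0, 0]]))
        assert h.loglik == pytest.approx(best_ll, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            counts = random_genotype_table(rng)
            h = two_locus_em(counts)
            f_oracle, ll_oracle = grid_em_mle(counts)
            assert h.loglik >= ll_oracle - 1e-6
            np.testing.assert_allclose(
                [h.f_AB, h.f_Ab, h.f_aB, h.f_ab], f_oracle, atol=1.5e-3
            )

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            trace = em_loglik_trace(random_genotype_table(rng))
            assert np.all(np.diff(trace) >= -1e-9)

    def test_monomorphic_table_errors(self):
        with pytest.raises(MonomorphicError):
            two_locus_em(np.array([[3, 1, 0], [0, 0, 0], [0, 0, 0]]))


class TestLDMeasures:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ((0.5, 0.0, 0.0, 0.5), (0.25, 1.0, 1.0)),       # perfect LD
            ((0.25, 0.25, 0.25, 0.25), (0.0, 0.0, 0.0)),    # independence
            ((0.4, 0.1, 0.1, 0.4), (0.15, 0.6, 0.36)),
        ],
    )
    def test_values(self, freqs, expected):
        h = HaplotypeFreqs2(*freqs, loglik=0.0, n_iter=0, converged=True)
        D, adp, r2 = ld_measures(h)
        assert D == pytest.approx(expected[0], abs=1e-12)
        assert adp == pytest.approx(expected[1], abs=1e-12)
        assert r2 == pytest.approx(expected[2], abs=1e-12)

    def test_monomorphic_marginal_errors(self):
        h = HaplotypeFreqs2(0.6, 0.4, 0.0, 0.0, loglik=0.0, n_iter=0, converged=True)
        with pytest.raises(MonomorphicError):
            ld_measures(h)

    def test_allele_swap_leaves_r2_dprime_unchanged(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = random_genotype_table(rng)
            _, a1, r1 = ld_measures(two_locus_em(counts))
            _, a2, r2 = ld_measures(two_locus_em(counts[::-1, :]))  # swap locus A
            _, a3, r3 = ld_measures(two_locus_em(counts[:, ::-1]))  # swap locus B
            assert r1 == pytest.approx(r2, abs=1e-6) == pytest.approx(r3, abs=1e-6)
            assert a1 == pytest.approx(a2, abs=1e-6) == pytest.approx(a3, abs=1e-6)


class TestPairwiseLD:
    def test_three_snps_three_pairs(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.choice([0, 1, 2], size=(30, 3), p=[0.4, 0.4, 0.2]))
        table = pairwise_ld_region(ds)
        assert len(table) == 3

    def test_pairs_only_within_chromosome(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(
            rng.choice([0, 1, 2], size=(30, 4), p=[0.4, 0.4, 0.2]),
            chroms=["1", "1", "2", "2"],
            positions=[1, 2, 1, 2],
        )
        table = pairwise_ld_region(ds)
        assert len(table) == 2
        assert not table.inter_chromosome.any()

    def test_r2_bounded_by_dprime_squared(self, small_panel):
        ds, _ = small_panel
        from catld.genotype_io import apply_qc

        sub, _ = apply_qc(ds, "B", maf_min=0.05)
        table = pairwise_ld_region(sub)
        assert len(table) > 100
        assert (table.r2 <= table.abs_dprime**2 + 1e-9).all()
        assert table.r2.between(0, 1).all()
        assert table.abs_dprime.between(0, 1).all()

    def test_r2_agrees_with_phased_truth(self, small_panel):
        """Unphased-EM r² vs squared dosage correlation on true haplotypes."""
        ds, truth = small_panel
        from catld.genotype_io import apply_qc

        sub, _ = apply_qc(ds, "B", maf_min=0.05)
        table = pairwise_ld_region(sub)
        snp_idx = {s: i for i, s in enumerate(ds.snps.snp_id)}
        H = truth.haplotypes.astype(float)
        errs = []
        for row in table.itertuples():
            ha = H[:, snp_idx[row.snp_a]]
            hb = H[:, snp_idx[row.snp_b]]
            if ha.std() == 0 or hb.std() == 0:
                continue
            errs.append(abs(row.r2 - np.corrcoef(ha, hb)[0, 1] ** 2))
        assert len(errs) > 100
        assert np.mean(errs) < 0.02


class TestBackgroundLD:
    def test_duplicated_chromosomes_give_unity(self):
        # one SNP per chromosome, all three carrying identical genotypes:
        # every inter-chromosome pair is a perfect correlation
        rng = np.random.default_rng(4)
        g = rng.choice([0, 1, 2], size=(40, 1), p=[0.35, 0.4, 0.25])
        ds = make_dataset(
            np.hstack([g, g, g]), chroms=["1", "2", "3"], positions=[1, 1, 1]
        )
        mean_r2, n_pairs = background_ld(ds)
        assert n_pairs == 3
        assert mean_r2 == pytest.approx(1.0, abs=1e-9)

    def test_independent_chromosomes_near_null(self):
        rng = np.random.default_rng(6)
        n = 100
        g = rng.binomial(2, rng.uniform(0.2, 0.8, size=30), size=(n, 30)).astype(np.int8)
        ds = make_dataset(
            g, chroms=["1"] * 15 + ["2"] * 15, positions=list(range(1, 16)) * 2
        )
        mean_r2, n_pairs = background_ld(ds)
        assert n_pairs == 225
        assert mean_r2 < 0.05  # E[r²] ≈ 1/(2n) under independence

    def test_single_chromosome_errors(self):
        rng = np.random.default_rng(8)
        ds = make_dataset(rng.choice([0, 1, 2], size=(30, 5), p=[0.4, 0.4, 0.2]))
        with pytest.raises(ValueError):
            background_ld(ds)
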