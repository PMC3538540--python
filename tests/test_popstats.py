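"""Heterozygosity/F_is, Tajima's D, Hudson F_st, NJ tree, correlations."""

import numpy as np
import pandas as pd
import pytest

from catld.popstats import (
    feature_correlation,
    fst_matrix,
    heterozygosity_fis,
    nj_tree,
    pairwise_fst,
    population_region_summary,
    tajimas_d,
    tree_to_newick,
)

from conftest import make_dataset
from oracles import random_additive_matrix, tree_leaf_distances


class TestHeterozygosity:
    def test_worked_example(self):
        # one SNP, p = 0.5, n = 10, 6 hets
        ds = make_dataset([[1]] * 6 + [[2]] * 2 + [[0]] * 2)
        Ho, He, Fis = heterozygosity_fis(ds)
        assert Ho == pytest.approx(0.6)
        assert He == pytest.approx(0.5263, abs=1e-4)
        assert Fis == pytest.approx(-0.14, abs=1e-2)

    def test_all_homozygous_polymorphic_site(self):
        ds = make_dataset([[2]] * 5 + [[0]] * 5)
        Ho, He, Fis = heterozygosity_fis(ds)
        assert Ho == 0.0
        assert Fis == pytest.approx(1.0)

    def test_hardy_weinberg_null_fis_near_zero(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(0.1, 0.9, size=200)
        calls = rng.binomial(1, p, size=(500, 200)) + rng.binomial(1, p, size=(500, 200))
        _, _, Fis = heterozygosity_fis(make_dataset(calls.astype(np.int8)))
        assert abs(Fis) < 0.02


class TestTajimasD:
    def test_four_sequence_singleton(self):
        # 2 diploids = 4 sequences, one singleton site
        assert tajimas_d(make_dataset([[1], [0]])) == pytest.approx(-0.612, abs=1e-3)

    def test_no_segregating_sites_undefined(self):
        assert np.isnan(tajimas_d(make_dataset([[0, 2], [0, 2], [0, 2]])))

    def test_invariant_to_reference_allele_choice(self):
        rng = np.random.default_rng(23)
        calls = rng.choice([0, 1, 2], size=(12, 40), p=[0.5, 0.3, 0.2]).astype(np.int8)
        d1 = tajimas_d(make_dataset(calls))
        d2 = tajimas_d(make_dataset(2 - calls))
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_bottleneck_shifts_d_upward(self):
        """On a pre-ascertained panel without new mutation, a founder
        bottleneck prunes rare alleles and pushes D up relative to a
        large-Ne history (the sign the statistic can show here; rare-variant
        input would be needed for the classic negative-D expansion signal)."""
        from catld.simulate import simulate_panel

        from conftest import small_breed_config

        tight, loose = [], []
        for seed in range(5):
            ds, _ = simulate_panel(
                small_breed_config(seed=seed, bottleneck_ne=10, sample_n=25,
                                   n_regions=2, snps_per_region=40)
            )
            tight.append(tajimas_d(ds.for_population("B")))
            ds, _ = simulate_panel(
                small_breed_config(seed=seed, bottleneck_ne=200, sample_n=25,
                                   n_regions=2, snps_per_region=40)
            )
            loose.append(tajimas_d(ds.for_population("B")))
        assert np.median(tight) > np.median(loose)


class TestFst:
    def test_fixed_difference_is_one(self):
        a = make_dataset([[2, 2]] * 10)
        b = make_dataset([[0, 0]] * 10)
        assert pairwise_fst(a, b) == pytest.approx(1.0)

    def test_worked_value(self):
        # p1 = 0.8, p2 = 0.2, 20 diploids each
        a = make_dataset([[2]] * 12 + [[1]] * 8)
        b = make_dataset([[0]] * 12 + [[1]] * 8)
        assert pairwise_fst(a, b) == pytest.approx(0.5047, abs=1e-3)

    def test_symmetric_and_label_swap_invariant(self):
        rng = np.random.default_rng(31)
        a = make_dataset(rng.choice([0, 1, 2], size=(15, 30), p=[0.5, 0.3, 0.2]))
        b = make_dataset(rng.choice([0, 1, 2], size=(12, 30), p=[0.3, 0.3, 0.4]))
        f = pairwise_fst(a, b)
        assert pairwise_fst(b, a) == pytest.approx(f, abs=1e-12)
        a_sw = make_dataset(2 - a.calls)
        b_sw = make_dataset(2 - b.calls)
        assert pairwise_fst(a_sw, b_sw) == pytest.approx(f, abs=1e-12)

    def test_panmictic_split_near_zero(self):
        rng = np.random.default_rng(37)
        p = rng.uniform(0.1, 0.9, size=100)
        calls = (rng.binomial(1, p, size=(200, 100)) +
                 rng.binomial(1, p, size=(200, 100))).astype(np.int8)
        a = make_dataset(calls[:100])
        b = make_dataset(calls[100:])
        assert abs(pairwise_fst(a, b)) < 0.01

    def test_matrix_symmetric_zero_diagonal(self, multi_pop_panel):
        ds, _ = multi_pop_panel
        mat = fst_matrix(ds)
        assert (mat.to_numpy().diagonal() == 0).all()
        assert np.allclose(mat, mat.T)
        assert ((mat.to_numpy() >= 0) & (mat.to_numpy() <= 1)).all()


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = nj_tree(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            labels, dist = random_additive_matrix(rng, n)
            d = pd.DataFrame(dist, index=labels, columns=labels)
            tree = nj_tree(d)
            np.testing.assert_allclose(tree_leaf_distances(tree, labels), dist,
                                       atol=1e-9)

    def test_agrees_with_skbio_on_additive_input(self):
        from skbio.tree import nj as skbio_nj
        from skbio import DistanceMatrix

        rng = np.random.default_rng(43)
        labels, dist = random_additive_matrix(rng, 6)
        ours = tree_leaf_distances(nj_tree(pd.DataFrame(dist, index=labels, columns=labels)), labels)
        theirs_tree = skbio_nj(DistanceMatrix(dist, ids=labels))
        theirs = tree_leaf_distances(theirs_tree, labels)
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_equal_distances_tie_break_deterministic(self):
        labels = list("ABCD")
        d = pd.DataFrame(1.0 - np.eye(4), index=labels, columns=labels)
        nwk1 = tree_to_newick(nj_tree(d))
        nwk2 = tree_to_newick(nj_tree(d))
        assert nwk1 == nwk2
        lengths = {t.name: t.length for t in nj_tree(d).tips()}
        assert len(set(round(v, 9) for v in lengths.values())) == 1

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d)


class TestFeatureCorrelation:
    def test_perfectly_linear(self):
        r, p = feature_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(47)
        x, y = rng.random(10), rng.random(10)
        r, _ = feature_correlation(x, y)
        direct = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            feature_correlation([1, 1, 1], [1, 2, 3])


def test_population_region_summary_shape(multi_pop_panel):
    ds, _ = multi_pop_panel
    df = population_region_summary(ds)
    assert len(df) == 6 * 3  # populations × regions
    assert df.Ho.between(0, 1).all()
    assert df.He.between(0, 1).all()
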