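"""Shannon-Weaver binning/indices, Ho/Hs/Fis, allele retention and Kappa."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_genotype_matrix
from oracles import (
    diversity_brute_force,
    kappa_brute_force,
    shannon_brute_force,
)

from germcore.diversity import (
    BinningScheme,
    allele_count,
    allele_retention,
    bin_quantitative,
    cohen_kappa,
    kappa_coincidence,
    make_binning,
    molecular_diversity,
    retention_percent,
    shannon_weaver,
)


class TestBinning:
    def test_range_extremes_land_in_first_and_last_class(self):
        scheme = BinningScheme(trait="x", vmin=0.0, vmax=6.0)
        assert bin_quantitative([0.0], scheme)[0] == 1
        assert bin_quantitative([6.0], scheme)[0] == 6

    def test_boundary_value_belongs_to_lower_class(self):
        # classes are half-open on the left: (lo, hi], so 1.0 with
        # boundaries at multiples of 1 falls in class 1
        scheme = BinningScheme(trait="x", vmin=0.0, vmax=6.0)
        assert bin_quantitative([1.0], scheme)[0] == 1
        assert bin_quantitative([1.0 + 1e-6], scheme)[0] == 2

    def test_uniform_values_spread_evenly(self, rng):
        scheme = BinningScheme(trait="x", vmin=0.0, vmax=6.0)
        values = rng.uniform(0, 6, 6000)
        values[0], values[1] = 0.0, 6.0
        classes = bin_quantitative(values, scheme)
        counts = np.bincount(classes, minlength=7)[1:]
        assert counts.sum() == 6000
        # each class expects 1000; 5 sigma multinomial slack
        assert np.abs(counts - 1000).max() < 5 * np.sqrt(6000 * (1 / 6) * (5 / 6))

    def test_zero_amplitude_is_monomorphic_class_one(self):
        scheme = BinningScheme(trait="x", vmin=2.0, vmax=2.0)
        with pytest.warns(UserWarning, match="monomorphic"):
            classes = bin_quantitative([2.0, 2.0], scheme)
        assert (classes == 1).all()

    def test_out_of_range_value_rejected(self):
        scheme = make_binning([1.0, 5.0], "x")
        with pytest.raises(ValueError, match="outside"):
            bin_quantitative([6.0], scheme)


class TestShannonWeaver:
    def test_monomorphic_is_zero(self):
        assert shannon_weaver([1] * 20, 6) == 0.0

    def test_uniform_is_one(self):
        labels = np.repeat(np.arange(1, 7), 10)
        assert shannon_weaver(labels, 6) == pytest.approx(1.0)

    def test_hand_computed_frequencies(self):
        # frequencies (0.5, 0.25, 0.25) over 3 classes
        labels = [1, 1, 2, 3]
        assert shannon_weaver(labels, 3, normalized=False) == pytest.approx(
            1.0397, abs=1e-4
        )
        assert shannon_weaver(labels, 3) == pytest.approx(0.946, abs=1e-3)

    def test_missing_class_penalized_by_defined_class_count(self):
        labels = np.repeat([1, 2, 3], 10)  # uniform over 3 of 6 classes
        assert shannon_weaver(labels, 6) == pytest.approx(np.log(3) / np.log(6))

    def test_empty_input_is_nan(self):
        assert np.isnan(shannon_weaver([], 6))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(min_value=1, max_value=5), min_size=1, max_size=60)
    )
    def test_matches_brute_force_and_stays_in_unit_interval(self, labels):
        h = shannon_weaver(labels, 5)
        assert 0.0 <= h <= 1.0 + 1e-12
        assert h == pytest.approx(shannon_brute_force(labels, 5), abs=1e-12)


class TestMolecularDiversity:
    def test_all_heterozygous_locus(self):
        gm = random_genotype_matrix(np.random.default_rng(0), 10, 3, 0.0)
        gm.dosages[:, 0] = 1.0
        per_locus, _ = molecular_diversity(gm)
        row = per_locus.iloc[0]
        assert row["ho"] == 1.0
        assert row["hs"] == pytest.approx(0.5)  # (10/9)(1 - 0.5 - 0.05)
        assert row["fis"] == pytest.approx(-1.0)

    def test_monomorphic_locus(self):
        gm = random_genotype_matrix(np.random.default_rng(0), 8, 3, 0.0)
        gm.dosages[:, 1] = 0.0
        per_locus, _ = molecular_diversity(gm)
        row = per_locus.iloc[1]
        assert row["ho"] == 0.0
        assert row["hs"] == pytest.approx(0.0)
        assert np.isnan(row["fis"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_counting(self, seed):
        gen = np.random.default_rng(seed)
        gm = random_genotype_matrix(gen, n_acc=15, n_loci=30, missing_rate=0.12)
        per_locus, means = molecular_diversity(gm)
        ho, hs, fis = diversity_brute_force(gm.dosages)
        np.testing.assert_allclose(per_locus["ho"], ho, atol=1e-12)
        np.testing.assert_allclose(per_locus["hs"], hs, atol=1e-12)
        np.testing.assert_allclose(per_locus["fis"], fis, atol=1e-12)
        assert means["ho"] == pytest.approx(np.nanmean(ho))

    def test_fis_identity_wherever_hs_positive(self, rng):
        gm = random_genotype_matrix(rng, n_acc=20, n_loci=50, missing_rate=0.1)
        per_locus, _ = molecular_diversity(gm)
        defined = per_locus.dropna(subset=["fis"])
        np.testing.assert_allclose(
            defined["fis"], 1 - defined["ho"] / defined["hs"], atol=1e-12
        )


class TestAlleleRetention:
    def test_subset_equal_reference_is_100(self, small_panel):
        gm, _, _ = small_panel
        out = allele_retention(gm, list(gm.accession_ids))
        assert out["retention_pct"] == 100.0

    def test_printed_count_arithmetic(self):
        assert retention_percent(53251, 58671) == 90.76
        assert retention_percent(51688, 58671) == 88.10
        assert retention_percent(52211, 58671) == 88.99

    def test_monotone_under_subsetting(self, small_panel, rng):
        gm, _, _ = small_panel
        sub = list(rng.choice(gm.accession_ids, size=20, replace=False))
        assert allele_count(gm, sub) <= allele_count(gm)

    def test_removing_private_allele_carriers_drops_exact_count(self):
        gm = random_genotype_matrix(np.random.default_rng(1), 12, 20, 0.0)
        # plant 3 private alt alleles carried only by the first 2 accessions
        gm.dosages[:, :3] = 0.0
        gm.dosages[0, :3] = 1.0
        gm.dosages[1, :3] = 1.0
        full = allele_count(gm)
        rest = allele_count(gm, gm.accession_ids[2:])
        assert full - rest == 3

    def test_subset_must_be_contained(self, small_panel):
        gm, _, _ = small_panel
        with pytest.raises(ValueError, match="contained"):
            allele_retention(gm, ["GHOST"], gm.accession_ids[:5])


class TestKappa:
    def test_identical_vectors_give_one(self):
        v = np.array([1, 0, 1, 1, 0], dtype=bool)
        assert cohen_kappa(v, v) == pytest.approx(1.0)

    def test_independent_sparse_vectors_near_zero(self, rng):
        x = rng.random(10000) < 0.04
        y = rng.random(10000) < 0.04
        assert abs(cohen_kappa(x, y)) < 0.05

    def test_hand_computed_2x2_table(self):
        # a=11 both-selected, b=61, c=53, d=1685
        x = np.array([1] * 11 + [1] * 61 + [0] * 53 + [0] * 1685, dtype=bool)
        y = np.array([1] * 11 + [0] * 61 + [1] * 53 + [0] * 1685, dtype=bool)
        expected = kappa_brute_force(x, y)
        assert cohen_kappa(x, y) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn(self, seed):
        from sklearn.metrics import cohen_kappa_score

        gen = np.random.default_rng(seed)
        x = gen.random(200) < 0.3
        y = gen.random(200) < 0.3
        assert cohen_kappa(x, y) == pytest.approx(
            cohen_kappa_score(x, y), abs=1e-12
        )

    def test_matrix_symmetric_unit_diagonal(self):
        membership = {"a": ["x", "y"], "b": ["y", "z"], "c": ["x", "z"]}
        mat = kappa_coincidence(membership, universe=["x", "y", "z", "w"])
        np.testing.assert_allclose(np.diag(mat), 1.0)
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)

    def test_degenerate_vector_reported_missing(self):
        membership = {"all": ["x", "y"], "one": ["x"]}
        with pytest.warns(UserWarning, match="Kappa undefined"):
            mat = kappa_coincidence(membership, universe=["x", "y"])
        assert np.isnan(mat.loc["all", "one"])
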