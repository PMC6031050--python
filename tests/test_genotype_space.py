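"""Accessibility, peaks and epistasis classification of small landscapes."""

import io

import numpy as np
import pytest

from oncodag import (
    FitnessLandscape,
    accessible_genotypes,
    classify_square,
    peaks,
    rse_fraction,
)
from oncodag.genotypes import RECIPROCAL_SIGN, genotype_label

from conftest import two_locus_square
from helpers_oracles import (
    brute_accessible,
    brute_accessible_paths,
    brute_peaks,
    brute_classify,
    random_fitness,
)


class TestAccessibility:
    def test_dependency_blocks_lone_downstream_mutant(self, chain_pair):
        # B depends on A: genotype {B} sits behind a fitness valley
        dag, landscape = chain_pair
        acc = accessible_genotypes(landscape)
        b_alone = 1 << landscape.gene_names.index("B")
        a_alone = 1 << landscape.gene_names.index("A")
        assert b_alone not in acc
        assert a_alone in acc
        assert (a_alone | b_alone) in acc

    def test_additive_landscape_fully_accessible(self, additive_landscape):
        assert accessible_genotypes(additive_landscape) == set(range(8))

    def test_agrees_with_bruteforce_on_random_landscapes(self, rng):
        for _ in range(50):
            m = int(rng.integers(2, 6))
            fit = random_fitness(rng, m)
            L = FitnessLandscape(tuple("ABCDE"[:m]), fit)
            expected = brute_accessible(fit, m)
            assert accessible_genotypes(L) == expected
            assert brute_accessible_paths(fit, m) == expected

    def test_every_accessible_genotype_has_accessible_predecessor(self, rng):
        # closed under removing the last step of a path
        for _ in range(20):
            m = 4
            L = FitnessLandscape(tuple("ABCD"), random_fitness(rng, m))
            acc = accessible_genotypes(L)
            for g in acc - {0}:
                preds = [
                    g & ~(1 << k)
                    for k in range(m)
                    if g >> k & 1
                ]
                assert any(
                    p in acc and L[p] < L[g] for p in preds
                ), f"{g} lacks an accessible predecessor"

    def test_lethal_genotypes_never_accessible(self, rng):
        m = 4
        fit = random_fitness(rng, m)
        lethal = [3, 7, 12]
        fit[lethal] = 1e-9
        L = FitnessLandscape(tuple("ABCD"), fit)
        assert not set(lethal) & accessible_genotypes(L)


class TestPeaks:
    def test_additive_has_single_peak_at_full_genotype(self, additive_landscape):
        assert peaks(additive_landscape) == {0b111}
        assert peaks(additive_landscape, gains_only=True) == {0b111}

    def test_constant_fitness_has_no_strict_peak(self):
        L = FitnessLandscape(("A", "B"), np.ones(4))
        assert peaks(L, restrict_to_accessible=False) == set()

    def test_agrees_with_bruteforce(self, rng):
        for _ in range(30):
            m = int(rng.integers(2, 6))
            fit = random_fitness(rng, m)
            L = FitnessLandscape(tuple("ABCDE"[:m]), fit)
            assert peaks(L, restrict_to_accessible=False) == brute_peaks(fit, m)
            assert peaks(L, restrict_to_accessible=False, gains_only=True) == (
                brute_peaks(fit, m, gains_only=True)
            )

    def test_restriction_to_accessible_set(self, rng):
        m = 4
        fit = random_fitness(rng, m)
        L = FitnessLandscape(tuple("ABCD"), fit)
        assert peaks(L) == brute_peaks(fit, m) & brute_accessible(fit, m)


class TestEpistasisSquares:
    def test_individually_beneficial_jointly_deleterious_is_reciprocal_sign(self):
        L = two_locus_square(1.0, 1.3, 1.3, 0.5)
        assert classify_square(L, 0, 1, 0) == RECIPROCAL_SIGN

    def test_additive_square_has_no_epistasis(self, additive_landscape):
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            for b in range(8):
                if not b & ((1 << i) | (1 << j)):
                    assert classify_square(additive_landscape, i, j, b) == "no_epistasis"

    @pytest.mark.parametrize(
        "square, expected",
        [
            ((1.0, 1.3, 1.3, 0.5), "reciprocal_sign"),
            ((1.0, 1.3, 0.8, 1.5), "sign"),  # j deleterious alone, helpful with i
            ((1.0, 1.2, 1.3, 1.9), "magnitude"),
            ((1.0, 1.2, 1.3, 1.5), "no_epistasis"),
        ],
    )
    def test_named_squares(self, square, expected):
        L = two_locus_square(*square)
        assert classify_square(L, 0, 1, 0) == expected
        assert brute_classify(*square) == expected

    def test_all_squares_agree_with_independent_sign_table(self, rng):
        for _ in range(20):
            m = 4
            fit = random_fitness(rng, m)
            L = FitnessLandscape(tuple("ABCD"), fit)
            for i in range(m):
                for j in range(i + 1, m):
                    for b in range(2**m):
                        if b & ((1 << i) | (1 << j)):
                            continue
                        expected = brute_classify(
                            fit[b],
                            fit[b | (1 << i)],
                            fit[b | (1 << j)],
                            fit[b | (1 << i) | (1 << j)],
                        )
                        assert classify_square(L, i, j, b) == expected

    def test_rejects_same_locus_and_mutated_background(self, additive_landscape):
        with pytest.raises(ValueError):
            classify_square(additive_landscape, 1, 1, 0)
        with pytest.raises(ValueError):
            classify_square(additive_landscape, 0, 1, 0b001)


class TestRseFraction:
    def test_additive_is_zero(self, additive_landscape):
        assert rse_fraction(additive_landscape) == 0.0

    def test_single_reciprocal_square_is_one(self):
        assert rse_fraction(two_locus_square(1.0, 1.3, 1.3, 0.5)) == 1.0

    def test_invariant_under_monotone_transform_and_relabeling(self, rng):
        m = 4
        fit = random_fitness(rng, m)
        L = FitnessLandscape(tuple("ABCD"), fit)
        base = rse_fraction(L)
        # strictly monotone transform preserves every sign comparison
        L2 = FitnessLandscape(tuple("ABCD"), np.exp(2.0 * np.log(fit) + 1.0))
        assert rse_fraction(L2) == pytest.approx(base)
        # gene relabeling: permute loci of the genotype index
        perm = rng.permutation(m)
        fit_perm = np.empty_like(fit)
        for g in range(2**m):
            h = 0
            for k in range(m):
                if g >> k & 1:
                    h |= 1 << perm[k]
            fit_perm[h] = fit[g]
        L3 = FitnessLandscape(tuple("WXYZ"), fit_perm)
        assert rse_fraction(L3) == pytest.approx(base)

    def test_per_locus_pair_aggregation_bounds_per_square(self, rng):
        for _ in range(10):
            L = FitnessLandscape(tuple("ABCD"), random_fitness(rng, 4))
            assert rse_fraction(L, per_locus_pair=True) >= rse_fraction(L)


class TestLandscapeIO:
    def test_csv_round_trip(self, rng, tmp_path):
        L = FitnessLandscape(("A", "B", "C"), random_fitness(rng, 3))
        path = tmp_path / "landscape.csv"
        L.to_csv(path)
        L2 = FitnessLandscape.from_csv(path)
        assert L2.gene_names == L.gene_names
        np.testing.assert_allclose(L2.fitness, L.fitness, rtol=1e-12)

    def test_rejects_wrong_shape_and_nonpositive_fitness(self):
        with pytest.raises(ValueError):
            FitnessLandscape(("A", "B"), np.ones(3))
        with pytest.raises(ValueError):
            FitnessLandscape(("A",), np.array([1.0, 0.0]))

    def test_genotype_labels(self):
        L = two_locus_square(1.0, 1.1, 1.2, 1.3)
        assert genotype_label(0, L.gene_names) == "WT"
        assert genotype_label(0b11, L.gene_names) == "AB"
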