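import numpy as np
import pytest

import ucross
from ucross.genetics import (EffectsTable, ScalingStats,
                             estimate_heritability, genotypic_value,
                             genotypic_values, heterozygosity,
                             ideal_genotypic_value, selection_index,
                             selection_indices)
from ucross.genome import Individual, Population
from ucross.synthetic import generate_founder_populations, \
    simulate_phenotypes


def _toy_map():
    return ucross.MarkerMap(np.array(["a", "b"], dtype=object),
                            np.array([1, 1]), np.array([0.0, 30.0]))


def _toy_effects(b1=(1.0, 2.0), b2=(5.0, 7.0)):
    beta = np.array([[list(b1)], [list(b2)]])  # (P=2, M=1, L=2)
    return EffectsTable(beta, ("S1", "S2"), ("t",))


def _ind(alleles, origins, gmap=None):
    return Individual(np.asarray(alleles, dtype=np.uint8),
                      np.asarray(origins, dtype=np.uint8),
                      "x", ("S1", "S2"), gmap or _toy_map())


class TestGenotypicValue:
    def test_all_zero_alleles(self):
        ind = _ind([[0, 0], [0, 0]], [[0, 0], [0, 0]])
        assert genotypic_value(ind, _toy_effects(), "t") == 0.0

    def test_homozygous_single_origin(self):
        # beta_S1 = (1, 2), homozygous 1/1 at both loci, S1 origin -> 6
        ind = _ind([[1, 1], [1, 1]], [[0, 0], [0, 0]])
        assert genotypic_value(ind, _toy_effects(), "t") == 6.0

    def test_mixed_origin_heterozygote_sums_population_effects(self):
        # locus 0: one S1-origin and one S2-origin alternative allele
        ind = _ind([[1, 0], [1, 0]], [[0, 0], [1, 1]])
        eff = _toy_effects()
        assert genotypic_value(ind, eff, "t") == 1.0 + 5.0

    def test_additive_over_haplotypes(self, merged_pop, small_effects):
        ind = merged_pop.individual(3)
        for trait in small_effects.traits:
            total = genotypic_value(ind, small_effects, trait)
            parts = 0.0
            for h in range(2):
                half = Individual(
                    np.stack([ind.alleles[h],
                              np.zeros_like(ind.alleles[h])]),
                    np.stack([ind.origins[h], ind.origins[h]]),
                    "h", ind.origin_labels, ind.gmap)
                parts += genotypic_value(half, small_effects, trait)
            assert total == pytest.approx(parts)

    def test_unknown_origin_label_rejected(self):
        ind = Individual(np.ones((2, 2), dtype=np.uint8),
                         np.zeros((2, 2), dtype=np.uint8), "x",
                         ("mystery", "S2"), _toy_map())
        with pytest.raises(KeyError, match="mystery"):
            genotypic_value(ind, _toy_effects(), "t")

    def test_batch_matches_scalar(self, merged_pop, small_effects):
        u = genotypic_values(merged_pop, small_effects)
        for i in (0, 17, 60):
            ind = merged_pop.individual(i)
            for m, trait in enumerate(small_effects.traits):
                assert u[i, m] == pytest.approx(
                    genotypic_value(ind, small_effects, trait))


class TestSelectionIndex:
    def test_two_traits_sum(self, merged_pop, small_effects, scaling):
        ind = merged_pop.individual(2)
        vals = [(genotypic_value(ind, small_effects, t)
                 - scaling.mean[m]) / scaling.sd[m]
                for m, t in enumerate(small_effects.traits)]
        assert selection_index(ind, small_effects, scaling) == \
            pytest.approx(sum(vals))

    def test_ranking_invariant_to_trait_shift(self, merged_pop,
                                              small_effects):
        # adding a constant to one trait's values shifts the scaling mean
        # identically, so scaled rankings do not move
        base = genotypic_values(merged_pop, small_effects)
        sc = ScalingStats(base.mean(0), base.std(0, ddof=1),
                          small_effects.traits)
        idx = ((base - sc.mean) / sc.sd).sum(1)
        shifted = base + np.array([3.5, -2.0])
        sc2 = ScalingStats(shifted.mean(0), shifted.std(0, ddof=1),
                           small_effects.traits)
        idx2 = ((shifted - sc2.mean) / sc2.sd).sum(1)
        assert np.array_equal(np.argsort(idx), np.argsort(idx2))


class TestHeterozygosity:
    def test_monomorphic_population_zero(self, small_map):
        L = small_map.n_markers
        alleles = np.ones((4, 2, L), dtype=np.uint8)
        pop = Population(alleles, np.zeros_like(alleles),
                         [f"i{k}" for k in range(4)], small_map)
        assert heterozygosity(pop) == 0.0

    def test_balanced_frequencies_half(self, small_map):
        L = small_map.n_markers
        alleles = np.zeros((4, 2, L), dtype=np.uint8)
        alleles[:, 1, :] = 1  # every locus at p = 0.5
        pop = Population(alleles, np.zeros_like(alleles),
                         [f"i{k}" for k in range(4)], small_map)
        assert heterozygosity(pop) == pytest.approx(0.5)


class TestIdealGenotypicValue:
    def test_all_negative_effects_floor_zero(self):
        eff = _toy_effects(b1=(-1, -2), b2=(-3, -4))
        assert ideal_genotypic_value(eff, "t", "across") == 0.0

    def test_opposite_sign_populations(self):
        # beta_1 = (+1, -1), beta_2 = (-1, +1): within 2 each, across 4
        eff = _toy_effects(b1=(1, -1), b2=(-1, 1))
        assert ideal_genotypic_value(eff, "t", "within", "S1") == 2.0
        assert ideal_genotypic_value(eff, "t", "within", "S2") == 2.0
        assert ideal_genotypic_value(eff, "t", "across") == 4.0

    def test_across_enumeration_two_loci(self):
        # brute force over the 3 allele choices per locus
        rng = np.random.default_rng(0)
        for _ in range(20):
            b = rng.normal(size=(2, 1, 2))
            eff = EffectsTable(b, ("S1", "S2"), ("t",))
            brute = 0.0
            for l in range(2):
                brute += 2 * max(0.0, b[0, 0, l], b[1, 0, l])
            assert ideal_genotypic_value(eff, "t", "across") == \
                pytest.approx(brute)

    def test_across_dominates_within(self, small_effects):
        for trait in small_effects.traits:
            across = ideal_genotypic_value(small_effects, trait, "across")
            for p in small_effects.populations:
                assert across >= ideal_genotypic_value(
                    small_effects, trait, "within", p)


class TestEstimateHeritability:
    def test_noiseless_limit(self, small_map, small_effects):
        p1, _ = generate_founder_populations(small_map, 300, seed=31)
        u = genotypic_values(p1, small_effects)[:, 1]
        est = estimate_heritability(p1.genotype_matrix(), u)
        assert est.h2 >= 0.95

    def test_pure_noise_near_zero(self, small_map):
        p1, _ = generate_founder_populations(small_map, 300, seed=32)
        rng = np.random.default_rng(33)
        est = estimate_heritability(p1.genotype_matrix(), rng.normal(size=300))
        assert est.h2 <= 0.15

    def test_recovers_intermediate_h2(self, small_map, small_effects):
        # moderate-replicate parameter recovery at the package's scale
        p1, _ = generate_founder_populations(small_map, 300, seed=34)
        h2s = []
        for rep in range(5):
            phen = simulate_phenotypes(p1, small_effects, 0.5, seed=40 + rep)
            est = estimate_heritability(p1.genotype_matrix(),
                                        phen.values[:, 1])
            h2s.append(est.h2)
        assert abs(np.mean(h2s) - 0.5) < 0.15

    def test_constant_phenotype_rejected(self, small_pops):
        p1, _ = small_pops
        with pytest.raises(ValueError, match="constant"):
            estimate_heritability(p1.genotype_matrix(),
                                  np.ones(len(p1)))
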