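import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ucross
from ucross.uc import (LDMatrices, cross_mean, evaluate_crosses,
                       generation_recombination, ld_matrices, mc_oracle,
                       progeny_variance, rank_crosses, rank_overlap,
                       recombination_fractions, usefulness)

from _oracles import exact_ld


class TestGenerationRecombination:
    def test_g1_is_c1(self, small_map):
        c1 = small_map.pairwise_recombination()
        assert np.allclose(generation_recombination(c1, 1), c1)

    def test_zero_recombination_stays_zero(self):
        c = np.zeros((2, 2))
        for g in (1, 3, 50):
            assert np.all(generation_recombination(c, g) == 0)

    def test_unlinked_stays_half_and_limit(self):
        c1 = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.fill_diagonal(c1, 0)
        assert generation_recombination(c1, 7)[0, 1] == pytest.approx(0.5)
        # C^g -> 2c / (1 + 2c) as g -> infinity
        c = 0.2
        cg = generation_recombination(np.array([[0, c], [c, 0.0]]), 50)
        assert cg[0, 1] == pytest.approx(2 * c / (1 + 2 * c))

    def test_invalid_generation(self):
        with pytest.raises(ValueError):
            generation_recombination(np.zeros((2, 2)), 0)


class TestLDMatrices:
    def test_g1_identities(self, small_map):
        ld = ld_matrices(recombination_fractions(small_map), 1)
        assert np.allclose(np.diag(ld.d_within), 0.25)
        assert np.allclose(ld.d_between, 0.0)

    def test_unlinked_pair_zero_ld(self):
        c1 = np.array([[0.0, 0.5], [0.5, 0.0]])
        for g in (1, 2, 5):
            ld = ld_matrices(c1, g)
            assert ld.d_within[0, 1] == pytest.approx(0.0)
            assert ld.d_between[0, 1] == pytest.approx(0.0)

    @pytest.mark.parametrize("c", [0.0, 0.05, 0.15, 0.3, 0.45, 0.5])
    def test_matches_exact_origin_chain(self, c):
        """Closed forms agree with the exact 256-state origin chain."""
        c1 = np.array([[0.0, c], [c, 0.0]])
        for g in range(1, 7):
            ld = ld_matrices(c1, g)
            dw, db = exact_ld(c, g)
            assert ld.d_within[0, 1] == pytest.approx(dw, abs=1e-12)
            assert ld.d_between[0, 1] == pytest.approx(db, abs=1e-12)

    def test_ril_limit(self):
        c = 0.1
        c1 = np.array([[0.0, c], [c, 0.0]])
        ld = ld_matrices(c1, 60)
        lim = 0.25 * (1 - 2 * c) / (1 + 2 * c)
        assert ld.d_within[0, 1] == pytest.approx(lim)
        assert ld.d_between[0, 1] == pytest.approx(lim)

    def test_shared_across_crosses(self, small_map):
        # D depends only on the map and g, never on the parents
        m = recombination_fractions(small_map)
        a, b = ld_matrices(m, 3), ld_matrices(m, 3)
        assert np.array_equal(a.d_within, b.d_within)


class TestProgenyVariance:
    def test_identical_inbred_parents_zero_variance(self, small_map,
                                                    small_effects):
        L = small_map.n_markers
        al = np.ones((2, L), dtype=np.uint8)
        a = ucross.Individual(al, np.zeros_like(al), "a", ("S1", "S2"),
                              small_map)
        b = ucross.Individual(al.copy(), np.zeros_like(al), "b",
                              ("S1", "S2"), small_map)
        ld = ld_matrices(recombination_fractions(small_map), 5)
        pv = progeny_variance(a, b, small_effects, ld, "traitB")
        assert pv.total == pytest.approx(0.0, abs=1e-12)

    def test_inbred_parent_within_component_zero(self, small_pops,
                                                 small_effects, rng):
        # fix a parent by long SSD: identical haplotypes => delta = 0
        p1, p2 = small_pops
        fixed = ucross.advance_ssd(p1, 12, rng)
        ld = ld_matrices(recombination_fractions(p1.gmap), 4)
        i = next(k for k in range(len(fixed))
                 if np.array_equal(fixed.alleles[k, 0], fixed.alleles[k, 1]))
        pv = progeny_variance(fixed.individual(i), p2.individual(0),
                              small_effects, ld, "traitB")
        assert pv.components["12"] == pytest.approx(0.0, abs=1e-12)

    def test_six_components_sum_to_total(self, merged_pop, small_effects):
        ld = ld_matrices(recombination_fractions(merged_pop.gmap), 3)
        pv = progeny_variance(merged_pop.individual(1),
                              merged_pop.individual(70),
                              small_effects, ld, "traitA")
        assert pv.total == pytest.approx(sum(pv.components.values()))

    @pytest.mark.parametrize("g", [2, 3, 5])
    def test_matches_monte_carlo(self, merged_pop, small_effects, g):
        """Analytical variance within 3 SE of 1e5 simulated progeny."""
        rng = np.random.default_rng(100 + g)
        ld = ld_matrices(recombination_fractions(merged_pop.gmap), g)
        p1, p2 = merged_pop.individual(6), merged_pop.individual(55)
        mc = mc_oracle(p1, p2, small_effects, g, 100_000, rng)
        for m, trait in enumerate(small_effects.traits):
            pv = progeny_variance(p1, p2, small_effects, ld, trait)
            assert abs(pv.total - mc.variance[m]) < 3 * mc.se_variance[m]
            mu = cross_mean(p1, p2, small_effects, trait)
            assert abs(mu - mc.mean[m]) < 3 * mc.se_mean[m]

    def test_batch_engine_matches_per_pair(self, merged_pop, small_effects,
                                           scaling):
        ld = ld_matrices(recombination_fractions(merged_pop.gmap), 4)
        pairs = np.array([[0, 41], [3, 50], [12, 77], [5, 9]])
        table = evaluate_crosses(merged_pop, pairs, small_effects, ld,
                                 scaling)
        for row, (i, j) in enumerate(pairs):
            a, b = merged_pop.individual(int(i)), merged_pop.individual(
                int(j))
            for trait in small_effects.traits:
                pv = progeny_variance(a, b, small_effects, ld, trait)
                assert table[f"sigma2_{trait}"].iloc[row] == \
                    pytest.approx(pv.total, abs=1e-9)
                assert table[f"mu_{trait}"].iloc[row] == \
                    pytest.approx(cross_mean(a, b, small_effects, trait))


class TestCrossMean:
    def test_identical_parents(self, merged_pop, small_effects):
        p = merged_pop.individual(4)
        q = merged_pop.individual(4)
        assert cross_mean(p, q, small_effects, "traitA") == pytest.approx(
            ucross.genotypic_value(p, small_effects, "traitA"))

    def test_midpoint_arithmetic(self, merged_pop, small_effects):
        p1, p2 = merged_pop.individual(0), merged_pop.individual(60)
        u1 = ucross.genotypic_value(p1, small_effects, "traitB")
        u2 = ucross.genotypic_value(p2, small_effects, "traitB")
        assert cross_mean(p1, p2, small_effects, "traitB") == \
            pytest.approx((u1 + u2) / 2)


class TestUsefulness:
    def test_unit_variance(self):
        assert usefulness(0.0, 1.0, 1.96) == pytest.approx(1.96)

    def test_zero_variance_reduces_to_mean(self):
        assert usefulness(2.5, 0.0, 1.96) == 2.5

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            usefulness(0.0, -1e-3)

    @given(st.floats(-5, 5), st.floats(0.01, 10), st.floats(0.01, 10),
           st.floats(0.1, 3))
    def test_monotone_in_mean_and_variance(self, mu, s2, bump, i):
        assert usefulness(mu + bump, s2, i) > usefulness(mu, s2, i)
        assert usefulness(mu, s2 + bump, i) > usefulness(mu, s2, i)


class TestRankCrosses:
    def test_full_ordering_is_permutation(self, merged_pop, small_effects,
                                          scaling):
        pairs = np.array(list(itertools.combinations(range(6), 2)))
        ranking = rank_crosses(merged_pop, small_effects, g=3, scaling=scaling,
                               K=len(pairs), pairs=pairs)
        got = {tuple(sorted((e.parent1, e.parent2))) for e in ranking}
        want = {tuple(sorted((str(merged_pop.ids[i]), str(merged_pop.ids[j]))))
                for i, j in pairs}
        assert got == want

    def test_k_exceeding_candidates_rejected(self, merged_pop,
                                             small_effects, scaling):
        with pytest.raises(ValueError, match="exceeds"):
            rank_crosses(merged_pop, small_effects, g=3, scaling=scaling,
                         K=10, pairs=np.array([[0, 1], [0, 2]]))

    def test_deterministic_tie_break(self, small_map, small_effects,
                                     scaling):
        # duplicated genotypes -> tied indices; order must follow ids
        L = small_map.n_markers
        alleles = np.zeros((4, 2, L), dtype=np.uint8)
        alleles[:2, 0, :] = 1
        origins = np.zeros_like(alleles)
        pop = ucross.Population(alleles, origins, ["a", "b", "c", "d"],
                                small_map, origin_labels=("S1", "S2"))
        ranking = rank_crosses(pop, small_effects, g=2, scaling=scaling, K=6)
        keys = [(e.parent1, e.parent2) for e in ranking]
        # ties resolve lexicographically within equal index values
        idxs = [round(e.index, 9) for e in ranking]
        for v in set(idxs):
            block = [k for k, x in zip(keys, idxs) if x == v]
            assert block == sorted(block)

    def test_selection_intensity_rank_stability(self, merged_pop,
                                                small_effects, scaling):
        """Nearby selection intensities pick nearly the same top set."""
        a = rank_crosses(merged_pop, small_effects, g=15, i=1.64,
                         scaling=scaling, K=10)
        b = rank_crosses(merged_pop, small_effects, g=15, i=1.96,
                         scaling=scaling, K=10)
        assert rank_overlap(a, b, 10) >= 7


class TestRankOverlap:
    def test_identical_rankings(self):
        r = [("a", "b"), ("c", "d"), ("e", "f")]
        assert rank_overlap(r, list(r), 3) == 3

    def test_disjoint(self):
        a = [("a", "b"), ("c", "d")]
        b = [("e", "f"), ("g", "h")]
        assert rank_overlap(a, b, 2) == 0

    def test_reversed_ranking_brute_force(self):
        items = [(f"p{i}", f"q{i}") for i in range(20)]
        rev = items[::-1]
        K = 10
        brute = len(set(items[:K]) & set(rev[:K]))
        assert rank_overlap(items, rev, K) == brute

    def test_orientation_insensitive(self):
        assert rank_overlap([("a", "b")], [("b", "a")], 1) == 1

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            rank_overlap([("a", "b")], [("a", "b")], 2)


class TestMcOracle:
    def test_identical_inbred_parents_uniform(self, small_map,
                                              small_effects, rng):
        L = small_map.n_markers
        al = np.ones((2, L), dtype=np.uint8)
        a = ucross.Individual(al, np.zeros_like(al), "a", ("S1", "S2"),
                              small_map)
        b = ucross.Individual(al.copy(), np.zeros_like(al), "b",
                              ("S1", "S2"), small_map)
        mc = mc_oracle(a, b, small_effects, 3, 2000, rng)
        assert np.allclose(mc.variance, 0.0, atol=1e-20)

    def test_f1_of_inbreds_is_uniform(self, small_pops, small_effects, rng):
        # g = 1 boundary: fully inbred parents give a uniform F1
        p1, p2 = small_pops
        fixed1 = ucross.advance_ssd(p1, 15, rng)
        fixed2 = ucross.advance_ssd(p2, 15, rng)
        mc = mc_oracle(fixed1.individual(0), fixed2.individual(1),
                       small_effects, 1, 2000, rng)
        assert np.allclose(mc.variance, 0.0, atol=1e-20)
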