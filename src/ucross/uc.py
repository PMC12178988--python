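"""Analytical usefulness criterion for interpopulation crosses.

For a cross k and trait m the usefulness criterion is

    UC_km = mu_km + i * sqrt(sigma2_km),

the expected mean of the selected upper fraction of progeny: mu_km is the
mid-parent genotypic value (exact under additivity) and sigma2_km the
genetic variance among progeny at a chosen reference generation g, where
g = 1 is the F1 of the cross and each further generation is one selfing
(single-seed descent).

sigma2_km decomposes over the four parental haplotypes ("alleles" 1, 2
from parent 1 and 3, 4 from parent 2) into six components — two
within-parent, four between-parent — each a quadratic form

    sigma2^(ab) = (v_a - v_b)' D (v_a - v_b)

in effect-weighted haplotype vectors v_a (allele times the marker effect
of the allele's source population, so population-specific effects enter
naturally).  D is the within-parent (a, b both from one parent) or
between-parent LD variance-covariance matrix; both depend only on the
recombination matrix C1 and g, so they are computed once per generation
and shared across all candidate crosses.

The D matrices used here are exact closed forms of the two-locus
parental-origin process under selfing (derivation in docs/methods.md):

    C^g  = 2 C1 (1 - 0.5^g (1 - 2 C1)^g) / (1 + 2 C1)
    D_w  = 0.25 (1 - 2 C^g)
    D_b  = 0.25 (1 - 2 C^g - 2 (0.5 (1 - 2 C1))^g)

At g = 1 these give D_w with diagonal 0.25 and D_b identically zero (the
F1 of two inbred parents is uniform: all four between-parent variance
components vanish).  For g -> infinity both tend to the classic RIL
limit 0.25 (1 - 2c) / (1 + 2c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import MarkerMap
from .genome import Individual, Population, cross, advance_ssd
from .genetics import (EffectsTable, ScalingStats, genotypic_value,
                       genotypic_values)

__all__ = [
    "RecombinationModel",
    "LDMatrices",
    "ProgenyVariance",
    "CrossEvaluation",
    "McResult",
    "recombination_fractions",
    "generation_recombination",
    "ld_matrices",
    "haplotype_values",
    "progeny_variance",
    "cross_mean",
    "usefulness",
    "evaluate_crosses",
    "rank_crosses",
    "rank_overlap",
    "mc_oracle",
]

COMPONENT_PAIRS = ("12", "34", "13", "14", "23", "24")
NEGATIVE_TOLERANCE = -1e-9


@dataclass(frozen=True)
class RecombinationModel:
    """Single-meiosis recombination fractions between all marker pairs."""

    c1: np.ndarray

    def __post_init__(self) -> None:
        c1 = np.asarray(self.c1, dtype=float)
        object.__setattr__(self, "c1", c1)
        if c1.ndim != 2 or c1.shape[0] != c1.shape[1]:
            raise ValueError("C1 must be square")
        if not np.allclose(c1, c1.T):
            raise ValueError("C1 must be symmetric")
        if np.any(np.diag(c1) != 0):
            raise ValueError("C1 diagonal must be zero")
        if np.any((c1 < 0) | (c1 > 0.5)):
            raise ValueError("recombination fractions must lie in [0, 0.5]")


def recombination_fractions(gmap: MarkerMap) -> RecombinationModel:
    """C1 from a map: Haldane within chromosomes, 0.5 across."""
    return RecombinationModel(gmap.pairwise_recombination())


def generation_recombination(c1: np.ndarray | RecombinationModel,
                             g: int) -> np.ndarray:
    """Accumulated recombination C^g after g generations (g = 1: C^1)."""
    if not float(g).is_integer() or g < 1:
        raise ValueError("g must be an integer >= 1")
    g = int(g)
    c1 = c1.c1 if isinstance(c1, RecombinationModel) else np.asarray(c1,
                                                                     float)
    return 2.0 * c1 * (1.0 - 0.5 ** g * (1.0 - 2.0 * c1) ** g) \
        / (1.0 + 2.0 * c1)


@dataclass(frozen=True)
class LDMatrices:
    """Within- and between-parent LD matrices at reference generation g.

    Shared by all candidate crosses: they depend only on the map and g.
    """

    d_within: np.ndarray
    d_between: np.ndarray
    g: int


def ld_matrices(c1: np.ndarray | RecombinationModel, g: int) -> LDMatrices:
    """Materialize D_within = D^(12) = D^(34) and
    D_between = D^(13) = D^(14) = D^(23) = D^(24) for generation g."""
    c1 = c1.c1 if isinstance(c1, RecombinationModel) else np.asarray(c1,
                                                                     float)
    cg = generation_recombination(c1, g)
    d_within = 0.25 * (1.0 - 2.0 * cg)
    d_between = 0.25 * (1.0 - 2.0 * cg
                        - 2.0 * (0.5 * (1.0 - 2.0 * c1)) ** int(g))
    return LDMatrices(d_within, d_between, int(g))


def haplotype_values(individual: Individual, effects: EffectsTable,
                     trait: str) -> np.ndarray:
    """(2, L) effect-weighted haplotype vectors v_a: the allele code times
    the marker effect of the allele's source population."""
    for lab in individual.origin_labels:
        if lab not in effects.populations:
            raise KeyError(f"no marker effects for origin label {lab!r}")
    beta = effects.aligned_to(individual.origin_labels)
    m = effects.trait_index(trait)
    L = individual.n_markers
    b = beta[individual.origins, m, np.arange(L)[None, :]]
    return individual.alleles * b


@dataclass(frozen=True)
class ProgenyVariance:
    """Six-component progeny-variance decomposition for one cross/trait."""

    components: dict[str, float]     # keys "12","34","13","14","23","24"
    total: float

    def __post_init__(self) -> None:
        if set(self.components) != set(COMPONENT_PAIRS):
            raise ValueError("components must cover the six allele pairs")


def progeny_variance(parent1: Individual, parent2: Individual,
                     effects: EffectsTable, ld: LDMatrices,
                     trait: str) -> ProgenyVariance:
    """Analytical variance of progeny genotypic values at generation
    ``ld.g``, decomposed over the four parental haplotypes."""
    if parent1.n_markers != parent2.n_markers:
        raise ValueError("parents do not share a marker map")
    if ld.d_within.shape[0] != parent1.n_markers:
        raise ValueError("LD matrices do not match the marker count")
    v1 = haplotype_values(parent1, effects, trait)   # alleles 1, 2
    v2 = haplotype_values(parent2, effects, trait)   # alleles 3, 4
    v = {"1": v1[0], "2": v1[1], "3": v2[0], "4": v2[1]}
    comps: dict[str, float] = {}
    for pair in COMPONENT_PAIRS:
        d = ld.d_within if pair in ("12", "34") else ld.d_between
        delta = v[pair[0]] - v[pair[1]]
        comps[pair] = float(delta @ d @ delta)
    total = float(sum(comps.values()))
    if total < NEGATIVE_TOLERANCE:
        raise ValueError(f"progeny variance {total} is negative beyond "
                         "numerical tolerance")
    return ProgenyVariance(comps, max(total, 0.0))


def cross_mean(parent1: Individual, parent2: Individual,
               effects: EffectsTable, trait: str) -> float:
    """Mid-parent genotypic value: the exact expected progeny value under
    the additive model, at every generation."""
    return 0.5 * (genotypic_value(parent1, effects, trait)
                  + genotypic_value(parent2, effects, trait))


def usefulness(mu_scaled: float, sigma2_scaled: float,
               i: float = 1.96) -> float:
    """UC = mu + i * sigma on the scaled scale."""
    if sigma2_scaled < 0:
        if sigma2_scaled < NEGATIVE_TOLERANCE:
            raise ValueError("negative progeny variance")
        sigma2_scaled = 0.0
    return float(mu_scaled + i * np.sqrt(sigma2_scaled))


@dataclass(frozen=True)
class CrossEvaluation:
    """Full evaluation of one candidate cross pair."""

    parent1: str
    parent2: str
    mu: dict[str, float]                       # raw trait units
    variance: dict[str, ProgenyVariance]       # raw trait units
    uc: dict[str, float]                       # scaled
    index: float                               # summed scaled UC


def _pair_matrices(pop: Population, effects: EffectsTable,
                   ld: LDMatrices) -> tuple[np.ndarray, np.ndarray,
                                            np.ndarray]:
    """Per-trait building blocks for evaluating many crosses at once.

    Returns ``within`` (M, n): within-parent quadratic form per
    individual; ``s`` (M, n): sum of the two between-form diagonal terms
    per individual; ``H`` (M, n, n): summed between-parent cross terms for
    every ordered pair.  The four between-parent components of pair
    (i, j) sum to ``2 (s_i + s_j) - 2 H[i, j]``.
    """
    n, L = len(pop), pop.n_markers
    M = len(effects.traits)
    beta = effects.aligned_to(pop.origin_labels)       # (P, M, L)
    cols = np.arange(L)
    V = pop.alleles[..., None] * beta[pop.origins, :, cols[None, None, :]]
    within = np.empty((M, n))
    s = np.empty((M, n))
    H = np.empty((M, n, n))
    for m in range(M):
        Vm = V[:, :, :, m]                             # (n, 2, L)
        e = Vm[:, 0, :] - Vm[:, 1, :]
        within[m] = np.einsum("il,il->i", e @ ld.d_within, e)
        A = Vm.reshape(2 * n, L)
        G = (A @ ld.d_between) @ A.T                   # (2n, 2n)
        q = np.diag(G)
        s[m] = q[0::2] + q[1::2]
        H[m] = G.reshape(n, 2, n, 2).sum(axis=(1, 3))
    return within, s, H


def evaluate_crosses(pop: Population, pairs: np.ndarray,
                     effects: EffectsTable, ld: LDMatrices,
                     scaling: ScalingStats, i: float = 1.96) -> pd.DataFrame:
    """Vectorized mean / variance / UC / summed-UC for many cross pairs.

    ``pairs`` is a (k, 2) array of indices into ``pop``.  The LD matrices
    are computed once by the caller and reused for every pair.
    """
    pairs = np.asarray(pairs, dtype=int)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must have shape (k, 2)")
    if np.any(pairs[:, 0] == pairs[:, 1]):
        raise ValueError("selfing pairs are not valid cross candidates")
    if tuple(scaling.traits) != tuple(effects.traits):
        raise ValueError("scaling statistics do not cover the effect traits")
    u = genotypic_values(pop, effects)                 # (n, M)
    within, s, H = _pair_matrices(pop, effects, ld)
    i1, i2 = pairs[:, 0], pairs[:, 1]
    out = {"parent1": pop.ids[i1], "parent2": pop.ids[i2]}
    index = np.zeros(pairs.shape[0])
    for m, trait in enumerate(effects.traits):
        mu = 0.5 * (u[i1, m] + u[i2, m])
        sigma2 = within[m, i1] + within[m, i2] \
            + 2.0 * (s[m, i1] + s[m, i2]) - 2.0 * H[m, i1, i2]
        if sigma2.min() < NEGATIVE_TOLERANCE:
            raise ValueError("negative progeny variance beyond tolerance")
        sigma2 = np.clip(sigma2, 0.0, None)
        mu_s = (mu - scaling.mean[m]) / scaling.sd[m]
        uc = mu_s + i * np.sqrt(sigma2 / scaling.sd[m] ** 2)
        out[f"mu_{trait}"] = mu
        out[f"sigma2_{trait}"] = sigma2
        out[f"uc_{trait}"] = uc
        index += uc
    out["index"] = index
    return pd.DataFrame(out)


def _all_pairs(n: int) -> np.ndarray:
    i1, i2 = np.triu_indices(n, k=1)
    return np.stack([i1, i2], axis=1)


def rank_crosses(pop: Population, effects: EffectsTable, g: int,
                 i: float = 1.96, scaling: ScalingStats | None = None,
                 K: int = 10, pairs: np.ndarray | None = None,
                 model: RecombinationModel | None = None
                 ) -> list[CrossEvaluation]:
    """Top-K cross pairs by summed UC.

    Candidates default to all unordered non-self pairs in ``pop``.  Ties
    break lexicographically on (-index, parent1 id, parent2 id) so
    rankings are reproducible.
    """
    if scaling is None:
        scaling = ScalingStats.from_populations(pop, effects)
    if pairs is None:
        pairs = _all_pairs(len(pop))
    pairs = np.asarray(pairs, dtype=int)
    if K > pairs.shape[0]:
        raise ValueError(f"K={K} exceeds the {pairs.shape[0]} candidates")
    model = model or recombination_fractions(pop.gmap)
    ld = ld_matrices(model, g)
    table = evaluate_crosses(pop, pairs, effects, ld, scaling, i)
    order = np.lexsort((table["parent2"].to_numpy(),
                        table["parent1"].to_numpy(),
                        -table["index"].to_numpy()))
    evaluations = []
    for row in order[:K]:
        j1, j2 = pairs[row]
        p1, p2 = pop.individual(int(j1)), pop.individual(int(j2))
        mu, var, uc = {}, {}, {}
        for m, trait in enumerate(effects.traits):
            mu[trait] = float(table[f"mu_{trait}"].iloc[row])
            var[trait] = progeny_variance(p1, p2, effects, ld, trait)
            uc[trait] = float(table[f"uc_{trait}"].iloc[row])
        evaluations.append(CrossEvaluation(
            parent1=p1.id, parent2=p2.id, mu=mu, variance=var, uc=uc,
            index=float(table["index"].iloc[row])))
    return evaluations


def rank_overlap(ranking_a, ranking_b, K: int) -> int:
    """Size of the intersection of the two top-K sets.

    Rankings are sequences of cross identifiers (e.g. (parent1, parent2)
    tuples or :class:`CrossEvaluation` objects), best first.
    """

    def key(item):
        if isinstance(item, CrossEvaluation):
            return tuple(sorted((item.parent1, item.parent2)))
        if isinstance(item, (tuple, list)) and len(item) == 2:
            return tuple(sorted(item))
        return item

    a = [key(x) for x in ranking_a]
    b = [key(x) for x in ranking_b]
    if K > len(a) or K > len(b):
        raise ValueError("K exceeds the length of a ranking")
    return len(set(a[:K]) & set(b[:K]))


@dataclass(frozen=True)
class McResult:
    """Monte-Carlo progeny mean/variance with standard errors, per trait."""

    mean: np.ndarray
    variance: np.ndarray
    se_mean: np.ndarray
    se_variance: np.ndarray
    n_sim: int
    traits: tuple[str, ...]


def mc_oracle(parent1: Individual, parent2: Individual,
              effects: EffectsTable, g: int, n_sim: int,
              rng: np.random.Generator) -> McResult:
    """Brute-force validator for the analytical machinery.

    Simulates ``n_sim`` independent progeny lines — the cross followed by
    g - 1 generations of single-seed descent — through the meiosis
    simulator, and returns the empirical mean and variance of their
    genotypic values.  The SE of the variance uses the fourth central
    moment, so no normality is assumed.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    if n_sim < 2:
        raise ValueError("n_sim must be at least 2")
    f1 = cross(parent1, parent2, n_sim, rng, generation="mc")
    pop = advance_ssd(f1, g - 1, rng)
    u = genotypic_values(pop, effects)
    mean = u.mean(axis=0)
    var = u.var(axis=0, ddof=1)
    centered = u - mean
    m4 = (centered ** 4).mean(axis=0)
    se_var = np.sqrt(np.clip(m4 - var ** 2, 0.0, None) / n_sim)
    se_mean = u.std(axis=0, ddof=1) / np.sqrt(n_sim)
    return McResult(mean, var, se_mean, se_var, n_sim, effects.traits)
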