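"""Synthetic founder genomes, maps, population-specific marker effects,
F4 RIL populations and phenotypes.

The generator emulates the study system the package targets: two
biparental F4 recombinant-inbred populations that share one common parent
and differ in the alternative parent, phenotyped for two traits of
contrasting architecture — one governed by a handful of major QTL, one
polygenic with opposite effect-sign bias in the two populations.  Marker
effects are population-specific: the same marker may act differently (or
only) in one population.

Founders are fully inbred: the common parent is fixed for the baseline
(0) allele and each alternative parent for the 1 allele at every marker,
so every marker segregates within its own population.  Each F4 individual
descends from one F1 by three rounds of single-seed descent, giving the
expected per-locus heterozygosity of 1/8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import MarkerMap
from .genome import Population, advance_ssd, _gametes
from .genetics import EffectsTable, genotypic_values

__all__ = [
    "TraitArchitecture",
    "ArchitectureSpec",
    "PhenotypeTable",
    "default_architecture",
    "generate_effects",
    "generate_founder_populations",
    "simulate_phenotypes",
]

POPULATION_LABELS = ("S1", "S2")


@dataclass(frozen=True)
class TraitArchitecture:
    """Effect architecture for one (trait, population) combination.

    ``n_causal`` markers carry nonzero effects; of these, ``n_major`` are
    major QTL with magnitude ``major_effect``, the rest draw magnitudes
    from a half-normal with scale ``effect_sd``.  Each effect is positive
    with probability ``sign_bias``.
    """

    n_causal: int
    effect_sd: float = 0.2
    sign_bias: float = 0.5
    n_major: int = 0
    major_effect: float = 1.0

    def __post_init__(self) -> None:
        if self.n_causal < 0 or self.n_major < 0:
            raise ValueError("causal counts must be non-negative")
        if self.n_major > self.n_causal:
            raise ValueError("n_major cannot exceed n_causal")
        if not 0.0 <= self.sign_bias <= 1.0:
            raise ValueError("sign_bias must lie in [0, 1]")
        if not (np.isfinite(self.effect_sd) and np.isfinite(self.major_effect)):
            raise ValueError("effect magnitudes must be finite")
        if self.effect_sd < 0 or self.major_effect < 0:
            raise ValueError("effect magnitudes must be non-negative")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Mapping trait -> population label -> :class:`TraitArchitecture`."""

    traits: dict[str, dict[str, TraitArchitecture]]

    def __post_init__(self) -> None:
        if not self.traits:
            raise ValueError("at least one trait is required")
        pops = None
        for trait, per_pop in self.traits.items():
            if pops is None:
                pops = tuple(per_pop)
            elif tuple(per_pop) != pops:
                raise ValueError("all traits must cover the same populations")

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(self.traits)

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(next(iter(self.traits.values())))


def default_architecture(n_markers: int) -> ArchitectureSpec:
    """Two traits mirroring the contrast the package is built around.

    ``traitA`` (major-gene trait): five major QTL per population, mostly
    favorable.  ``traitB`` (polygenic trait): 40% of markers causal with
    small effects and opposite sign bias between the two populations, so
    each population holds favorable alleles the other lacks.
    """
    n_poly = max(1, int(round(0.4 * n_markers)))
    major = dict(n_causal=5, n_major=5, major_effect=1.0, effect_sd=0.0,
                 sign_bias=0.9)
    return ArchitectureSpec(traits={
        "traitA": {
            POPULATION_LABELS[0]: TraitArchitecture(**major),
            POPULATION_LABELS[1]: TraitArchitecture(**major),
        },
        "traitB": {
            POPULATION_LABELS[0]: TraitArchitecture(
                n_causal=n_poly, effect_sd=0.15, sign_bias=0.2),
            POPULATION_LABELS[1]: TraitArchitecture(
                n_causal=n_poly, effect_sd=0.15, sign_bias=0.8),
        },
    })


@dataclass(frozen=True)
class PhenotypeTable:
    """Trait values per individual, no missing entries."""

    values: np.ndarray            # (n, M)
    traits: tuple[str, ...]
    ids: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        ids = np.asarray(self.ids, dtype=object)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "traits", tuple(self.traits))
        if values.ndim != 2 or values.shape[1] != len(self.traits):
            raise ValueError("values must have shape (n, n_traits)")
        if ids.size != values.shape[0]:
            raise ValueError("ids must match the number of individuals")
        if not np.all(np.isfinite(values)):
            raise ValueError("phenotypes must be finite")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.traits))
        df.insert(0, "id", self.ids)
        return df


def generate_effects(gmap: MarkerMap, spec: ArchitectureSpec,
                     seed: int | None = None) -> EffectsTable:
    """Draw population-specific marker effects with the requested
    sparsity and sign structure; non-causal markers are exactly 0."""
    rng = np.random.default_rng(seed)
    L = gmap.n_markers
    traits = spec.trait_names
    pops = spec.populations
    beta = np.zeros((len(pops), len(traits), L))
    for m, trait in enumerate(traits):
        for p, pop in enumerate(pops):
            arch = spec.traits[trait][pop]
            if arch.n_causal > L:
                raise ValueError(
                    f"{trait}/{pop}: {arch.n_causal} causal markers exceed "
                    f"the {L} mapped markers")
            loci = rng.choice(L, size=arch.n_causal, replace=False)
            mag = np.abs(rng.normal(0.0, arch.effect_sd, arch.n_causal))
            mag[:arch.n_major] = arch.major_effect
            sign = np.where(rng.random(arch.n_causal) < arch.sign_bias,
                            1.0, -1.0)
            beta[p, m, loci] = sign * mag
    return EffectsTable(beta, pops, traits)


def _inbred_founder_cross(gmap: MarkerMap, origin_code: int, n_progeny: int,
                          origin_labels: tuple[str, ...],
                          rng: np.random.Generator,
                          family: str) -> Population:
    """F1 of (common parent x alternative parent), then SSD to F4.

    Both founders are fully homozygous, so every F1 is identical: one
    all-0 and one all-1 haplotype, all loci heterozygous.  F2 individuals
    are independent selfed offspring of the F1; two further rounds of SSD
    give the F4.
    """
    L = gmap.n_markers
    f1_alleles = np.zeros((n_progeny, 2, L), dtype=np.uint8)
    f1_alleles[:, 1, :] = 1
    f1_origins = np.full((n_progeny, 2, L), origin_code, dtype=np.uint8)
    f1 = Population(f1_alleles, f1_origins,
                    [f"{family}F2:{i}" for i in range(n_progeny)], gmap,
                    generation=f"{family}F1", origin_labels=origin_labels)
    # one selfing F1 -> F2 (independent per line), then SSD to F4
    a1, o1 = _gametes(f1.alleles, f1.origins, gmap, rng)
    a2, o2 = _gametes(f1.alleles, f1.origins, gmap, rng)
    f2 = Population(np.stack([a1, a2], axis=1), np.stack([o1, o2], axis=1),
                    f1.ids, gmap, f"{family}F2", origin_labels)
    f4 = advance_ssd(f2, 2, rng, generation_tags=[f"{family}F3",
                                                  f"{family}F4"])
    ids = np.array([f"{family}:{i}" for i in range(n_progeny)], dtype=object)
    return Population(f4.alleles, f4.origins, ids, gmap, "F4", origin_labels)


def generate_founder_populations(
        gmap: MarkerMap, n_per_pop: int, seed: int | None = None,
        labels: tuple[str, str] = POPULATION_LABELS,
) -> tuple[Population, Population]:
    """Two F4 biparental RIL populations sharing a common parent.

    Every allele in population k is origin-labelled ``labels[k]``; allele
    codes are 0 (common parent) or 1 (alternative parent).
    """
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be >= 1")
    rng = np.random.default_rng(seed)
    pop1 = _inbred_founder_cross(gmap, 0, n_per_pop, tuple(labels), rng,
                                 labels[0])
    pop2 = _inbred_founder_cross(gmap, 1, n_per_pop, tuple(labels), rng,
                                 labels[1])
    return pop1, pop2


def simulate_phenotypes(pop: Population, effects: EffectsTable,
                        target_h2: float,
                        seed: int | None = None) -> PhenotypeTable:
    """Genotypic values plus iid normal noise calibrated so that the
    realized ``var(u) / (var(u) + sigma_e^2)`` equals ``target_h2``."""
    if not 0.0 < target_h2 <= 1.0:
        raise ValueError("target_h2 must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    u = genotypic_values(pop, effects)
    y = u.copy()
    if target_h2 < 1.0:
        var_u = u.var(axis=0, ddof=1)
        if np.any(var_u == 0):
            raise ValueError("a trait has zero genetic variance; the error "
                             "variance for target_h2 < 1 is undefined")
        sigma_e2 = var_u * (1.0 - target_h2) / target_h2
        y = y + rng.normal(0.0, np.sqrt(sigma_e2), size=u.shape)
    return PhenotypeTable(y, effects.traits, pop.ids)
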