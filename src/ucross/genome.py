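"""Origin-tracked genomes, meiosis, crossing and single-seed descent.

Every allele copy carries an origin label recording which biparental
population it descends from.  Origin labels are copied together with the
allele during meiosis and never mutate, which is what allows
population-specific marker effects to be applied after populations are
mixed by interpopulation crossing.

Populations are stored as dense arrays: ``alleles`` and ``origins`` of
shape ``(n, 2, L)`` (individual, haplotype, marker).  Alleles are coded 0
(common-parent) / 1 (alternative-parent); origins are integer codes into
``origin_labels``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genmap import MarkerMap

__all__ = [
    "OriginHaplotype",
    "Individual",
    "Population",
    "make_gamete",
    "cross",
    "self_progeny",
    "cross_pairs",
    "advance_ssd",
]


@dataclass(frozen=True)
class OriginHaplotype:
    """A single gamete: allele codes plus per-locus origin labels."""

    allele: np.ndarray   # (L,) in {0, 1}
    origin: np.ndarray   # (L,) codes into the population's origin_labels

    def __post_init__(self) -> None:
        if self.allele.shape != self.origin.shape or self.allele.ndim != 1:
            raise ValueError("allele and origin must be 1-D of equal length")


@dataclass(frozen=True)
class Individual:
    """Lightweight view of one individual (two origin-tracked haplotypes)."""

    alleles: np.ndarray  # (2, L)
    origins: np.ndarray  # (2, L)
    id: str
    origin_labels: tuple[str, ...]
    gmap: MarkerMap | None = None
    parents: tuple[str, str] | None = None
    generation: str = ""

    def __post_init__(self) -> None:
        if self.alleles.shape != self.origins.shape or self.alleles.ndim != 2 \
                or self.alleles.shape[0] != 2:
            raise ValueError("alleles/origins must both have shape (2, L)")

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def genotype(self) -> np.ndarray:
        """0/1/2 scores counting alternative-allele copies."""
        return self.alleles.sum(axis=0)


class Population:
    """A set of individuals sharing one marker map."""

    def __init__(self, alleles: np.ndarray, origins: np.ndarray,
                 ids: list[str] | np.ndarray, gmap: MarkerMap,
                 generation: str = "",
                 origin_labels: tuple[str, ...] = ("P1", "P2"),
                 parents: np.ndarray | None = None) -> None:
        alleles = np.ascontiguousarray(alleles, dtype=np.uint8)
        origins = np.ascontiguousarray(origins, dtype=np.uint8)
        if alleles.shape != origins.shape or alleles.ndim != 3 \
                or alleles.shape[1] != 2:
            raise ValueError("alleles/origins must have shape (n, 2, L)")
        if alleles.shape[2] != gmap.n_markers:
            raise ValueError("marker dimension does not match the map")
        ids = np.asarray(ids, dtype=object)
        if ids.size != alleles.shape[0]:
            raise ValueError("number of ids does not match population size")
        if len(set(ids.tolist())) != ids.size:
            raise ValueError("individual ids must be unique")
        if origins.size and origins.max() >= len(origin_labels):
            raise ValueError("origin code outside the known label set")
        self.alleles = alleles
        self.origins = origins
        self.ids = ids
        self.gmap = gmap
        self.generation = generation
        self.origin_labels = tuple(origin_labels)
        self.parents = parents

    def __len__(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[2]

    def individual(self, i: int) -> Individual:
        par = tuple(self.parents[i]) if self.parents is not None else None
        return Individual(self.alleles[i], self.origins[i], str(self.ids[i]),
                          self.origin_labels, self.gmap, par, self.generation)

    def genotype_matrix(self) -> np.ndarray:
        """(n, L) matrix of 0/1/2 alternative-allele counts."""
        return self.alleles.sum(axis=1, dtype=np.int16)

    def subset(self, index: np.ndarray, generation: str | None = None
               ) -> "Population":
        index = np.asarray(index)
        par = self.parents[index] if self.parents is not None else None
        return Population(self.alleles[index], self.origins[index],
                          self.ids[index], self.gmap,
                          generation or self.generation,
                          self.origin_labels, par)

    @classmethod
    def merge(cls, a: "Population", b: "Population",
              generation: str | None = None) -> "Population":
        if a.gmap is not b.gmap and a.n_markers != b.n_markers:
            raise ValueError("populations do not share a marker map")
        if a.origin_labels != b.origin_labels:
            raise ValueError("populations use different origin label sets")
        par = None
        if a.parents is not None and b.parents is not None:
            par = np.concatenate([a.parents, b.parents])
        return cls(np.concatenate([a.alleles, b.alleles]),
                   np.concatenate([a.origins, b.origins]),
                   np.concatenate([a.ids, b.ids]), a.gmap,
                   generation or a.generation, a.origin_labels, par)


def _gamete_choosers(n: int, gmap: MarkerMap,
                     rng: np.random.Generator) -> np.ndarray:
    """(n, L) array selecting the parental haplotype at each marker.

    Crossovers follow the Haldane model: the chooser is the running parity
    of Bernoulli switches with the map's adjacent recombination fractions;
    the fair-coin switch at each chromosome start makes chromosomes assort
    independently.
    """
    r = gmap.adjacent_recombination()
    switches = rng.random((n, gmap.n_markers)) < r
    return np.cumsum(switches, axis=1, dtype=np.int64) & 1


def _gametes(alleles: np.ndarray, origins: np.ndarray, gmap: MarkerMap,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One gamete per individual from (n, 2, L) parent arrays."""
    n, _, L = alleles.shape
    ch = _gamete_choosers(n, gmap, rng)
    rows = np.arange(n)[:, None]
    cols = np.arange(L)[None, :]
    return alleles[rows, ch, cols], origins[rows, ch, cols]


def make_gamete(individual: Individual, gmap: MarkerMap | None = None,
                rng: np.random.Generator | None = None) -> OriginHaplotype:
    """Simulate one meiosis; allele and origin are copied together."""
    gmap = gmap or individual.gmap
    if gmap is None:
        raise ValueError("a marker map is required")
    if individual.n_markers != gmap.n_markers:
        raise ValueError("individual does not match the map")
    rng = rng if rng is not None else np.random.default_rng()
    a, o = _gametes(individual.alleles[None], individual.origins[None],
                    gmap, rng)
    return OriginHaplotype(a[0], o[0])


def cross_pairs(pop: Population, pair_index: np.ndarray,
                progeny_per_cross: int, rng: np.random.Generator,
                generation: str = "") -> Population:
    """Cross the given (k, 2) index pairs, ``progeny_per_cross`` each.

    Progeny receive one gamete from each parent; pedigree is recorded.
    """
    pair_index = np.asarray(pair_index, dtype=int)
    if pair_index.ndim != 2 or pair_index.shape[1] != 2:
        raise ValueError("pair_index must have shape (k, 2)")
    if np.any(pair_index[:, 0] == pair_index[:, 1]):
        raise ValueError("selfing pairs are not allowed in cross_pairs")
    p1 = np.repeat(pair_index[:, 0], progeny_per_cross)
    p2 = np.repeat(pair_index[:, 1], progeny_per_cross)
    a1, o1 = _gametes(pop.alleles[p1], pop.origins[p1], pop.gmap, rng)
    a2, o2 = _gametes(pop.alleles[p2], pop.origins[p2], pop.gmap, rng)
    alleles = np.stack([a1, a2], axis=1)
    origins = np.stack([o1, o2], axis=1)
    n = p1.size
    ids = np.array([f"{generation or 'X'}:{i}" for i in range(n)],
                   dtype=object)
    parents = np.stack([pop.ids[p1], pop.ids[p2]], axis=1)
    return Population(alleles, origins, ids, pop.gmap, generation,
                      pop.origin_labels, parents)


def cross(parent1: Individual, parent2: Individual, n_progeny: int,
          rng: np.random.Generator, gmap: MarkerMap | None = None,
          generation: str = "F1") -> Population:
    """Biparental cross of two individuals.

    Selfing is a distinct operation (:func:`self_progeny`); crossing an
    individual with itself raises.
    """
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    if parent1.id == parent2.id:
        raise ValueError("parents are identical; use self_progeny for selfing")
    gmap = gmap or parent1.gmap or parent2.gmap
    if gmap is None:
        raise ValueError("a marker map is required")
    if parent1.n_markers != parent2.n_markers:
        raise ValueError("parents do not share a marker map")
    if parent1.origin_labels != parent2.origin_labels:
        raise ValueError("parents use different origin label sets")
    stack_a = np.stack([parent1.alleles, parent2.alleles])
    stack_o = np.stack([parent1.origins, parent2.origins])
    pop = Population(stack_a, stack_o, [parent1.id, parent2.id], gmap,
                     origin_labels=parent1.origin_labels)
    return cross_pairs(pop, np.array([[0, 1]]), n_progeny, rng, generation)


def self_progeny(individual: Individual, n_progeny: int,
                 rng: np.random.Generator, gmap: MarkerMap | None = None,
                 generation: str = "") -> Population:
    """Self-pollinate one individual, collecting ``n_progeny`` offspring."""
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    gmap = gmap or individual.gmap
    if gmap is None:
        raise ValueError("a marker map is required")
    tiled_a = np.repeat(individual.alleles[None], n_progeny, axis=0)
    tiled_o = np.repeat(individual.origins[None], n_progeny, axis=0)
    a1, o1 = _gametes(tiled_a, tiled_o, gmap, rng)
    a2, o2 = _gametes(tiled_a, tiled_o, gmap, rng)
    ids = np.array([f"{generation or 'S'}:{i}" for i in range(n_progeny)],
                   dtype=object)
    parents = np.full((n_progeny, 2), individual.id, dtype=object)
    return Population(np.stack([a1, a2], axis=1), np.stack([o1, o2], axis=1),
                      ids, gmap, generation, individual.origin_labels, parents)


def advance_ssd(pop: Population, n_generations: int,
                rng: np.random.Generator,
                generation_tags: list[str] | None = None) -> Population:
    """Single-seed descent: one selfed offspring per individual per
    generation; population size is conserved."""
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    current = pop
    for step in range(n_generations):
        a1, o1 = _gametes(current.alleles, current.origins, pop.gmap, rng)
        a2, o2 = _gametes(current.alleles, current.origins, pop.gmap, rng)
        tag = (generation_tags[step] if generation_tags
               else f"{pop.generation}+S{step + 1}")
        parents = np.stack([current.ids, current.ids], axis=1)
        current = Population(np.stack([a1, a2], axis=1),
                             np.stack([o1, o2], axis=1),
                             current.ids.copy(), pop.gmap, tag,
                             pop.origin_labels, parents)
    return current
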