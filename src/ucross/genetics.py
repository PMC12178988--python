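"""Genotypic values, selection indices, heterozygosity, ideal genotypic
values and genomic heritability.

The central quantity is the origin-aware genotypic value: each
alternative-allele copy contributes the marker effect estimated in the
population the allele descends from,

    u_im = sum_p x_ip' beta_pm ,

where x_ip counts the individual's alternative alleles of population-p
origin at each marker.  The common-parent (baseline) allele contributes 0
everywhere, which is what makes effects estimated separately in each
population comparable on one scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genome import Individual, Population

__all__ = [
    "EffectsTable",
    "ScalingStats",
    "HeritabilityEstimate",
    "genotypic_value",
    "genotypic_values",
    "selection_index",
    "selection_indices",
    "heterozygosity",
    "observed_heterozygosity",
    "ideal_genotypic_value",
    "estimate_heritability",
]


@dataclass(frozen=True)
class EffectsTable:
    """Per-population, per-trait additive marker effects.

    ``beta[p, m, l]`` is the effect of one alternative-allele copy of
    population-``p`` origin on trait ``m`` at marker ``l``, in trait units.
    """

    beta: np.ndarray                 # (P, M, L)
    populations: tuple[str, ...]
    traits: tuple[str, ...]

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "traits", tuple(self.traits))
        if beta.ndim != 3:
            raise ValueError("beta must have shape (P, M, L)")
        if beta.shape[0] != len(self.populations):
            raise ValueError("beta first axis must match populations")
        if beta.shape[1] != len(self.traits):
            raise ValueError("beta second axis must match traits")
        if not np.all(np.isfinite(beta)):
            raise ValueError("marker effects must be finite")

    @property
    def n_markers(self) -> int:
        return self.beta.shape[2]

    def trait_index(self, trait: str) -> int:
        try:
            return self.traits.index(trait)
        except ValueError:
            raise KeyError(f"unknown trait {trait!r}") from None

    def population_index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None

    def beta_for(self, population: str, trait: str) -> np.ndarray:
        return self.beta[self.population_index(population),
                         self.trait_index(trait)]

    def aligned_to(self, origin_labels: tuple[str, ...]) -> np.ndarray:
        """beta reordered as (len(origin_labels), M, L) by origin code."""
        idx = [self.population_index(lab) for lab in origin_labels]
        return self.beta[idx]

    def to_frame(self, marker_ids: np.ndarray | None = None) -> pd.DataFrame:
        P, M, L = self.beta.shape
        markers = (np.asarray(marker_ids, dtype=object) if marker_ids
                   is not None else np.array([f"m{l}" for l in range(L)],
                                             dtype=object))
        rows = []
        for p, pop in enumerate(self.populations):
            for m, trait in enumerate(self.traits):
                rows.append(pd.DataFrame({
                    "marker": markers, "population": pop, "trait": trait,
                    "beta": self.beta[p, m]}))
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class ScalingStats:
    """Per-trait mean and standard deviation of genotypic values in a
    reference generation, used to put traits on one scale before summing
    them into a selection index or a summed usefulness criterion."""

    mean: np.ndarray   # (M,)
    sd: np.ndarray     # (M,)
    traits: tuple[str, ...]

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        sd = np.atleast_1d(np.asarray(self.sd, dtype=float))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)
        object.__setattr__(self, "traits", tuple(self.traits))
        if mean.shape != sd.shape or mean.size != len(self.traits):
            raise ValueError("mean/sd must be per-trait vectors")
        if np.any(sd <= 0):
            raise ValueError("scaling standard deviations must be positive")

    @classmethod
    def from_populations(cls, pops: list[Population] | Population,
                         effects: EffectsTable) -> "ScalingStats":
        """Pool genotypic values across the given populations (typically
        both F4 populations) and take per-trait mean and sd."""
        if isinstance(pops, Population):
            pops = [pops]
        values = np.concatenate([genotypic_values(p, effects) for p in pops])
        return cls(values.mean(axis=0), values.std(axis=0, ddof=1),
                   effects.traits)


@dataclass(frozen=True)
class HeritabilityEstimate:
    """REML variance components on the marker-kernel scale."""

    sigma_u2: float
    sigma_e2: float

    @property
    def h2(self) -> float:
        return self.sigma_u2 / (self.sigma_u2 + self.sigma_e2)


def _aligned_beta(obj: Individual | Population,
                  effects: EffectsTable) -> np.ndarray:
    for lab in obj.origin_labels:
        if lab not in effects.populations:
            raise KeyError(f"no marker effects for origin label {lab!r}")
    return effects.aligned_to(obj.origin_labels)


def genotypic_values(pop: Population, effects: EffectsTable) -> np.ndarray:
    """(n, M) matrix of origin-aware genotypic values."""
    if pop.n_markers != effects.n_markers:
        raise ValueError("population and effects disagree on marker count")
    beta = _aligned_beta(pop, effects)            # (P, M, L)
    L = pop.n_markers
    cols = np.arange(L)
    # (n, 2, L, M): effect of each allele copy under its own origin
    per_copy = pop.alleles[..., None] * \
        beta[pop.origins, :, cols[None, None, :]]
    return per_copy.sum(axis=(1, 2))


def genotypic_value(individual: Individual, effects: EffectsTable,
                    trait: str) -> float:
    """Origin-aware genotypic value of one individual for one trait."""
    if individual.n_markers != effects.n_markers:
        raise ValueError("individual and effects disagree on marker count")
    beta = _aligned_beta(individual, effects)
    m = effects.trait_index(trait)
    b = beta[individual.origins, m, np.arange(individual.n_markers)[None, :]]
    return float((individual.alleles * b).sum())


def selection_indices(pop: Population, effects: EffectsTable,
                      scaling: ScalingStats | None = None) -> np.ndarray:
    """Sum of (scaled) per-trait genotypic values for every individual."""
    values = genotypic_values(pop, effects)
    if scaling is not None:
        values = (values - scaling.mean) / scaling.sd
    return values.sum(axis=1)


def selection_index(individual: Individual, effects: EffectsTable,
                    scaling: ScalingStats | None = None) -> float:
    """Selection index of one individual: per-trait genotypic values,
    optionally standardized by reference-generation statistics, summed."""
    values = np.array([genotypic_value(individual, effects, t)
                       for t in effects.traits])
    if scaling is not None:
        values = (values - scaling.mean) / scaling.sd
    return float(values.sum())


def heterozygosity(pop: Population) -> float:
    """Average gene diversity, H = 1 - (1/L) sum_l sum_i p_li^2, with
    allele frequencies counted over both haplotypes."""
    if len(pop) == 0:
        raise ValueError("population is empty")
    p_alt = pop.alleles.mean(axis=(0, 1))
    return float(np.mean(1.0 - p_alt ** 2 - (1.0 - p_alt) ** 2))


def observed_heterozygosity(pop: Population) -> float:
    """Fraction of (individual, locus) genotype calls that are
    heterozygous; halves each selfing generation in expectation."""
    if len(pop) == 0:
        raise ValueError("population is empty")
    return float((pop.alleles[:, 0, :] != pop.alleles[:, 1, :]).mean())


def ideal_genotypic_value(effects: EffectsTable, trait: str,
                          mode: str = "across",
                          population: str | None = None) -> float:
    """Upper bound of the attainable genotypic value for a trait.

    ``mode="within"``: every locus carries the better of the baseline
    allele (effect 0) and the named population's alternative allele, two
    copies.  ``mode="across"``: the best allele among the baseline and all
    populations' alternatives.
    """
    m = effects.trait_index(trait)
    if mode == "within":
        if population is None:
            raise ValueError("mode='within' requires a population")
        b = effects.beta[effects.population_index(population), m]
        return float(2.0 * np.clip(b, 0.0, None).sum())
    if mode == "across":
        best = effects.beta[:, m, :].max(axis=0)
        return float(2.0 * np.clip(best, 0.0, None).sum())
    raise ValueError(f"unknown mode {mode!r}")


def _vanraden_kernel(genotypes: np.ndarray) -> np.ndarray:
    X = np.asarray(genotypes, dtype=float)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not np.any(poly):
        raise ValueError("no polymorphic markers; kernel is undefined")
    M = X[:, poly] - 2.0 * p[poly]
    K = M @ M.T
    # normalize to mean diagonal 1 so sigma_u^2 is the per-individual
    # genetic variance even under inbreeding (where the HWE denominator
    # 2*sum(p*q) would leave the diagonal near 1 + F)
    return K * (K.shape[0] / np.trace(K))


def estimate_heritability(genotypes: np.ndarray,
                          phenotypes: np.ndarray) -> HeritabilityEstimate:
    """Single-kernel REML estimate of genomic heritability.

    Fits ``y = mu + u + e`` with ``u ~ N(0, sigma_u^2 K)`` for a VanRaden
    marker kernel ``K``, by spectral decomposition of the projected kernel
    (the EMMA device: the restricted likelihood is a one-dimensional
    function of the variance ratio).
    """
    y = np.asarray(phenotypes, dtype=float).ravel()
    X = np.asarray(genotypes, dtype=float)
    n = y.size
    if X.shape[0] != n:
        raise ValueError("genotypes and phenotypes disagree on sample size")
    if n < 10:
        raise ValueError("too few individuals for a variance-component fit")
    if np.std(y) == 0:
        raise ValueError("phenotype is constant; variance ratio undefined")
    K = _vanraden_kernel(X)
    # project out the intercept, drop the null dimension
    yc = y - y.mean()
    J = np.full((n, n), 1.0 / n)
    S = np.eye(n) - J
    xi, U = np.linalg.eigh(S @ K @ S)
    keep = np.argsort(xi)[1:]          # discard the (~0) projected direction
    xi = np.clip(xi[keep], 0.0, None)
    eta2 = (U[:, keep].T @ yc) ** 2
    nq = n - 1

    def neg_rll(log_delta: float) -> float:
        delta = np.exp(log_delta)      # delta = sigma_e^2 / sigma_u^2
        denom = xi + delta
        return 0.5 * (nq * np.log(np.sum(eta2 / denom))
                      + np.sum(np.log(denom)))

    res = minimize_scalar(neg_rll, bounds=(-12.0, 12.0), method="bounded")
    delta = float(np.exp(res.x))
    sigma_u2 = float(np.sum(eta2 / (xi + delta)) / nq)
    return HeritabilityEstimate(sigma_u2=sigma_u2,
                                sigma_e2=delta * sigma_u2)
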