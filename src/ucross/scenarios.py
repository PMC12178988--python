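"""The two simulated breeding programs.

Both start from two F4 biparental populations (600 individuals pooled),
run for 15 generations after the first cross, and maintain 900
individuals from the first cross onward.  Crossing happens exactly twice
— once in the F4 and once in generation G_t (t in 1..4) — with
single-seed descent everywhere else:

* Scenario 1 (individual-based): select the 9 individuals with the
  highest selection index (5 + 4 per source population at the first
  round, the best 9 of all 900 at the second), cross them in all 36
  non-self combinations, 25 progeny each.
* Scenario 2 (cross-pair-based): rank candidate pairs by the summed
  usefulness criterion and take the top 10, 90 progeny each.  The
  progeny-variance term is evaluated at a reference generation — either
  G_t (the generation of the second cross) or G_15 (the final, nearly
  fixed generation).  Under the G_15 reference the second crossing round
  is skipped by default; a flag restores it.  At the second round the UC
  is computed over all pairs of the 450 individuals with the highest
  index, to bound the candidate count.

Selection uses genotypic values only (heritability 1 in the selection
step); the genomic-prediction model is never refit during the program.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import comb

import numpy as np
import pandas as pd

from .genome import Population, advance_ssd, cross_pairs
from .genetics import (EffectsTable, ScalingStats, genotypic_values,
                       selection_indices)
from .uc import (LDMatrices, RecombinationModel, evaluate_crosses,
                 ld_matrices, recombination_fractions)

__all__ = [
    "ScenarioConfig",
    "TrajectoryResult",
    "ReplicateSet",
    "run_scenario1",
    "run_scenario2",
    "run_replicates",
    "fraction_with_both_origins",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Design parameters of the breeding program."""

    t: int = 4                        # generation of the second cross
    uc_reference: str = "G_t"         # "G_t" or "G_15"
    n_select: int = 9
    split: tuple[int, int] = (5, 4)   # first-round per-population quota (S1)
    progeny_per_cross_s1: int = 25
    n_pairs_s2: int = 10
    progeny_per_cross_s2: int = 90
    shortlist: int = 450
    selection_intensity: float = 1.96
    total_generations: int = 15
    n_replicates: int = 50
    base_seed: int = 0
    second_cross_when_g15: bool = False
    max_distinct_parents: int | None = None

    def __post_init__(self) -> None:
        if self.uc_reference not in ("G_t", "G_15"):
            raise ValueError("uc_reference must be 'G_t' or 'G_15'")
        if not 1 <= self.t < self.total_generations:
            raise ValueError("t must satisfy 1 <= t < total_generations")
        if sum(self.split) != self.n_select:
            raise ValueError("split must sum to n_select")
        if self.n_crosses_s1 * self.progeny_per_cross_s1 \
                != self.n_pairs_s2 * self.progeny_per_cross_s2:
            raise ValueError("the two scenarios must maintain the same "
                             "population size")

    @property
    def n_crosses_s1(self) -> int:
        return comb(self.n_select, 2)

    @property
    def population_size(self) -> int:
        return self.n_crosses_s1 * self.progeny_per_cross_s1


@dataclass
class TrajectoryResult:
    """Per-generation summaries of one replicate of one scenario.

    Raw means/variances are stored; standardized genetic gain and
    variance ratios are derived on demand (``gain``, ``variance_ratio``).
    The selection index is on the scaled scale (per-trait genotypic
    values standardized by the pooled-F4 statistics, then summed);
    per-trait records are in raw trait units.
    """

    scenario: int
    t: int
    uc_reference: str
    seed: object
    traits: tuple[str, ...]
    generations: np.ndarray            # 0..15
    pop_size: np.ndarray               # individuals per generation
    index_mean_all: np.ndarray         # (G+1,)
    index_mean_top: np.ndarray
    index_var_all: np.ndarray
    index_var_top: np.ndarray
    trait_mean_all: np.ndarray         # (G+1, M)
    trait_mean_top: np.ndarray
    trait_var_all: np.ndarray
    trait_var_top: np.ndarray
    sigma_g2_index: float
    sigma_g2_traits: np.ndarray        # (M,)

    def gain(self, subset: str = "all") -> np.ndarray:
        """Standardized genetic gain G(t) of the selection index."""
        mean = self.index_mean_all if subset == "all" else self.index_mean_top
        return (mean - mean[0]) / np.sqrt(self.sigma_g2_index)

    def trait_gain(self, trait: str, subset: str = "top") -> np.ndarray:
        m = self.traits.index(trait)
        mean = (self.trait_mean_all if subset == "all"
                else self.trait_mean_top)[:, m]
        return (mean - mean[0]) / np.sqrt(self.sigma_g2_traits[m])

    def variance_ratio(self, subset: str = "all") -> np.ndarray:
        var = self.index_var_all if subset == "all" else self.index_var_top
        return var / self.sigma_g2_index

    def trait_variance_ratio(self, trait: str,
                             subset: str = "all") -> np.ndarray:
        m = self.traits.index(trait)
        var = (self.trait_var_all if subset == "all"
               else self.trait_var_top)[:, m]
        return var / self.sigma_g2_traits[m]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "scenario": self.scenario, "t": self.t,
            "uc_reference": self.uc_reference, "seed": str(self.seed),
            "generation": self.generations,
            "pop_size": self.pop_size,
            "index_mean_all": self.index_mean_all,
            "index_mean_top": self.index_mean_top,
            "index_var_all": self.index_var_all,
            "index_var_top": self.index_var_top,
            "index_gain_all": self.gain("all"),
            "index_gain_top": self.gain("top"),
            "index_var_ratio": self.variance_ratio("all"),
        })
        for m, trait in enumerate(self.traits):
            df[f"{trait}_mean_all"] = self.trait_mean_all[:, m]
            df[f"{trait}_mean_top"] = self.trait_mean_top[:, m]
            df[f"{trait}_var_all"] = self.trait_var_all[:, m]
            df[f"{trait}_gain_top"] = self.trait_gain(trait, "top")
            df[f"{trait}_var_ratio"] = self.trait_variance_ratio(trait)
        return df


def _top_fraction(n: int, fraction: float = 0.01) -> int:
    return max(1, int(round(fraction * n)))


def _population_stats(pop: Population, effects: EffectsTable,
                      scaling: ScalingStats) -> dict:
    values = genotypic_values(pop, effects)            # raw trait units
    scaled = (values - scaling.mean) / scaling.sd
    index = scaled.sum(axis=1)
    k = _top_fraction(len(pop))
    top_by_index = np.argsort(index)[::-1][:k]
    stats = {
        "n": len(pop),
        "index_mean_all": index.mean(),
        "index_mean_top": index[top_by_index].mean(),
        "index_var_all": index.var(ddof=1) if len(pop) > 1 else 0.0,
        "index_var_top": (index[top_by_index].var(ddof=1)
                          if k > 1 else 0.0),
    }
    M = values.shape[1]
    tm_all = values.mean(axis=0)
    tm_top = np.empty(M)
    tv_all = values.var(axis=0, ddof=1) if len(pop) > 1 else np.zeros(M)
    tv_top = np.empty(M)
    for m in range(M):
        top_by_trait = np.argsort(values[:, m])[::-1][:k]
        tm_top[m] = values[top_by_trait, m].mean()
        tv_top[m] = (values[top_by_trait, m].var(ddof=1)
                     if k > 1 else 0.0)
    stats.update(trait_mean_all=tm_all, trait_mean_top=tm_top,
                 trait_var_all=tv_all, trait_var_top=tv_top)
    return stats


def _collect(records: list[dict], scenario: int, config: ScenarioConfig,
             seed, traits, sigma_g2_index, sigma_g2_traits
             ) -> TrajectoryResult:
    G = len(records)
    M = len(traits)
    arr = {k: np.empty(G) for k in ("index_mean_all", "index_mean_top",
                                    "index_var_all", "index_var_top")}
    mats = {k: np.empty((G, M)) for k in ("trait_mean_all", "trait_mean_top",
                                          "trait_var_all", "trait_var_top")}
    for gidx, rec in enumerate(records):
        for k in arr:
            arr[k][gidx] = rec[k]
        for k in mats:
            mats[k][gidx] = rec[k]
    return TrajectoryResult(
        scenario=scenario, t=config.t, uc_reference=config.uc_reference,
        seed=seed, traits=tuple(traits), generations=np.arange(G),
        pop_size=np.array([rec["n"] for rec in records]),
        sigma_g2_index=sigma_g2_index, sigma_g2_traits=sigma_g2_traits,
        **arr, **mats)


def _initial_state(populations, effects):
    pop1, pop2 = populations
    merged = Population.merge(pop1, pop2, "G0")
    scaling = ScalingStats.from_populations([pop1, pop2], effects)
    values = genotypic_values(merged, effects)
    scaled = (values - scaling.mean) / scaling.sd
    sigma_g2_index = scaled.sum(axis=1).var(ddof=1)
    sigma_g2_traits = values.var(axis=0, ddof=1)
    return merged, scaling, sigma_g2_index, sigma_g2_traits


def _select_top(pop: Population, effects: EffectsTable,
                scaling: ScalingStats, k: int) -> np.ndarray:
    if len(pop) < k:
        raise ValueError(f"cannot select {k} from {len(pop)} individuals")
    index = selection_indices(pop, effects, scaling)
    # deterministic tie-break on id
    order = np.lexsort((pop.ids, -index))
    return order[:k]


def _rank_pairs(pop: Population, pairs: np.ndarray, effects: EffectsTable,
                ld: LDMatrices, scaling: ScalingStats, i: float,
                n_pairs: int, max_distinct: int | None) -> np.ndarray:
    table = evaluate_crosses(pop, pairs, effects, ld, scaling, i)
    order = np.lexsort((table["parent2"].to_numpy(),
                        table["parent1"].to_numpy(),
                        -table["index"].to_numpy()))
    if max_distinct is None:
        chosen = order[:n_pairs]
    else:
        chosen, parents = [], set()
        for row in order:
            cand = parents | {table["parent1"].iloc[row],
                              table["parent2"].iloc[row]}
            if len(cand) <= max_distinct:
                chosen.append(row)
                parents = cand
            if len(chosen) == n_pairs:
                break
        if len(chosen) < n_pairs:
            raise ValueError("max_distinct_parents constraint cannot yield "
                             f"{n_pairs} pairs")
        chosen = np.asarray(chosen)
    return np.asarray(pairs)[chosen]


def _all_non_self_pairs(n: int) -> np.ndarray:
    i1, i2 = np.triu_indices(n, k=1)
    return np.stack([i1, i2], axis=1)


def run_scenario1(config: ScenarioConfig, populations, effects: EffectsTable,
                  rng: np.random.Generator | int | None = None,
                  seed_label=None) -> TrajectoryResult:
    """Individual-based truncation selection on the summed index."""
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    pop1, pop2 = populations
    merged, scaling, sg2_i, sg2_t = _initial_state(populations, effects)
    records = [_population_stats(merged, effects, scaling)]

    k1, k2 = config.split
    sel1 = pop1.subset(_select_top(pop1, effects, scaling, k1))
    sel2 = pop2.subset(_select_top(pop2, effects, scaling, k2))
    parents = Population.merge(sel1, sel2)
    current = cross_pairs(parents, _all_non_self_pairs(len(parents)),
                          config.progeny_per_cross_s1, rng, "G1")
    for gen in range(1, config.total_generations + 1):
        records.append(_population_stats(current, effects, scaling))
        if gen == config.total_generations:
            break
        if gen == config.t:
            pool = current.subset(
                _select_top(current, effects, scaling, config.n_select))
            current = cross_pairs(pool, _all_non_self_pairs(len(pool)),
                                  config.progeny_per_cross_s1, rng,
                                  f"G{gen + 1}")
        else:
            current = advance_ssd(current, 1, rng, [f"G{gen + 1}"])
    return _collect(records, 1, config, seed_label, effects.traits,
                    sg2_i, sg2_t)


def run_scenario2(config: ScenarioConfig, populations, effects: EffectsTable,
                  rng: np.random.Generator | int | None = None,
                  seed_label=None) -> TrajectoryResult:
    """Cross-pair selection by summed usefulness criterion."""
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    merged, scaling, sg2_i, sg2_t = _initial_state(populations, effects)
    records = [_population_stats(merged, effects, scaling)]
    model = recombination_fractions(merged.gmap)

    # reference generation for the first round: progeny of this cross are
    # g = 1, so G_t corresponds to g = t and G_15 to g = 15
    g_first = config.t if config.uc_reference == "G_t" \
        else config.total_generations
    top = _rank_pairs(merged, _all_non_self_pairs(len(merged)), effects,
                      ld_matrices(model, g_first), scaling,
                      config.selection_intensity, config.n_pairs_s2,
                      config.max_distinct_parents)
    current = cross_pairs(merged, top, config.progeny_per_cross_s2, rng, "G1")

    second_round = config.uc_reference == "G_t" or config.second_cross_when_g15
    for gen in range(1, config.total_generations + 1):
        records.append(_population_stats(current, effects, scaling))
        if gen == config.total_generations:
            break
        if gen == config.t and second_round:
            short = current.subset(
                _select_top(current, effects, scaling,
                            min(config.shortlist, len(current))))
            # progeny of the second cross are g = 1 at G_{t+1}; the final
            # generation is always the reference here
            g_second = config.total_generations - config.t
            top = _rank_pairs(short, _all_non_self_pairs(len(short)),
                              effects, ld_matrices(model, g_second), scaling,
                              config.selection_intensity, config.n_pairs_s2,
                              config.max_distinct_parents)
            current = cross_pairs(short, top, config.progeny_per_cross_s2,
                                  rng, f"G{gen + 1}")
        else:
            current = advance_ssd(current, 1, rng, [f"G{gen + 1}"])
    return _collect(records, 2, config, seed_label, effects.traits,
                    sg2_i, sg2_t)


@dataclass
class ReplicateSet:
    """Paired replicate trajectories for both scenarios."""

    config: ScenarioConfig
    results: dict            # (scenario, t) -> list[TrajectoryResult]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for (scenario, t), trajectories in sorted(self.results.items()):
            for rep, traj in enumerate(trajectories):
                df = traj.to_frame()
                df.insert(0, "replicate", rep)
                frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def aggregate(self) -> pd.DataFrame:
        """Mean +/- sd of the standardized metrics across replicates."""
        df = self.to_frame()
        metrics = [c for c in df.columns
                   if c.endswith(("gain_all", "gain_top", "var_ratio"))]
        g = df.groupby(["scenario", "t", "generation"])[metrics]
        agg = g.agg(["mean", "std"])
        agg.columns = [f"{m}_{s}" for m, s in agg.columns]
        return agg.reset_index()


def run_replicates(config: ScenarioConfig, populations,
                   effects: EffectsTable,
                   ts: tuple[int, ...] | None = None) -> ReplicateSet:
    """Run both scenarios for each requested t, with paired seeds.

    Replicate r of scenario 1 and of scenario 2 share one seed stream, so
    per-replicate win counting (the binomial scenario comparison) is a
    matched comparison.
    """
    ts = ts or (config.t,)
    results = {}
    for t in ts:
        cfg = replace(config, t=t)
        runs1, runs2 = [], []
        for rep in range(config.n_replicates):
            ss = np.random.SeedSequence(config.base_seed,
                                        spawn_key=(t, rep))
            label = (config.base_seed, t, rep)
            runs1.append(run_scenario1(cfg, populations, effects,
                                       np.random.default_rng(ss), label))
            runs2.append(run_scenario2(cfg, populations, effects,
                                       np.random.default_rng(ss), label))
        results[(1, t)] = runs1
        results[(2, t)] = runs2
    return ReplicateSet(config=config, results=results)


def fraction_with_both_origins(pop: Population) -> float:
    """Fraction of individuals carrying alleles of both source
    populations anywhere in their genome."""
    has0 = (pop.origins == 0).any(axis=(1, 2))
    has1 = (pop.origins == 1).any(axis=(1, 2))
    return float((has0 & has1).mean())
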