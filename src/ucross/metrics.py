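"""Genetic gain, variance ratio and scenario-comparison statistics.

Gains are standardized by the genetic variance of the initial F4
population: G(t) = (mean u(t) - mean u(0)) / sqrt(sigma_g^2), and the
variance ratio is sigma^2(t) = var(u(t)) / sigma_g^2, where u is the
selection index (or a single trait's genotypic value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "ComparisonResult",
    "genetic_gain",
    "variance_ratio",
    "binomial_superiority",
    "compare_replicates",
    "compare_table",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Win count of scenario 2 over scenario 1 and its binomial p-value."""

    wins: int
    n: int
    p_value: float
    metric: str = ""
    t: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.wins <= self.n:
            raise ValueError("wins must lie in [0, n]")


def _subset_mean(values: np.ndarray, subset: str, top_fraction: float,
                 select_by: np.ndarray | None) -> float:
    values = np.asarray(values, dtype=float)
    if subset == "all":
        return float(values.mean())
    if subset == "top":
        k = max(1, int(round(top_fraction * values.size)))
        crit = values if select_by is None else np.asarray(select_by)
        idx = np.argsort(crit)[::-1][:k]
        return float(values[idx].mean())
    raise ValueError(f"unknown subset {subset!r}")


def genetic_gain(values_t: np.ndarray, values_0: np.ndarray,
                 sigma_g2: float, subset: str = "all",
                 top_fraction: float = 0.01,
                 select_by_t: np.ndarray | None = None,
                 select_by_0: np.ndarray | None = None) -> float:
    """Standardized gain of the subset mean between two generations.

    ``values_*`` are per-individual index or trait values; the top
    subset is chosen by the values themselves unless ``select_by_*``
    supplies a different ranking criterion (e.g. top-by-index when
    reporting a single trait).
    """
    if sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive")
    m_t = _subset_mean(values_t, subset, top_fraction, select_by_t)
    m_0 = _subset_mean(values_0, subset, top_fraction, select_by_0)
    return (m_t - m_0) / float(np.sqrt(sigma_g2))


def variance_ratio(values_t: np.ndarray, sigma_g2: float) -> float:
    """Current over initial genetic variance."""
    if sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive")
    values_t = np.asarray(values_t, dtype=float)
    return float(values_t.var(ddof=1) / sigma_g2)


def binomial_superiority(wins: int, n: int,
                         alternative: str = "greater",
                         metric: str = "", t: int | None = None
                         ) -> ComparisonResult:
    """Exact binomial test of scenario-2 superiority under p0 = 0.5.

    One-sided by default (the directional claim that cross-pair-based
    selection outperforms individual-based selection); pass
    ``alternative="two-sided"`` for the symmetric test.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    res = binomtest(wins, n, p=0.5, alternative=alternative)
    return ComparisonResult(wins=wins, n=n, p_value=float(res.pvalue),
                            metric=metric, t=t)


_FINAL_METRICS = ("index_gain_all", "index_gain_top", "index_var_ratio")


def compare_replicates(repset, metrics: tuple[str, ...] | None = None,
                       alternative: str = "greater") -> pd.DataFrame:
    """Per-metric, per-t win counts of scenario 2 over scenario 1 at the
    final generation, with exact binomial p-values.

    Accepts a :class:`~ucross.scenarios.ReplicateSet` whose replicates
    are paired across scenarios (same seed stream).
    """
    return compare_table(repset.to_frame(), metrics, alternative)


def compare_table(df: pd.DataFrame, metrics: tuple[str, ...] | None = None,
                  alternative: str = "greater") -> pd.DataFrame:
    """Same comparison from a raw per-replicate trajectory table (the
    format emitted by ``ReplicateSet.to_frame`` / the run-scenario CLI)."""
    if metrics is None:
        metrics = tuple(m for m in df.columns
                        if m in _FINAL_METRICS
                        or m.endswith(("gain_top", "var_ratio")))
    final = df[df["generation"] == df["generation"].max()]
    rows = []
    for t in sorted(final["t"].unique()):
        s1 = final[(final["scenario"] == 1) & (final["t"] == t)] \
            .sort_values("replicate")
        s2 = final[(final["scenario"] == 2) & (final["t"] == t)] \
            .sort_values("replicate")
        for metric in metrics:
            wins = int((s2[metric].to_numpy()
                        > s1[metric].to_numpy()).sum())
            res = binomial_superiority(wins, len(s1), alternative,
                                       metric, int(t))
            rows.append({"metric": metric, "t": int(t), "wins": res.wins,
                         "n": res.n, "p_value": res.p_value})
    return pd.DataFrame(rows)
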