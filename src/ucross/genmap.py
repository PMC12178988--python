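"""Genetic maps and the Haldane mapping function.

A :class:`MarkerMap` holds marker identifiers, chromosome assignments and
genetic positions in centimorgans.  All recombination fractions in the
package — both those driving the meiosis simulator and those entering the
analytical progeny-variance machinery — are derived from the same map
through :func:`haldane`, so the stochastic and analytical halves of the
package agree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "generate_map",
    "haldane",
    "inverse_haldane",
]


def haldane(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Map distance (cM) to recombination fraction, assuming no interference.

    ``c = (1 - exp(-2 d / 100)) / 2``; approaches 0.5 for distant loci.
    """
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def inverse_haldane(c: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction to map distance (cM); ``c`` must be < 0.5."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or np.any(c >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return -50.0 * np.log(1.0 - 2.0 * c)


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker map: identifiers, chromosomes, positions in cM.

    Markers must be sorted by (chromosome, position) with strictly
    increasing positions within each chromosome.
    """

    marker_ids: np.ndarray
    chromosome: np.ndarray
    position_cM: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.marker_ids, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=int)
        pos = np.asarray(self.position_cM, dtype=float)
        object.__setattr__(self, "marker_ids", ids)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_cM", pos)
        if not (ids.shape == chrom.shape == pos.shape) or ids.ndim != 1:
            raise ValueError("marker_ids, chromosome and position_cM must be "
                             "1-D arrays of equal length")
        if ids.size < 2:
            raise ValueError("a map needs at least two markers")
        if len(set(ids.tolist())) != ids.size:
            raise ValueError("marker identifiers must be unique")
        if np.any(pos < 0):
            raise ValueError("map positions must be non-negative")
        # grouped by chromosome, strictly increasing positions within each
        seen: list[int] = []
        for c in chrom:
            if seen and c != seen[-1] and c in seen:
                raise ValueError("markers of one chromosome must be contiguous")
            if not seen or c != seen[-1]:
                seen.append(int(c))
        for c in seen:
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions on chromosome {c} must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return self.marker_ids.size

    @property
    def chromosomes(self) -> np.ndarray:
        """Chromosome labels in map order."""
        _, idx = np.unique(self.chromosome, return_index=True)
        return self.chromosome[np.sort(idx)]

    def chromosome_start(self) -> np.ndarray:
        """Boolean mask marking the first marker of each chromosome."""
        start = np.empty(self.n_markers, dtype=bool)
        start[0] = True
        start[1:] = self.chromosome[1:] != self.chromosome[:-1]
        return start

    def adjacent_recombination(self) -> np.ndarray:
        """Per-marker recombination fraction with the preceding marker.

        The first marker of each chromosome gets 0.5 (independent
        assortment), which doubles as a fair-coin start for the crossover
        parity process used by the meiosis simulator.
        """
        r = np.empty(self.n_markers, dtype=float)
        d = np.diff(self.position_cM)
        r[1:] = haldane(d)
        r[self.chromosome_start()] = 0.5
        return r

    def pairwise_recombination(self) -> np.ndarray:
        """L x L matrix of recombination fractions between all marker pairs.

        Haldane transform of cM distance within chromosomes, 0.5 between
        chromosomes, 0 on the diagonal.
        """
        d = np.abs(self.position_cM[:, None] - self.position_cM[None, :])
        c = haldane(d)
        c[self.chromosome[:, None] != self.chromosome[None, :]] = 0.5
        np.fill_diagonal(c, 0.0)
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker": self.marker_ids,
            "chrom": self.chromosome,
            "pos_cM": self.position_cM,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMap":
        return cls(df["marker"].to_numpy(dtype=object),
                   df["chrom"].to_numpy(dtype=int),
                   df["pos_cM"].to_numpy(dtype=float))


def generate_map(n_chrom: int, markers_per_chrom: int, chrom_length_cM: float,
                 seed: int | None = None,
                 spacing: str = "uniform") -> MarkerMap:
    """Build a synthetic marker map.

    Parameters
    ----------
    n_chrom, markers_per_chrom, chrom_length_cM
        Number of chromosomes, markers per chromosome and chromosome length.
    seed
        Seeds marker placement when ``spacing="random"``; ignored for the
        deterministic uniform layout.
    spacing
        ``"uniform"`` places markers evenly from 0 to the chromosome end;
        ``"random"`` draws sorted uniform positions.
    """
    if n_chrom < 1 or markers_per_chrom < 2 or chrom_length_cM <= 0:
        raise ValueError("need n_chrom >= 1, markers_per_chrom >= 2 and a "
                         "positive chromosome length")
    if spacing not in ("uniform", "random"):
        raise ValueError(f"unknown spacing {spacing!r}")
    rng = np.random.default_rng(seed)
    ids, chroms, pos = [], [], []
    for c in range(1, n_chrom + 1):
        if spacing == "uniform":
            p = np.linspace(0.0, chrom_length_cM, markers_per_chrom)
        else:
            while True:
                p = np.sort(rng.uniform(0.0, chrom_length_cM,
                                        markers_per_chrom))
                if np.all(np.diff(p) > 0):
                    break
        ids.extend(f"c{c}m{j + 1}" for j in range(markers_per_chrom))
        chroms.extend([c] * markers_per_chrom)
        pos.append(p)
    return MarkerMap(np.array(ids, dtype=object), np.array(chroms),
                     np.concatenate(pos))
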