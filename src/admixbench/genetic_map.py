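"""Genetic maps: physical (bp) <-> genetic (cM) coordinate interpolation.

A :class:`GeneticMap` is a piecewise-linear, monotone mapping between physical
position on one chromosome and cumulative genetic distance, in the spirit of
the HapMap recombination-map files (position, rate in cM/Mb, cumulative cM).
It is used to place crossovers uniformly in genetic distance and to weight
ancestry tracts by the genetic length they span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneticMap", "make_genetic_map", "read_hapmap_map", "write_hapmap_map"]


@dataclass(frozen=True)
class GeneticMap:
    """Monotone piecewise-linear map between bp and cumulative cM.

    Parameters
    ----------
    chromosome
        Chromosome label.
    positions
        Strictly increasing physical coordinates (bp, 1-based).
    cumulative_cm
        Non-decreasing cumulative genetic distance at each position,
        starting at 0 by convention.
    """

    chromosome: str
    positions: np.ndarray = field(repr=False)
    cumulative_cm: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        cm = np.asarray(self.cumulative_cm, dtype=np.float64)
        if pos.ndim != 1 or cm.ndim != 1 or pos.size != cm.size:
            raise ValueError("positions and cumulative_cm must be 1-D and of equal length")
        if pos.size < 2:
            raise ValueError("a genetic map needs at least two points")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.diff(cm) >= 0):
            raise ValueError("cumulative_cm must be non-decreasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "cumulative_cm", cm)

    @property
    def span_bp(self) -> tuple[int, int]:
        return int(self.positions[0]), int(self.positions[-1])

    @property
    def length_bp(self) -> int:
        return int(self.positions[-1])

    @property
    def total_cm(self) -> float:
        return float(self.cumulative_cm[-1] - self.cumulative_cm[0])

    def cm_at(self, bp) -> np.ndarray | float:
        """Cumulative cM at physical position(s), clamped outside the map span."""
        out = np.interp(np.asarray(bp, dtype=np.float64), self.positions, self.cumulative_cm)
        return float(out) if np.isscalar(bp) else out

    def bp_at(self, cm) -> np.ndarray | float:
        """Physical position at cumulative genetic position(s) (inverse interpolation).

        Flat (zero-recombination) stretches carry zero genetic measure, so a
        continuous uniform draw in cM never resolves inside them.
        """
        out = np.interp(np.asarray(cm, dtype=np.float64), self.cumulative_cm, self.positions)
        return float(out) if np.isscalar(cm) else out


def make_genetic_map(
    chromosome_length_bp: int,
    total_cm: float,
    n_points: int,
    seed: int,
    chromosome: str = "1",
) -> GeneticMap:
    """Draw a random monotone genetic map spanning ``[1, chromosome_length_bp]``.

    Interior anchor positions are uniform draws; genetic-length increments are
    Dirichlet(1) fractions of ``total_cm``, so rate variation along the
    chromosome is irregular, as in empirical maps.
    """
    length = int(chromosome_length_bp)
    if length < 2:
        raise ValueError("chromosome_length_bp must be >= 2")
    if total_cm < 0:
        raise ValueError("total_cm must be >= 0")
    n_points = int(n_points)
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rng = np.random.default_rng(seed)
    if n_points > 2:
        interior = rng.choice(np.arange(2, length, dtype=np.int64), size=min(n_points - 2, length - 2), replace=False)
        positions = np.concatenate(([1], np.sort(interior), [length]))
    else:
        positions = np.array([1, length], dtype=np.int64)
    increments = rng.dirichlet(np.ones(positions.size - 1)) * total_cm
    cumulative = np.concatenate(([0.0], np.cumsum(increments)))
    if total_cm > 0:
        cumulative[-1] = total_cm  # pin the endpoint against float drift
    return GeneticMap(chromosome=chromosome, positions=positions, cumulative_cm=cumulative)


def write_hapmap_map(gmap: GeneticMap, path) -> None:
    """Write a HapMap-style map file: chromosome, position, rate (cM/Mb), cumulative cM."""
    pos = gmap.positions
    cm = gmap.cumulative_cm
    rate = np.zeros_like(cm)
    # rate on the interval starting at each point; last point repeats 0
    dbp = np.diff(pos).astype(float)
    rate[:-1] = np.diff(cm) / dbp * 1e6
    with open(path, "w") as fh:
        fh.write("chr\tposition\trate(cM/Mb)\tcM\n")
        for p, r, c in zip(pos, rate, cm):
            fh.write(f"{gmap.chromosome}\t{p}\t{r:.10g}\t{c:.10g}\n")


def read_hapmap_map(path) -> GeneticMap:
    """Read a HapMap-style map file written by :func:`write_hapmap_map`."""
    chroms: list[str] = []
    positions: list[int] = []
    cms: list[float] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("chr"):
            raise ValueError("not a HapMap map file (missing header)")
        for line in fh:
            if not line.strip():
                continue
            chrom, p, _rate, c = line.rstrip("\n").split("\t")
            chroms.append(chrom)
            positions.append(int(p))
            cms.append(float(c))
    if not positions:
        raise ValueError("empty genetic map file")
    if len(set(chroms)) != 1:
        raise ValueError("expected a single-chromosome map file")
    return GeneticMap(chromosome=chroms[0], positions=np.array(positions), cumulative_cm=np.array(cms))
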