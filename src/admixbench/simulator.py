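"""Forward-in-time simulation of an admixed cohort with exact ancestry tracts.

Each generation, a fraction of the population is replaced by fresh migrants
(whole diploid individuals copied from the founder reference panel) according
to a :class:`~admixbench.demography.MigrationSchedule`; the remainder are
offspring of two distinct random parents from the previous generation.
Meiosis follows a Poisson crossover model without interference: the crossover
count on a gamete is Poisson in the chromosome's genetic length (Morgans) and
crossover positions are uniform in genetic distance, mapped to physical
coordinates by inverse interpolation of the genetic map. Ancestry breakpoints
are tracked exactly through every meiosis, so the emitted cohort carries both
phased genotypes and ground-truth local-ancestry tracts, from which true
global ancestry proportions are derived as genetic-length-weighted tract
shares.

Coordinates are 0-based half-open internally; breakpoints are continuous
(float64) base-pair positions and are only rounded at file export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .demography import MigrationSchedule, expected_proportions
from .genetic_map import GeneticMap
from .synthetic_reference import ReferencePanel

__all__ = [
    "AncestryTract",
    "SimulatedCohort",
    "split_reference",
    "recombine",
    "simulate_cohort",
    "true_global_from_tracts",
]


@dataclass(frozen=True)
class AncestryTract:
    """Maximal single-ancestry segment of one haplotype, 0-based half-open."""

    chromosome: str
    start_bp: float
    end_bp: float
    ancestry: str
    haplotype_id: str

    def __post_init__(self) -> None:
        if not self.start_bp < self.end_bp:
            raise ValueError("tract must satisfy start_bp < end_bp")


# Internal haplotype representation: (alleles, bounds, anc).
#   alleles: uint8 vector over the shared site set (never mutated in place)
#   bounds:  float64 tract END coordinates, strictly increasing, last == chrom_end
#   anc:     int16 ancestry codes per tract, adjacent entries distinct
Hap = tuple[np.ndarray, np.ndarray, np.ndarray]


def _merge_adjacent(bounds: list[float], anc: list[int]) -> Hap:
    mb: list[float] = []
    ma: list[int] = []
    for b, a in zip(bounds, anc):
        if ma and ma[-1] == a:
            mb[-1] = b
        else:
            mb.append(b)
            ma.append(a)
    return np.array(mb, dtype=np.float64), np.array(ma, dtype=np.int16)


def split_reference(
    panel: ReferencePanel, n_founders_per_pop: int, seed: int
) -> tuple[ReferencePanel, ReferencePanel]:
    """Randomly split a panel into (founder, holdout) sub-panels.

    Exactly ``n_founders_per_pop`` individuals per population go to the
    founder panel (the simulator's gene pool); the rest form the holdout used
    as inference reference. Mirrors the 55 / 444 split of the five-way
    benchmark design (11 founders from each of five panels).
    """
    n_f = int(n_founders_per_pop)
    if n_f < 1:
        raise ValueError("n_founders_per_pop must be >= 1")
    rng = np.random.default_rng(seed)
    founder_idx: list[int] = []
    holdout_idx: list[int] = []
    for pop in panel.populations:
        members = panel.individuals_of(pop)
        if members.size <= n_f:
            raise ValueError(
                f"population {pop!r} has {members.size} individuals; needs more than {n_f} to split"
            )
        chosen = rng.choice(members, size=n_f, replace=False)
        founder_idx.extend(sorted(chosen.tolist()))
        holdout_idx.extend(sorted(set(members.tolist()) - set(chosen.tolist())))
    return panel.subset_individuals(sorted(founder_idx)), panel.subset_individuals(sorted(holdout_idx))


def _gamete(
    hap_a: Hap,
    hap_b: Hap,
    gmap: GeneticMap,
    rng: np.random.Generator,
    site_positions: np.ndarray,
    chrom_start: float,
    chrom_end: float,
) -> Hap:
    total_cm = gmap.total_cm
    n_x = rng.poisson(total_cm / 100.0) if total_cm > 0 else 0
    first = int(rng.integers(2))
    parents = (hap_a, hap_b)
    if n_x == 0:
        al, bd, an = parents[first]
        return al, bd.copy(), an.copy()

    u = rng.uniform(gmap.cumulative_cm[0], gmap.cumulative_cm[-1], size=n_x)
    bps = np.asarray(gmap.bp_at(u), dtype=np.float64).ravel()
    bps = bps[(bps > chrom_start) & (bps < chrom_end)]
    # crossovers at an identical position cancel pairwise
    vals, counts = np.unique(bps, return_counts=True)
    cuts = vals[counts % 2 == 1]
    if cuts.size == 0:
        al, bd, an = parents[first]
        return al, bd.copy(), an.copy()

    seg_edges = np.concatenate(([chrom_start], cuts, [chrom_end]))
    alleles = np.empty(site_positions.size, dtype=np.uint8)
    site_cuts = np.searchsorted(site_positions, seg_edges)
    out_bounds: list[float] = []
    out_anc: list[int] = []
    for s in range(seg_edges.size - 1):
        a, b = seg_edges[s], seg_edges[s + 1]
        src_al, src_bd, src_an = parents[(first + s) % 2]
        alleles[site_cuts[s]:site_cuts[s + 1]] = src_al[site_cuts[s]:site_cuts[s + 1]]
        i = int(np.searchsorted(src_bd, a, side="right"))
        while i < src_bd.size:
            end = min(float(src_bd[i]), b)
            out_bounds.append(end)
            out_anc.append(int(src_an[i]))
            if src_bd[i] >= b:
                break
            i += 1
    bounds, anc = _merge_adjacent(out_bounds, out_anc)
    return alleles, bounds, anc


def recombine(
    parent_hap_a: Hap,
    parent_hap_b: Hap,
    gmap: GeneticMap,
    rng: np.random.Generator,
    site_positions: np.ndarray,
    chrom_start: float = 0.0,
    chrom_end: float | None = None,
) -> Hap:
    """Produce one gamete from a parent's two haplotypes.

    Crossover count ~ Poisson(genetic length in Morgans); positions are
    uniform in cM, mapped to bp by inverse interpolation. A zero-cM map
    yields a fair-coin copy of one whole parental haplotype. The gamete's
    tracts are the interleaving of the parental tracts, re-maximalized.
    """
    if chrom_end is None:
        chrom_end = float(parent_hap_a[1][-1])
    if parent_hap_a[0].size != parent_hap_b[0].size:
        raise ValueError("parent haplotypes must span the same sites")
    return _gamete(parent_hap_a, parent_hap_b, gmap, rng, np.asarray(site_positions), chrom_start, chrom_end)


def _hap_global(bounds: np.ndarray, anc: np.ndarray, gmap: GeneticMap, k: int, chrom_start: float) -> np.ndarray:
    """Genetic-length (fallback physical-length) ancestry shares of one haplotype."""
    starts = np.concatenate(([chrom_start], bounds[:-1]))
    glen = np.asarray(gmap.cm_at(bounds)) - np.asarray(gmap.cm_at(starts))
    if glen.sum() <= 0:
        glen = bounds - starts
    out = np.zeros(k)
    np.add.at(out, anc, glen)
    return out


@dataclass
class SimulatedCohort:
    """Phased genotypes plus exact ancestry truth for a simulated admixed cohort."""

    chromosome: str
    positions: np.ndarray = field(repr=False)
    ref: np.ndarray = field(repr=False)
    alt: np.ndarray = field(repr=False)
    sample_ids: list[str] = field(repr=False)
    ancestries: tuple[str, ...]
    haplotypes: np.ndarray = field(repr=False)
    tract_bounds: list[np.ndarray] = field(repr=False)
    tract_anc: list[np.ndarray] = field(repr=False)
    chrom_start: float
    chrom_end: float
    gmap: GeneticMap = field(repr=False)
    schedule_used: MigrationSchedule = field(repr=False)
    seed: int
    true_global: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.true_global is None:
            k = len(self.ancestries)
            tg = np.zeros((self.n_individuals, k))
            for i in range(self.n_individuals):
                w = _hap_global(self.tract_bounds[2 * i], self.tract_anc[2 * i], self.gmap, k, self.chrom_start)
                w += _hap_global(self.tract_bounds[2 * i + 1], self.tract_anc[2 * i + 1], self.gmap, k, self.chrom_start)
                tg[i] = w / w.sum()
            self.true_global = tg
        sums = self.true_global.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("true_global rows must sum to 1")

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def haplotype_ids(self) -> list[str]:
        return [f"{sid}.{h}" for sid in self.sample_ids for h in (0, 1)]

    def tracts_dataframe(self) -> pd.DataFrame:
        """All truth tracts as a BED-like table (float bp rounded to int)."""
        rows = []
        hap_ids = self.haplotype_ids()
        for h, hid in enumerate(hap_ids):
            bounds = self.tract_bounds[h]
            starts = np.concatenate(([self.chrom_start], bounds[:-1]))
            for s, e, a in zip(starts, bounds, self.tract_anc[h]):
                rows.append((self.chromosome, int(round(s)), int(round(e)), hid, self.ancestries[a]))
        return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp", "haplotype_id", "ancestry"])

    def switch_point_counts(self) -> np.ndarray:
        """Number of ancestry switch points per haplotype."""
        return np.array([b.size - 1 for b in self.tract_bounds])

    def true_global_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.true_global, index=self.sample_ids, columns=list(self.ancestries))

    def write_vcf(self, path) -> None:
        from . import format_io

        format_io.write_phased_vcf(
            path, self.chromosome, self.positions, self.ref, self.alt, self.sample_ids, self.haplotypes
        )

    def write_tracts(self, path) -> None:
        self.tracts_dataframe().to_csv(path, sep="\t", index=False, header=False)

    def write_true_global(self, path) -> None:
        self.true_global_dataframe().to_csv(path, sep="\t", index=True, header=True, float_format="%.6f")

    def write_manifest(self, path) -> None:
        manifest = {
            "seed": int(self.seed),
            "n_individuals": self.n_individuals,
            "n_sites": self.n_sites,
            "chromosome": self.chromosome,
            "ancestries": list(self.ancestries),
            "generations": self.schedule_used.generations,
            "migration_matrix": self.schedule_used.m.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2)


def simulate_cohort(
    founders: ReferencePanel,
    schedule: MigrationSchedule,
    gmap: GeneticMap,
    n_out: int,
    pop_size: int = 1000,
    seed: int = 0,
) -> SimulatedCohort:
    """Run the forward admixture simulation and return the final cohort.

    At generation 1 every individual is a migrant (founding pulse or row 1 of
    the schedule); at each later generation t each individual is independently
    a fresh migrant with probability Σ_k m_k(t) (ancestry k with probability
    m_k(t)/Σ), otherwise the offspring of two distinct random parents of
    generation t−1. Migrants are whole diploid founder individuals resampled
    with replacement from the founder panel. ``n_out`` individuals are sampled
    without replacement from the final generation.
    """
    pop_size = int(pop_size)
    n_out = int(n_out)
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    if not (1 <= n_out <= pop_size):
        raise ValueError("n_out must satisfy 1 <= n_out <= pop_size")
    missing = [a for a in schedule.ancestries if a not in founders.populations]
    if missing:
        raise ValueError(f"schedule ancestries missing from founder panel: {missing}")
    if founders.positions[-1] > gmap.length_bp:
        raise ValueError("founder sites extend beyond the genetic map span")

    rng = np.random.default_rng(seed)
    chrom_start = 0.0
    chrom_end = float(gmap.length_bp) + 1.0
    site_positions = founders.positions
    pools = [founders.individuals_of(a) for a in schedule.ancestries]

    def migrant(k: int) -> tuple[Hap, Hap]:
        j = int(rng.choice(pools[k]))
        bounds = np.array([chrom_end])
        anc = np.array([k], dtype=np.int16)
        return (
            (founders.haplotypes[2 * j], bounds, anc),
            (founders.haplotypes[2 * j + 1], bounds.copy(), anc.copy()),
        )

    m = schedule.m
    population: list[tuple[Hap, Hap]] = [migrant(int(rng.choice(m.shape[1], p=m[0]))) for _ in range(pop_size)]
    for t in range(1, schedule.generations):
        total = m[t].sum()
        probs = m[t] / total if total > 0 else None
        new_population: list[tuple[Hap, Hap]] = []
        for _ in range(pop_size):
            if total > 0 and rng.random() < total:
                new_population.append(migrant(int(rng.choice(m.shape[1], p=probs))))
            else:
                pa, pb = rng.choice(pop_size, size=2, replace=False)
                g1 = _gamete(*population[pa], gmap, rng, site_positions, chrom_start, chrom_end)
                g2 = _gamete(*population[pb], gmap, rng, site_positions, chrom_start, chrom_end)
                new_population.append((g1, g2))
        population = new_population

    chosen = rng.choice(pop_size, size=n_out, replace=False)
    haplotypes = np.empty((2 * n_out, site_positions.size), dtype=np.uint8)
    tract_bounds: list[np.ndarray] = []
    tract_anc: list[np.ndarray] = []
    for i, c in enumerate(chosen):
        for h in (0, 1):
            al, bd, an = population[c][h]
            haplotypes[2 * i + h] = al
            tract_bounds.append(bd)
            tract_anc.append(an)
    return SimulatedCohort(
        chromosome=founders.chromosome,
        positions=site_positions.copy(),
        ref=np.asarray(founders.ref).copy(),
        alt=np.asarray(founders.alt).copy(),
        sample_ids=[f"sim_{i}" for i in range(n_out)],
        ancestries=tuple(schedule.ancestries),
        haplotypes=haplotypes,
        tract_bounds=tract_bounds,
        tract_anc=tract_anc,
        chrom_start=chrom_start,
        chrom_end=chrom_end,
        gmap=gmap,
        schedule_used=schedule,
        seed=int(seed),
    )


def true_global_from_tracts(
    tracts: Iterable[AncestryTract] | pd.DataFrame,
    gmap: GeneticMap,
    ancestries: Sequence[str],
) -> np.ndarray:
    """Genetic-length-weighted ancestry shares for one individual's tracts.

    ``tracts`` must tile each of the individual's haplotypes without gaps or
    overlaps (both haplotypes spanning the same interval); violations raise.
    Falls back to physical-length weighting on a zero-cM map.
    """
    if isinstance(tracts, pd.DataFrame):
        df = tracts
    else:
        df = pd.DataFrame(
            [(t.start_bp, t.end_bp, t.haplotype_id, t.ancestry) for t in tracts],
            columns=["start_bp", "end_bp", "haplotype_id", "ancestry"],
        )
    if df.empty:
        raise ValueError("no tracts supplied")
    unknown = set(df["ancestry"]) - set(ancestries)
    if unknown:
        raise ValueError(f"unknown ancestry labels: {sorted(unknown)}")
    spans = []
    for hid, grp in df.groupby("haplotype_id", sort=True):
        grp = grp.sort_values("start_bp")
        starts = grp["start_bp"].to_numpy(dtype=float)
        ends = grp["end_bp"].to_numpy(dtype=float)
        if np.any(starts[1:] != ends[:-1]):
            raise ValueError(f"haplotype {hid!r}: tracts have gaps or overlaps")
        if np.any(starts >= ends):
            raise ValueError(f"haplotype {hid!r}: empty or inverted tract")
        spans.append((starts[0], ends[-1]))
    if len({s for s in spans}) != 1:
        raise ValueError("haplotypes do not span the same interval")

    code = {a: i for i, a in enumerate(ancestries)}
    glen = np.asarray(gmap.cm_at(df["end_bp"].to_numpy(float))) - np.asarray(gmap.cm_at(df["start_bp"].to_numpy(float)))
    if glen.sum() <= 0:
        glen = df["end_bp"].to_numpy(float) - df["start_bp"].to_numpy(float)
    out = np.zeros(len(ancestries))
    np.add.at(out, df["ancestry"].map(code).to_numpy(), glen)
    return out / out.sum()


def mean_true_global(cohort: SimulatedCohort) -> np.ndarray:
    """Cohort mean of the true global ancestry proportions (convenience)."""
    return cohort.true_global.mean(axis=0)


def expected_vs_realized(cohort: SimulatedCohort) -> pd.DataFrame:
    """Side-by-side closed-form expectation and realized cohort means."""
    return pd.DataFrame(
        {
            "expected": expected_proportions(cohort.schedule_used),
            "realized_mean": mean_true_global(cohort),
        },
        index=list(cohort.ancestries),
    )
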