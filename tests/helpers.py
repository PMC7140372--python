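"""Shared fixture builders: small simulation worlds used across test modules."""

from __future__ import annotations

import numpy as np

from admixbench import (
    GeneticMap,
    MigrationSchedule,
    PopulationSpec,
    ReferencePanel,
    simulate_panels,
)
from admixbench.simulator import SimulatedCohort


def linear_map(length_bp: int = 1_000_000, total_cm: float = 1.0, chromosome: str = "1") -> GeneticMap:
    return GeneticMap(
        chromosome=chromosome,
        positions=np.array([1, length_bp]),
        cumulative_cm=np.array([0.0, total_cm]),
    )


def pulse_schedule(proportions, extra_generations: int = 0, ancestries=None) -> MigrationSchedule:
    """Founding pulse followed by migration-free generations."""
    proportions = np.asarray(proportions, dtype=float)
    if ancestries is None:
        ancestries = tuple(f"P{i}" for i in range(proportions.size))
    m = np.zeros((1 + extra_generations, proportions.size))
    m[0] = proportions
    return MigrationSchedule(ancestries=tuple(ancestries), m=m)


def perfect_world(
    n_windows: int = 40,
    k: int = 5,
    n_per_pop: int = 5,
    window_bp: int = 10_001,
    window_cm: float = 0.25,
):
    """A world with perfectly informative markers and well-posed windows.

    Each window of ``window_bp`` bp carries ``window_cm`` cM and holds one
    cluster of K markers at its centre (population p's marker is fixed alt in
    population p, fixed ref elsewhere). The genetic map is flat across each
    marker cluster, so crossovers never fall inside a cluster and the
    window-majority truth projection provably agrees with a frequency-based
    caller wherever a window holds at most one ancestry breakpoint.

    Returns ``(panel, gmap, window_cm)``.
    """
    length = n_windows * window_bp
    positions_anchor = [1]
    cm_anchor = [0.0]
    site_positions = []
    site_block = []
    half = (window_bp - 1) // 2
    for w in range(n_windows):
        start = 1 + w * window_bp
        centre = start + half
        mid_cm = w * window_cm + window_cm / 2
        positions_anchor += [centre - 2, centre + 2, start + window_bp]
        cm_anchor += [mid_cm, mid_cm, (w + 1) * window_cm]
        for p in range(k):
            site_positions.append(centre - 2 + p)
            site_block.append(p)
    del length
    gmap = GeneticMap(chromosome="1", positions=np.array(positions_anchor), cumulative_cm=np.array(cm_anchor))
    site_positions = np.array(site_positions, dtype=np.int64)
    site_block = np.array(site_block)
    n_sites = site_positions.size
    haplotypes = np.zeros((2 * k * n_per_pop, n_sites), dtype=np.uint8)
    sample_population = np.array([f"P{p}" for p in range(k) for _ in range(n_per_pop)], dtype=object)
    hap_pop = np.repeat(np.arange(k), 2 * n_per_pop)
    for p in range(k):
        haplotypes[np.ix_(hap_pop == p, site_block == p)] = 1
    panel = ReferencePanel(
        chromosome="1",
        positions=site_positions,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        haplotypes=haplotypes,
        sample_ids=[f"P{p}_{i}" for p in range(k) for i in range(n_per_pop)],
        sample_population=sample_population,
    )
    return panel, gmap, window_cm


def differentiated_world(differentiations, n_per_pop: int = 30, n_sites: int = 400, seed: int = 11):
    """Balding–Nichols panels over a 20 cM chromosome, one spec per drift value."""
    gmap = GeneticMap(chromosome="1", positions=np.array([1, 10_000_000]), cumulative_cm=np.array([0.0, 20.0]))
    specs = [PopulationSpec(f"P{i}", n_per_pop, d) for i, d in enumerate(differentiations)]
    panel = simulate_panels(specs, n_sites, gmap, seed)
    return panel, gmap


def manual_cohort(gmap: GeneticMap, ancestries, hap_tracts, haplotypes=None, positions=None) -> SimulatedCohort:
    """Hand-build a SimulatedCohort from explicit per-haplotype tract lists.

    ``hap_tracts``: list (one entry per haplotype, two per individual) of
    lists of (end_bp, ancestry_code); the implicit start is the previous end
    (chromosome start 0).
    """
    n_hap = len(hap_tracts)
    assert n_hap % 2 == 0
    chrom_end = float(hap_tracts[0][-1][0])
    if positions is None:
        positions = np.array([1], dtype=np.int64)
    if haplotypes is None:
        haplotypes = np.zeros((n_hap, len(positions)), dtype=np.uint8)
    schedule = pulse_schedule(np.ones(len(ancestries)) / len(ancestries), ancestries=ancestries)
    return SimulatedCohort(
        chromosome=gmap.chromosome,
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.full(len(positions), "A", dtype=object),
        alt=np.full(len(positions), "G", dtype=object),
        sample_ids=[f"ind_{i}" for i in range(n_hap // 2)],
        ancestries=tuple(ancestries),
        haplotypes=np.asarray(haplotypes, dtype=np.uint8),
        tract_bounds=[np.array([e for e, _ in tr], dtype=float) for tr in hap_tracts],
        tract_anc=[np.array([a for _, a in tr], dtype=np.int16) for tr in hap_tracts],
        chrom_start=0.0,
        chrom_end=chrom_end,
        gmap=gmap,
        schedule_used=schedule,
        seed=0,
    )
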