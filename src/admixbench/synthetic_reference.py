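"""Synthetic differentiated reference panels under a Balding–Nichols model.

Real ancestry-inference benchmarks draw their source haplotypes from
restricted-access reference panels. This module emulates that gene pool:
``K`` source populations diverge from a shared ancestral allele-frequency
distribution, with a one-parameter drift/differentiation knob per population.
For each site an ancestral frequency ``p`` is drawn, each population's
frequency is Beta-distributed around ``p`` with variance ``F·p(1-p)``
(the Balding–Nichols parameterisation), and phased haplotype alleles are
then drawn independently per site. Linkage within the reference panels is
deliberately not modelled: downstream truth-tract bookkeeping depends only
on the haplotype copying process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genetic_map import GeneticMap, make_genetic_map  # noqa: F401  (re-export)

__all__ = ["PopulationSpec", "ReferencePanel", "simulate_panels", "make_genetic_map", "GeneticMap"]


@dataclass(frozen=True)
class PopulationSpec:
    """One source population: panel size and drift from the shared ancestor.

    ``differentiation`` is the Balding–Nichols F: the fraction of ancestral
    heterozygosity lost to drift on this population's branch. Two populations
    with parameters F1, F2 have expected pairwise Hudson F_ST ≈ (F1+F2)/2.
    """

    name: str
    n_individuals: int
    differentiation: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("population name must be non-empty")
        if int(self.n_individuals) < 1:
            raise ValueError(f"population {self.name!r}: n_individuals must be >= 1")
        if not (0.0 < float(self.differentiation) < 1.0):
            raise ValueError(f"population {self.name!r}: differentiation must lie in (0, 1)")


# Panel sizes of the five-way benchmark's merged reference dataset; the
# differentiation defaults put the two African populations closest to each
# other, then the Eurasian populations, echoing the confusability structure
# (KhoeSan <-> Bantu-speaking, European <-> South East Asian) seen in practice.
SAC_POPULATION_SPECS: tuple[PopulationSpec, ...] = (
    PopulationSpec("KhoeSan", 284, 0.05),
    PopulationSpec("European", 79, 0.12),
    PopulationSpec("Bantu", 35, 0.06),
    PopulationSpec("EastAsian", 50, 0.25),
    PopulationSpec("SouthEastAsian", 103, 0.10),
)


@dataclass
class ReferencePanel:
    """Phased haplotypes with population labels for a single chromosome.

    ``haplotypes`` is a strictly binary (2·n_individuals × n_sites) matrix;
    rows ``2i`` and ``2i+1`` are the two haplotypes of individual ``i``.
    """

    chromosome: str
    positions: np.ndarray = field(repr=False)
    ref: np.ndarray = field(repr=False)
    alt: np.ndarray = field(repr=False)
    haplotypes: np.ndarray = field(repr=False)
    sample_ids: list[str] = field(repr=False)
    sample_population: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.sample_population = np.asarray(self.sample_population, dtype=object)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("haplotype columns must match number of sites")
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype rows must equal 2 * n_individuals")
        if len(self.sample_ids) != self.sample_population.size:
            raise ValueError("one population label per individual required")
        if self.haplotypes.size and self.haplotypes.max(initial=0) > 1:
            raise ValueError("haplotype entries must be 0/1")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("site positions must be strictly increasing")

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        return list(dict.fromkeys(self.sample_population))

    def haplotype_population(self) -> np.ndarray:
        """Population label of each haplotype row."""
        return np.repeat(self.sample_population, 2)

    def individuals_of(self, population: str) -> np.ndarray:
        return np.flatnonzero(self.sample_population == population)

    def freq(self) -> pd.DataFrame:
        """Realized per-population alt-allele frequencies (populations × sites)."""
        hap_pop = self.haplotype_population()
        rows = {pop: self.haplotypes[hap_pop == pop].mean(axis=0) for pop in self.populations}
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.positions)

    def subset_individuals(self, indices: Sequence[int]) -> "ReferencePanel":
        idx = np.asarray(indices, dtype=np.int64)
        hap_idx = np.ravel(np.column_stack((2 * idx, 2 * idx + 1)))
        return ReferencePanel(
            chromosome=self.chromosome,
            positions=self.positions.copy(),
            ref=np.asarray(self.ref).copy(),
            alt=np.asarray(self.alt).copy(),
            haplotypes=self.haplotypes[hap_idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            sample_population=self.sample_population[idx].copy(),
        )

    def write_vcf(self, path) -> None:
        from . import format_io

        format_io.write_phased_vcf(
            path, self.chromosome, self.positions, self.ref, self.alt, self.sample_ids, self.haplotypes
        )

    def write_popmap(self, path) -> None:
        """Plain-text population map: sample_id<TAB>population."""
        with open(path, "w") as fh:
            for sid, pop in zip(self.sample_ids, self.sample_population):
                fh.write(f"{sid}\t{pop}\n")


def _balding_nichols_freqs(ancestral: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    if f < 1e-9:  # no-drift limit: Beta concentrates on the ancestral frequency
        return ancestral.copy()
    scale = (1.0 - f) / f
    return rng.beta(ancestral * scale, (1.0 - ancestral) * scale)


def simulate_panels(
    specs: Sequence[PopulationSpec],
    n_sites: int,
    gmap: GeneticMap,
    seed: int,
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95),
) -> ReferencePanel:
    """Simulate phased reference panels for all populations on one site set.

    Sites are placed uniformly (without replacement) over the genetic map's
    physical span. Sites left monomorphic across every population after the
    haplotype draw are redrawn, so every emitted site is usable downstream.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("specs must be non-empty")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate population names in specs")
    n_sites = int(n_sites)
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    lo, hi = gmap.span_bp
    if hi - lo + 1 < n_sites:
        raise ValueError("map span too short for the requested number of sites")

    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(np.arange(lo, hi + 1, dtype=np.int64), size=n_sites, replace=False))

    n_haps = np.array([2 * s.n_individuals for s in specs])
    hap_slices = np.concatenate(([0], np.cumsum(n_haps)))
    haplotypes = np.zeros((int(n_haps.sum()), n_sites), dtype=np.uint8)

    todo = np.arange(n_sites)
    while todo.size:
        ancestral = rng.uniform(*ancestral_freq_range, size=todo.size)
        for k, spec in enumerate(specs):
            pf = _balding_nichols_freqs(ancestral, float(spec.differentiation), rng)
            draws = rng.random((n_haps[k], todo.size)) < pf
            haplotypes[hap_slices[k]:hap_slices[k + 1], todo] = draws
        col = haplotypes[:, todo]
        todo = todo[(col.min(axis=0) == col.max(axis=0))]  # redraw monomorphic sites

    sample_ids = [f"{s.name}_{i}" for s in specs for i in range(s.n_individuals)]
    sample_population = np.array([s.name for s in specs for _ in range(s.n_individuals)], dtype=object)
    return ReferencePanel(
        chromosome=gmap.chromosome,
        positions=positions,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        haplotypes=haplotypes,
        sample_ids=sample_ids,
        sample_population=sample_population,
    )
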