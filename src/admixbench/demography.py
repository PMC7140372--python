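"""Continuous-migration demographic models for admixed populations.

A :class:`MigrationSchedule` holds the per-generation, per-ancestry migrant
replacement fractions ``m_k(t)`` for t = 1..G. Generation t = 1 is the
founding generation (entirely migrants, so its row sums to 1) and t = G is
the present. Under the copying model implemented by
:mod:`admixbench.simulator`, the expected ancestry proportion of ancestry k
follows the recursion

    a_k(1) = m_k(1)
    a_k(t) = (1 − Σ_j m_j(t)) · a_k(t−1) + m_k(t)

which :func:`expected_proportions` evaluates in closed form.

The flagship scenario is a five-way admixed population (the South African
Coloured population: Bantu-speaking African, KhoeSan, European, East Asian
and South East Asian contributions) whose admixture began roughly fifteen
generations ago under continuous migration. The exact per-generation
migration fractions of that published model are not redistributable here, so
:func:`default_sac_schedule` falls back to a single founding pulse at the
previously reported proportions (32/30/19/7/12 %), G = 15.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MigrationSchedule",
    "expected_proportions",
    "load_schedule",
    "save_schedule",
    "default_sac_schedule",
    "SAC_ANCESTRIES",
    "SAC_FOUNDING_PROPORTIONS",
]

SAC_ANCESTRIES: tuple[str, ...] = ("Bantu", "KhoeSan", "European", "EastAsian", "SouthEastAsian")
SAC_FOUNDING_PROPORTIONS: tuple[float, ...] = (0.32, 0.30, 0.19, 0.07, 0.12)

_FOUNDING_TOL = 1e-9


@dataclass(frozen=True)
class MigrationSchedule:
    """Per-generation, per-ancestry replacement fractions m_k(t), t = 1..G."""

    ancestries: tuple[str, ...]
    m: np.ndarray = field(repr=False)  # shape (G, K)

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=np.float64)
        object.__setattr__(self, "ancestries", tuple(self.ancestries))
        object.__setattr__(self, "m", m)
        if m.ndim != 2 or m.shape[1] != len(self.ancestries):
            raise ValueError("m must be a (generations × ancestries) table")
        if m.shape[0] < 1:
            raise ValueError("schedule needs at least the founding generation")
        if len(set(self.ancestries)) != len(self.ancestries):
            raise ValueError("duplicate ancestry labels")
        if np.any(m < 0):
            t, k = np.argwhere(m < 0)[0]
            raise ValueError(f"negative migration fraction at generation {t + 1}, ancestry {self.ancestries[k]!r}")
        row_sums = m.sum(axis=1)
        if abs(row_sums[0] - 1.0) > _FOUNDING_TOL:
            raise ValueError(f"founding generation 1 must sum to 1 (got {row_sums[0]:.6g})")
        bad = np.flatnonzero(row_sums > 1.0 + _FOUNDING_TOL)
        if bad.size:
            raise ValueError(f"migration fractions at generation {bad[0] + 1} sum to {row_sums[bad[0]]:.6g} > 1")

    @property
    def generations(self) -> int:
        return int(self.m.shape[0])

    @property
    def n_ancestries(self) -> int:
        return len(self.ancestries)


def expected_proportions(schedule: MigrationSchedule) -> np.ndarray:
    """Closed-form expected final ancestry proportions a_k(G)."""
    a = schedule.m[0].copy()
    for t in range(1, schedule.generations):
        row = schedule.m[t]
        a = (1.0 - row.sum()) * a + row
    return a


def default_sac_schedule(generations: int = 15) -> MigrationSchedule:
    """Five-way schedule: single founding pulse at the previously reported
    proportions, followed by ``generations − 1`` migration-free generations."""
    if generations < 1:
        raise ValueError("generations must be >= 1")
    m = np.zeros((generations, len(SAC_ANCESTRIES)))
    m[0] = SAC_FOUNDING_PROPORTIONS
    return MigrationSchedule(ancestries=SAC_ANCESTRIES, m=m)


def save_schedule(schedule: MigrationSchedule, path) -> None:
    """Write a schedule as a TSV: generation column then one column per ancestry.

    Fractions are written as full-precision reprs so save/load round-trips
    bit-exactly.
    """
    with open(path, "w") as fh:
        fh.write("generation\t" + "\t".join(schedule.ancestries) + "\n")
        for t in range(schedule.generations):
            cells = "\t".join(repr(float(v)) for v in schedule.m[t])
            fh.write(f"{t + 1}\t{cells}\n")


def load_schedule(path) -> MigrationSchedule:
    """Read a TSV schedule written by :func:`save_schedule`.

    Validation errors name the offending generation row.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "generation":
            raise ValueError("schedule file must start with a 'generation' header column")
        ancestries = tuple(header[1:])
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(ancestries) + 1:
                raise ValueError(f"line {lineno}: expected {len(ancestries) + 1} columns, got {len(cells)}")
            t = int(cells[0])
            if t != len(rows) + 1:
                raise ValueError(f"line {lineno}: generations must run 1..G in order (got {t})")
            rows.append([float(v) for v in cells[1:]])
    if not rows:
        raise ValueError("schedule file has no generation rows")
    return MigrationSchedule(ancestries=ancestries, m=np.array(rows))
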