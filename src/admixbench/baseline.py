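"""A deliberately simple reference-frequency local-ancestry caller.

This is harness plumbing, not a competitive method: for each genetic-distance
window and each haplotype it assigns the ancestry maximising the sum over the
window's sites of ``log f_k`` (allele 1) or ``log(1 − f_k)`` (allele 0),
where ``f_k`` are pseudocount-smoothed alt-allele frequencies estimated from
a holdout reference panel. It exists so the full simulate → call → evaluate
loop runs without external inference tools, and emits the same windowed call
format those tools produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .format_io import LocalAncestryCalls, windows_from_map
from .genetic_map import GeneticMap
from .synthetic_reference import ReferencePanel

__all__ = ["CallerModel", "fit_caller", "call_local_ancestry"]


@dataclass
class CallerModel:
    """Smoothed per-population allele frequencies plus the window size."""

    populations: tuple[str, ...]
    site_positions: np.ndarray = field(repr=False)
    freq: np.ndarray = field(repr=False)  # (K × sites), strictly inside (0, 1)
    window_cm: float = 0.2

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=np.float64)
        self.site_positions = np.asarray(self.site_positions, dtype=np.int64)
        if self.window_cm <= 0:
            raise ValueError("window_cm must be positive")
        if self.freq.shape != (len(self.populations), self.site_positions.size):
            raise ValueError("freq must be (populations × sites)")
        if np.any(self.freq <= 0) or np.any(self.freq >= 1):
            raise ValueError("smoothed frequencies must lie strictly inside (0, 1)")


def fit_caller(panel: ReferencePanel, window_cm: float = 0.2, pseudocount: float = 0.5) -> CallerModel:
    """Estimate smoothed frequencies from a reference panel.

    With ``c`` the pseudocount and ``n_k`` individuals in population k,
    ``f_k = (alt count + c) / (2 n_k + 2c)``, so the floor frequency is about
    ``c / (2 n_k)``.
    """
    pops = tuple(panel.populations)
    hap_pop = panel.haplotype_population()
    freq = np.empty((len(pops), panel.n_sites))
    for i, pop in enumerate(pops):
        rows = panel.haplotypes[hap_pop == pop]
        freq[i] = (rows.sum(axis=0) + pseudocount) / (rows.shape[0] + 2 * pseudocount)
    return CallerModel(populations=pops, site_positions=panel.positions.copy(), freq=freq, window_cm=window_cm)


def call_local_ancestry(
    haplotypes: np.ndarray,
    model: CallerModel,
    gmap: GeneticMap,
    haplotype_ids: list[str] | None = None,
    chrom_start: float = 0.0,
    chrom_end: float | None = None,
) -> LocalAncestryCalls:
    """Window-wise maximum-likelihood ancestry calls for phased haplotypes.

    Ties break toward the lower ancestry code and are counted in
    ``tie_count``; a window containing zero sites inherits the previous
    window's call (the first such window falls back to code 0).
    """
    haplotypes = np.asarray(haplotypes, dtype=np.uint8)
    if haplotypes.ndim != 2 or haplotypes.shape[1] != model.site_positions.size:
        raise ValueError("haplotypes must be (n_haplotypes × model sites)")
    spos, epos, sgpos, egpos, n_snps = windows_from_map(
        gmap, model.window_cm, model.site_positions, chrom_start, chrom_end
    )
    x = haplotypes.T.astype(np.float64)  # sites × haps
    slope = np.log(model.freq) - np.log1p(-model.freq)  # K × sites
    base = np.log1p(-model.freq)
    k = len(model.populations)
    n_hap = haplotypes.shape[0]
    calls = np.empty((spos.size, n_hap), dtype=np.int16)
    ties = 0
    lo = np.searchsorted(model.site_positions, spos)
    hi = np.searchsorted(model.site_positions, epos)
    prev = np.zeros(n_hap, dtype=np.int16)
    for w in range(spos.size):
        if hi[w] == lo[w]:
            calls[w] = prev
            continue
        score = slope[:, lo[w]:hi[w]] @ x[lo[w]:hi[w]] + base[:, lo[w]:hi[w]].sum(axis=1)[:, None]
        best = score.argmax(axis=0).astype(np.int16)
        ties += int(((score == score.max(axis=0)).sum(axis=0) > 1).sum())
        calls[w] = best
        prev = best
    if haplotype_ids is None:
        haplotype_ids = [f"hap{j}" for j in range(n_hap)]
    return LocalAncestryCalls(
        chromosome=gmap.chromosome,
        spos=spos,
        epos=epos,
        sgpos=sgpos,
        egpos=egpos,
        n_snps=n_snps,
        haplotype_ids=list(haplotype_ids),
        calls=calls,
        code_map={i: p for i, p in enumerate(model.populations)},
        tie_count=ties,
    )
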