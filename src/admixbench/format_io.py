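"""Readers and writers for ancestry-inference interchange formats.

Supported formats:

* ADMIXTURE ``.Q`` matrices (whitespace-separated, K columns, no header);
* RFMix local-ancestry output, both the windowed ``msp.tsv`` dialect
  (v2: subpopulation-code comment, ``#chm spos epos sgpos egpos n snps``
  header, per-haplotype columns) and the per-SNP Viterbi dialect (v1),
  auto-detected by header sniffing — per-SNP calls are represented
  internally as single-SNP windows;
* phased VCF (``GT`` with ``|`` separator), read through cyvcf2;
* BED-like ground-truth tract tables and HapMap-style genetic maps
  (see :mod:`admixbench.genetic_map`).

Readers reject malformed input rather than coercing it; writers round-trip
bit-exactly through their readers at the stated print precision. The code
``-1`` is reserved for "no call" in call matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_map import GeneticMap, read_hapmap_map, write_hapmap_map  # noqa: F401

__all__ = [
    "GlobalAncestryMatrix",
    "LocalAncestryCalls",
    "read_q_matrix",
    "write_q_matrix",
    "read_rfmix_calls",
    "read_msp",
    "write_msp",
    "read_viterbi",
    "global_from_local",
    "windows_from_map",
    "write_truth_as_calls",
    "write_phased_vcf",
    "read_phased_vcf",
    "read_tracts_bed",
]

MISSING_CODE = -1
_Q_ROW_SUM_TOL = 1e-4


@dataclass
class GlobalAncestryMatrix:
    """Individuals × K ancestry-proportion estimates (a Q matrix).

    ``ancestries`` may be real population labels or anonymous cluster names
    (e.g. from an unsupervised run); cluster→ancestry resolution is the
    evaluation module's job, not the reader's.
    """

    sample_ids: list[str]
    ancestries: list[str]
    proportions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=np.float64)
        if p.ndim != 2 or p.shape != (len(self.sample_ids), len(self.ancestries)):
            raise ValueError("proportions must be (n_samples × n_ancestries)")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("proportions must lie in [0, 1]")
        bad = np.flatnonzero(np.abs(p.sum(axis=1) - 1.0) > _Q_ROW_SUM_TOL)
        if bad.size:
            raise ValueError(f"row {bad[0] + 1} of Q matrix sums to {p[bad[0]].sum():.6g}, not 1")
        self.proportions = p

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.sample_ids, columns=self.ancestries)


def read_q_matrix(path, sample_ids=None, ancestries=None) -> GlobalAncestryMatrix:
    """Read an ADMIXTURE-style .Q file (whitespace-separated, no header).

    ``sample_ids`` must match the row count when given; anonymous cluster
    labels ``cluster0..cluster{K-1}`` are used when ``ancestries`` is None.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rows.append([float(v) for v in line.split()])
    if not rows:
        raise ValueError(f"empty Q file: {path}")
    k = len(rows[0])
    if any(len(r) != k for r in rows):
        raise ValueError("ragged Q file: inconsistent column counts")
    if sample_ids is not None and len(sample_ids) != len(rows):
        raise ValueError(f"Q file has {len(rows)} rows but {len(sample_ids)} sample ids were given")
    sample_ids = list(sample_ids) if sample_ids is not None else [f"sample{i}" for i in range(len(rows))]
    ancestries = list(ancestries) if ancestries is not None else [f"cluster{j}" for j in range(k)]
    return GlobalAncestryMatrix(sample_ids=sample_ids, ancestries=ancestries, proportions=np.array(rows))


def write_q_matrix(gam: GlobalAncestryMatrix, path, precision: int = 6) -> None:
    with open(path, "w") as fh:
        for row in gam.proportions:
            fh.write(" ".join(f"{v:.{precision}f}" for v in row) + "\n")


@dataclass
class LocalAncestryCalls:
    """Windowed local-ancestry calls for a set of haplotypes.

    Windows are half-open ``[spos, epos)``, sorted and non-overlapping.
    ``calls`` is a windows × haplotypes matrix of integer ancestry codes;
    ``code_map`` maps each code to its ancestry label. Haplotype columns
    pair into individuals as (2i, 2i+1).
    """

    chromosome: str
    spos: np.ndarray = field(repr=False)
    epos: np.ndarray = field(repr=False)
    sgpos: np.ndarray = field(repr=False)
    egpos: np.ndarray = field(repr=False)
    n_snps: np.ndarray = field(repr=False)
    haplotype_ids: list[str] = field(repr=False, default=None)
    calls: np.ndarray = field(repr=False, default=None)
    code_map: dict[int, str] = field(default=None)
    tie_count: int = 0

    def __post_init__(self) -> None:
        for name in ("spos", "epos", "n_snps"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        for name in ("sgpos", "egpos"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        self.calls = np.asarray(self.calls, dtype=np.int16)
        w = self.spos.size
        if not (self.epos.size == self.sgpos.size == self.egpos.size == self.n_snps.size == w):
            raise ValueError("window coordinate arrays must have equal length")
        if w == 0:
            raise ValueError("at least one window is required")
        if np.any(self.spos >= self.epos):
            raise ValueError("windows must satisfy spos < epos")
        if np.any(self.spos[1:] < self.epos[:-1]):
            raise ValueError("windows must be sorted and non-overlapping")
        if self.calls.shape != (w, len(self.haplotype_ids)):
            raise ValueError("calls must be (windows × haplotypes)")
        present = set(np.unique(self.calls).tolist()) - {MISSING_CODE}
        undeclared = present - set(self.code_map)
        if undeclared:
            raise ValueError(f"call codes missing from code_map: {sorted(undeclared)}")

    @property
    def n_windows(self) -> int:
        return int(self.spos.size)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    def ancestries(self) -> list[str]:
        return [self.code_map[c] for c in sorted(self.code_map)]

    def windows_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "spos": self.spos,
                "epos": self.epos,
                "sgpos": self.sgpos,
                "egpos": self.egpos,
                "n_snps": self.n_snps,
            }
        )


def write_msp(calls: LocalAncestryCalls, path) -> None:
    """Write the RFMix-v2 msp.tsv dialect."""
    codes = ", ".join(f"{calls.code_map[c]}={c}" for c in sorted(calls.code_map))
    with open(path, "w") as fh:
        fh.write(f"#Subpopulation order/codes: {codes}\n")
        fh.write("#chm\tspos\tepos\tsgpos\tegpos\tn snps\t" + "\t".join(calls.haplotype_ids) + "\n")
        for w in range(calls.n_windows):
            row = [
                calls.chromosome,
                str(calls.spos[w]),
                str(calls.epos[w]),
                f"{calls.sgpos[w]:.6f}",
                f"{calls.egpos[w]:.6f}",
                str(calls.n_snps[w]),
            ] + [str(int(c)) for c in calls.calls[w]]
            fh.write("\t".join(row) + "\n")


def read_msp(path) -> LocalAncestryCalls:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#Subpopulation"):
            raise ValueError("not an msp file: missing subpopulation code line")
        code_map: dict[int, str] = {}
        for part in first.split(":", 1)[1].replace(",", "\t").split("\t"):
            part = part.strip()
            if part:
                label, code = part.rsplit("=", 1)
                code_map[int(code)] = label.strip()
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 7 or header[0] != "#chm":
            raise ValueError("not an msp file: malformed column header")
        hap_ids = header[6:]
        chroms, spos, epos, sgpos, egpos, n_snps, rows = [], [], [], [], [], [], []
        for line in fh:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 6 + len(hap_ids):
                raise ValueError("msp row has wrong number of columns")
            chroms.append(cells[0])
            spos.append(int(cells[1]))
            epos.append(int(cells[2]))
            sgpos.append(float(cells[3]))
            egpos.append(float(cells[4]))
            n_snps.append(int(cells[5]))
            rows.append([int(v) for v in cells[6:]])
    if not rows:
        raise ValueError("msp file has no call rows")
    if len(set(chroms)) != 1:
        raise ValueError("expected a single-chromosome msp file")
    return LocalAncestryCalls(
        chromosome=chroms[0],
        spos=np.array(spos),
        epos=np.array(epos),
        sgpos=np.array(sgpos),
        egpos=np.array(egpos),
        n_snps=np.array(n_snps),
        haplotype_ids=hap_ids,
        calls=np.array(rows),
        code_map=code_map,
    )


def read_viterbi(path, positions=None, code_map=None, chromosome: str = "1") -> LocalAncestryCalls:
    """Read the RFMix-v1 per-SNP Viterbi dialect (whitespace code matrix).

    v1 codes are 1-based; they are shifted to 0-based internally. Each SNP
    becomes a single-SNP window; physical coordinates come from ``positions``
    when given, otherwise SNP indices are used.
    """
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rows.append([int(v) - 1 for v in line.split()])
    if not rows:
        raise ValueError(f"empty Viterbi file: {path}")
    calls = np.array(rows)
    n_snp, n_hap = calls.shape
    if positions is None:
        spos = np.arange(n_snp, dtype=np.int64)
    else:
        spos = np.asarray(positions, dtype=np.int64)
        if spos.size != n_snp:
            raise ValueError("positions length must match the number of SNP rows")
    epos = spos + 1
    if code_map is None:
        code_map = {int(c): f"pop{int(c)}" for c in np.unique(calls) if c != MISSING_CODE}
    return LocalAncestryCalls(
        chromosome=chromosome,
        spos=spos,
        epos=epos,
        sgpos=spos.astype(float),
        egpos=epos.astype(float),
        n_snps=np.ones(n_snp, dtype=np.int64),
        haplotype_ids=[f"hap{j}" for j in range(n_hap)],
        calls=calls,
        code_map=dict(code_map),
    )


def read_rfmix_calls(path, **kwargs) -> LocalAncestryCalls:
    """Auto-detect msp vs Viterbi dialect by header sniffing and read it."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        return read_msp(path)
    return read_viterbi(path, **kwargs)


def _window_weights(calls: LocalAncestryCalls, weighting: str) -> np.ndarray:
    if weighting == "snp-count":
        return calls.n_snps.astype(float)
    if weighting == "genetic":
        return calls.egpos - calls.sgpos
    if weighting == "physical":
        return (calls.epos - calls.spos).astype(float)
    raise ValueError(f"unknown weighting {weighting!r}; expected snp-count, genetic or physical")


def global_from_local(calls: LocalAncestryCalls, weighting: str = "snp-count") -> GlobalAncestryMatrix:
    """Length-weighted average of local calls per individual → Q matrix.

    Haplotype columns (2i, 2i+1) are pooled per individual; windows with the
    no-call code are excluded from both numerator and denominator.
    """
    if calls.n_haplotypes % 2:
        raise ValueError("odd haplotype count: columns must pair into individuals")
    weights = _window_weights(calls, weighting)
    codes = sorted(calls.code_map)
    n_ind = calls.n_haplotypes // 2
    totals = np.zeros((n_ind, len(codes)))
    for ci, code in enumerate(codes):
        mask = calls.calls == code
        per_hap = weights @ mask  # total weight called `code` per haplotype
        totals[:, ci] = per_hap[0::2] + per_hap[1::2]
    denom = totals.sum(axis=1, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("individual with zero called windows")
    sample_ids = [hid.rsplit(".", 1)[0] for hid in calls.haplotype_ids[0::2]]
    return GlobalAncestryMatrix(
        sample_ids=sample_ids,
        ancestries=[calls.code_map[c] for c in codes],
        proportions=totals / denom,
    )


def windows_from_map(gmap: GeneticMap, window_cm: float, site_positions, chrom_start: float = 0.0, chrom_end: float | None = None):
    """Uniform-in-cM window grid over a chromosome.

    Returns ``(spos, epos, sgpos, egpos, n_snps)``; boundaries are placed at
    multiples of ``window_cm`` along the cumulative map and converted to bp by
    inverse interpolation. On a zero-cM map the whole chromosome is a single
    window.
    """
    if window_cm <= 0:
        raise ValueError("window_cm must be positive")
    pos = np.asarray(site_positions, dtype=np.int64)
    if chrom_end is None:
        chrom_end = float(gmap.length_bp) + 1.0
    total = gmap.total_cm
    n_win = max(1, int(np.ceil(total / window_cm - 1e-9)))
    cm_edges = gmap.cumulative_cm[0] + np.arange(1, n_win) * window_cm
    inner = np.round(np.asarray(gmap.bp_at(cm_edges), dtype=float)).astype(np.int64) if n_win > 1 else np.array([], dtype=np.int64)
    edges = np.concatenate(([int(chrom_start)], inner, [int(chrom_end)]))
    if np.any(np.diff(edges) <= 0):  # collapse empty-bp windows
        edges = np.unique(edges)
    spos, epos = edges[:-1], edges[1:]
    sgpos = np.asarray(gmap.cm_at(spos), dtype=float)
    egpos = np.asarray(gmap.cm_at(epos), dtype=float)
    n_snps = np.searchsorted(pos, epos) - np.searchsorted(pos, spos)
    return spos, epos, sgpos, egpos, n_snps


def write_truth_as_calls(cohort, windows) -> LocalAncestryCalls:
    """Project a cohort's exact truth tracts onto a window grid.

    ``windows`` is an existing :class:`LocalAncestryCalls` (its grid is
    reused) or a ``(spos, epos, sgpos, egpos, n_snps)`` tuple from
    :func:`windows_from_map`. Each window/haplotype is assigned the ancestry
    covering the majority of the window's genetic length (physical length on
    a zero-cM map); exact ties break to the lower ancestry code and are
    counted in ``tie_count``.
    """
    if isinstance(windows, LocalAncestryCalls):
        grid = (windows.spos, windows.epos, windows.sgpos, windows.egpos, windows.n_snps)
    else:
        grid = windows
    spos, epos, sgpos, egpos, n_snps = (np.asarray(a) for a in grid)
    k = len(cohort.ancestries)
    n_hap = len(cohort.tract_bounds)
    calls = np.empty((spos.size, n_hap), dtype=np.int16)
    ties = 0
    use_genetic = cohort.gmap.total_cm > 0
    for h in range(n_hap):
        bounds = cohort.tract_bounds[h]
        anc = cohort.tract_anc[h]
        starts = np.concatenate(([cohort.chrom_start], bounds[:-1]))
        for w in range(spos.size):
            a, b = float(spos[w]), float(epos[w])
            i0 = int(np.searchsorted(bounds, a, side="right"))
            cover = np.zeros(k)
            i = i0
            while i < bounds.size and starts[i] < b:
                lo, hi = max(float(starts[i]), a), min(float(bounds[i]), b)
                if hi > lo:
                    if use_genetic:
                        cover[anc[i]] += cohort.gmap.cm_at(hi) - cohort.gmap.cm_at(lo)
                    else:
                        cover[anc[i]] += hi - lo
                i += 1
            best = int(np.argmax(cover))  # argmax takes the lowest index on ties
            if np.sum(cover == cover[best]) > 1:
                ties += 1
            calls[w, h] = best
    return LocalAncestryCalls(
        chromosome=cohort.chromosome,
        spos=spos,
        epos=epos,
        sgpos=sgpos,
        egpos=egpos,
        n_snps=n_snps,
        haplotype_ids=cohort.haplotype_ids(),
        calls=calls,
        code_map={i: a for i, a in enumerate(cohort.ancestries)},
        tie_count=ties,
    )


def write_phased_vcf(path, chromosome, positions, ref, alt, sample_ids, haplotypes) -> None:
    """Write a minimal phased VCF (GT only, '|' separator, 1-based positions)."""
    haplotypes = np.asarray(haplotypes, dtype=np.uint8)
    positions = np.asarray(positions, dtype=np.int64)
    if haplotypes.shape != (2 * len(sample_ids), positions.size):
        raise ValueError("haplotypes must be (2·n_samples × n_sites)")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chromosome}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for s in range(positions.size):
            gts = "\t".join(
                f"{haplotypes[2 * i, s]}|{haplotypes[2 * i + 1, s]}" for i in range(len(sample_ids))
            )
            fh.write(f"{chromosome}\t{positions[s]}\t.\t{ref[s]}\t{alt[s]}\t.\t.\t.\tGT\t{gts}\n")


def read_phased_vcf(path):
    """Read a phased single-chromosome VCF via cyvcf2.

    Returns ``(chromosome, positions, ref, alt, sample_ids, haplotypes)``;
    unphased heterozygotes are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    chroms, positions, ref, alt, haps = [], [], [], [], []
    for var in vcf:
        chroms.append(var.CHROM)
        positions.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0] if var.ALT else ".")
        col = np.empty(2 * len(sample_ids), dtype=np.uint8)
        for i, (a0, a1, phased) in enumerate(var.genotypes):
            if a0 != a1 and not phased:
                raise ValueError(f"unphased heterozygote at {var.CHROM}:{var.POS}, sample {sample_ids[i]}")
            col[2 * i], col[2 * i + 1] = a0, a1
        haps.append(col)
    vcf.close()
    if not positions:
        raise ValueError(f"no variants in VCF: {path}")
    if len(set(chroms)) != 1:
        raise ValueError("expected a single-chromosome VCF")
    return chroms[0], np.array(positions, dtype=np.int64), np.array(ref, dtype=object), np.array(alt, dtype=object), sample_ids, np.column_stack(haps)


def read_tracts_bed(path) -> pd.DataFrame:
    """Read a BED-like truth-tract table (chrom, start, end, haplotype_id, ancestry)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start_bp", "end_bp", "haplotype_id", "ancestry"],
        dtype={"start_bp": np.int64, "end_bp": np.int64},
    )
    if df.empty:
        raise ValueError(f"empty tract file: {path}")
    return df
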