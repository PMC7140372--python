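"""End-to-end orchestration: panels → split → simulate → filter → call → score.

The pipeline mirrors the benchmark workflow: generate (or load) reference
panels, split off founders for the simulation and a holdout reference set,
forward-simulate the admixed cohort with ground-truth tracts, apply the QC
and LD filters, run the bundled baseline caller and/or ingest externally
produced inference output (ADMIXTURE Q files, RFMix call files — external
tools are never invoked), and score everything against the simulated truth.
Every stage writes its artefacts into the run directory and is a pure
function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import baseline, evaluation, format_io, preprocess, simulator
from .demography import MigrationSchedule, default_sac_schedule, load_schedule, save_schedule
from .genetic_map import make_genetic_map, write_hapmap_map
from .preprocess import FilterSettings
from .synthetic_reference import SAC_POPULATION_SPECS, PopulationSpec, simulate_panels

__all__ = ["RunConfig", "validate_config", "run_pipeline", "load_config"]

log = logging.getLogger("admixbench.pipeline")


@dataclass(frozen=True)
class RunConfig:
    seed: int
    workdir: str
    population_specs: tuple[PopulationSpec, ...] = SAC_POPULATION_SPECS
    chromosome_length_bp: int = 50_000_000
    total_cm: float = 50.0
    map_points: int = 200
    n_sites: int = 5_000
    n_founders_per_pop: int = 11
    schedule: MigrationSchedule | None = None  # None → bundled default (G = 15)
    pop_size: int = 1_000
    n_out: int = 100
    filters: FilterSettings = field(default_factory=FilterSettings)
    window_cm: float = 0.2
    weighting: str = "snp-count"
    external_q: str | None = None
    external_calls: str | None = None
    run_baseline: bool = True


def validate_config(config: RunConfig) -> list[str]:
    """Validate a config, reporting every violation at once (empty list = valid)."""
    errors: list[str] = []
    if config.seed is None:
        errors.append("seed: a seed is mandatory")
    if not config.workdir:
        errors.append("workdir: a working directory is required")
    if config.pop_size < 2:
        errors.append("pop_size: must be >= 2")
    if not (1 <= config.n_out <= config.pop_size):
        errors.append("n_out: must satisfy 1 <= n_out <= pop_size")
    if config.n_sites < 1:
        errors.append("n_sites: must be >= 1")
    if config.total_cm < 0:
        errors.append("total_cm: must be >= 0")
    if config.window_cm <= 0:
        errors.append("window_cm: must be positive")
    if config.weighting not in ("snp-count", "genetic", "physical"):
        errors.append(f"weighting: unknown value {config.weighting!r}")
    names = [s.name for s in config.population_specs]
    if len(set(names)) != len(names):
        errors.append("population_specs: duplicate population names")
    for s in config.population_specs:
        if s.n_individuals <= config.n_founders_per_pop:
            errors.append(
                f"population_specs: {s.name!r} has {s.n_individuals} individuals, "
                f"needs more than n_founders_per_pop={config.n_founders_per_pop}"
            )
    schedule = config.schedule or default_sac_schedule()
    missing = [a for a in schedule.ancestries if a not in names]
    if missing:
        errors.append(f"schedule: ancestries {missing} not present among population specs")
    for path_field in ("external_q", "external_calls"):
        p = getattr(config, path_field)
        if p is not None and not Path(p).exists():
            errors.append(f"{path_field}: file not found: {p}")
    return errors


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (keys mirror the dataclass fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "population_specs" in raw:
        raw["population_specs"] = tuple(
            PopulationSpec(p["name"], int(p["n_individuals"]), float(p["differentiation"]))
            for p in raw["population_specs"]
        )
    if "filters" in raw:
        raw["filters"] = FilterSettings(**raw["filters"])
    if "schedule" in raw and raw["schedule"] is not None:
        raw["schedule"] = load_schedule(raw["schedule"])
    return RunConfig(**raw)


def _stage_seeds(seed: int, n: int = 6) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _config_hash(config: RunConfig) -> str:
    schedule = config.schedule or default_sac_schedule()
    payload = {
        k: v
        for k, v in {
            **{f: getattr(config, f) for f in (
                "seed", "chromosome_length_bp", "total_cm", "map_points", "n_sites",
                "n_founders_per_pop", "pop_size", "n_out", "window_cm", "weighting",
            )},
            "populations": [(s.name, s.n_individuals, s.differentiation) for s in config.population_specs],
            "filters": vars(config.filters),
            "schedule": schedule.m.tolist(),
        }.items()
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the run directory.

    Any stage failure raises a RuntimeError naming the stage; artefacts of
    completed stages are preserved in the run directory.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    out = Path(config.workdir)
    out.mkdir(parents=True, exist_ok=True)
    schedule = config.schedule or default_sac_schedule()
    seeds = _stage_seeds(config.seed)
    stage = "setup"
    t0 = time.time()
    try:
        stage = "simulate-panels"
        gmap = make_genetic_map(config.chromosome_length_bp, config.total_cm, config.map_points, seeds[0])
        panel = simulate_panels(config.population_specs, config.n_sites, gmap, seeds[1])
        write_hapmap_map(gmap, out / "genetic_map.txt")
        panel.write_vcf(out / "reference_panel.vcf")
        panel.write_popmap(out / "reference_panel.popmap.txt")
        save_schedule(schedule, out / "schedule.tsv")
        log.info("%s: %d sites, %d individuals", stage, panel.n_sites, panel.n_individuals)

        stage = "split-reference"
        founders, holdout = simulator.split_reference(panel, config.n_founders_per_pop, seeds[2])
        founders.write_popmap(out / "founders.popmap.txt")
        holdout.write_popmap(out / "holdout.popmap.txt")
        log.info("%s: %d founders / %d holdout", stage, founders.n_individuals, holdout.n_individuals)

        stage = "simulate-cohort"
        cohort = simulator.simulate_cohort(
            founders, schedule, gmap, n_out=config.n_out, pop_size=config.pop_size, seed=seeds[3]
        )
        cohort.write_vcf(out / "cohort.vcf")
        cohort.write_tracts(out / "truth_tracts.bed")
        cohort.write_true_global(out / "true_global.tsv")
        log.info("%s: %d individuals, %d truth tracts", stage, cohort.n_individuals,
                 sum(b.size for b in cohort.tract_bounds))

        stage = "preprocess"
        dosages = (cohort.haplotypes[0::2] + cohort.haplotypes[1::2]).T.astype(float)  # sites × individuals
        kept_sites, kept_indiv, qc_report = preprocess.qc_filter(dosages, config.filters)
        pruned = preprocess.ld_prune(dosages[kept_sites], cohort.positions[kept_sites], config.filters)
        np.savetxt(out / "kept_sites.txt", cohort.positions[kept_sites], fmt="%d")
        np.savetxt(out / "pruned_sites.txt", cohort.positions[kept_sites][pruned], fmt="%d")
        with open(out / "qc_report.json", "w") as fh:
            json.dump(vars(qc_report) | {"sites_after_ld_prune": int(pruned.size)}, fh, indent=2)
        log.info("%s: %d/%d sites kept, %d after LD pruning", stage, kept_sites.size, cohort.n_sites, pruned.size)

        stage = "truth-projection"
        windows = format_io.windows_from_map(
            gmap, config.window_cm, cohort.positions[kept_sites], cohort.chrom_start, cohort.chrom_end
        )
        truth_calls = format_io.write_truth_as_calls(cohort, windows)
        format_io.write_msp(truth_calls, out / "truth_calls.msp.tsv")

        reports: dict[str, evaluation.AccuracyReport] = {}
        truth_q = cohort.true_global_dataframe()

        if config.run_baseline:
            stage = "baseline-call"
            holdout_kept = replace_sites(holdout, kept_sites)
            model = baseline.fit_caller(holdout_kept, window_cm=config.window_cm)
            # keep the model's populations aligned with the cohort's ancestry order
            order = [model.populations.index(a) for a in cohort.ancestries]
            model = baseline.CallerModel(
                populations=tuple(cohort.ancestries),
                site_positions=model.site_positions,
                freq=model.freq[order],
                window_cm=model.window_cm,
            )
            calls = baseline.call_local_ancestry(
                cohort.haplotypes[:, kept_sites], model, gmap,
                haplotype_ids=cohort.haplotype_ids(),
                chrom_start=cohort.chrom_start, chrom_end=cohort.chrom_end,
            )
            format_io.write_msp(calls, out / "baseline_calls.msp.tsv")
            stage = "evaluate-baseline"
            est_q = format_io.global_from_local(calls, weighting=config.weighting)
            reports["baseline"] = evaluation.build_report(
                est_q, truth_q, calls, truth_calls, weighting=config.weighting, seed=seeds[4]
            )

        if config.external_q is not None:
            stage = "evaluate-external-q"
            ext = format_io.read_q_matrix(config.external_q, sample_ids=cohort.sample_ids)
            matched, match = evaluation.match_clusters(ext, truth_q)
            rmse = evaluation.gai_rmse(matched, truth_q)
            rmse.to_csv(out / "external_q_rmse.tsv", sep="\t", header=["rmse"])
            log.info("%s: cluster assignment %s", stage, match.assignment)

        if config.external_calls is not None:
            stage = "evaluate-external-calls"
            ext_calls = format_io.read_rfmix_calls(config.external_calls)
            ext_truth = format_io.write_truth_as_calls(cohort, ext_calls)
            est_q = format_io.global_from_local(ext_calls, weighting=config.weighting)
            reports["external"] = evaluation.build_report(
                est_q, truth_q, ext_calls, ext_truth, weighting=config.weighting, seed=seeds[4]
            )

        stage = "report"
        for name, report in reports.items():
            report.write(out / f"evaluation_{name}")
        manifest = {
            "seed": int(config.seed),
            "config_hash": _config_hash(config),
            "stage_seeds": seeds,
            "n_individuals": cohort.n_individuals,
            "n_sites": int(cohort.n_sites),
            "n_sites_kept": int(kept_sites.size),
            "runtime_s": round(time.time() - t0, 3),
            "reports": sorted(reports),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return out


def replace_sites(panel, site_indices: Sequence[int]):
    """Restrict a reference panel to a subset of site indices."""
    idx = np.asarray(site_indices, dtype=np.int64)
    from .synthetic_reference import ReferencePanel

    return ReferencePanel(
        chromosome=panel.chromosome,
        positions=panel.positions[idx],
        ref=np.asarray(panel.ref)[idx],
        alt=np.asarray(panel.alt)[idx],
        haplotypes=panel.haplotypes[:, idx],
        sample_ids=list(panel.sample_ids),
        sample_population=panel.sample_population.copy(),
    )
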