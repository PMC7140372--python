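import numpy as np
import pytest

from admixbench import (
    PopulationSpec,
    simulate_cohort,
    simulate_panels,
    split_reference,
    true_global_from_tracts,
)
from admixbench.simulator import recombine

import helpers


# ---------------------------------------------------------------------------
# split_reference


def test_split_contract_on_flagship_sizes(flagship_world):
    founders, holdout = split_reference(flagship_world["panel"], 11, seed=0)
    assert founders.n_individuals == 55
    for pop in founders.populations:
        assert founders.individuals_of(pop).size == 11


def test_split_is_deterministic_and_disjoint(flagship_world):
    panel = flagship_world["panel"]
    f1, h1 = split_reference(panel, 3, seed=42)
    f2, h2 = split_reference(panel, 3, seed=42)
    assert f1.sample_ids == f2.sample_ids and h1.sample_ids == h2.sample_ids
    assert not set(f1.sample_ids) & set(h1.sample_ids)
    assert sorted(f1.sample_ids + h1.sample_ids) == sorted(panel.sample_ids)


def test_split_rejects_too_small_population():
    gmap = helpers.linear_map()
    panel = simulate_panels([PopulationSpec("Tiny", 3, 0.1)], 20, gmap, seed=0)
    with pytest.raises(ValueError, match="Tiny"):
        split_reference(panel, 3, seed=0)


# ---------------------------------------------------------------------------
# recombine


def _pure_hap(alleles, ancestry, chrom_end):
    return (
        np.asarray(alleles, dtype=np.uint8),
        np.array([chrom_end], dtype=float),
        np.array([ancestry], dtype=np.int16),
    )


def test_zero_cm_map_copies_one_whole_parent(rng):
    gmap = helpers.linear_map(1000, 0.0)
    pos = np.arange(1, 1001, 50)
    a = _pure_hap(np.zeros(pos.size), 0, 1001.0)
    b = _pure_hap(np.ones(pos.size), 1, 1001.0)
    for _ in range(10):
        al, bd, an = recombine(a, b, gmap, rng, pos, 0.0, 1001.0)
        assert an.size == 1
        assert al.tolist() in (a[0].tolist(), b[0].tolist())
        assert (al == a[0]).all() if an[0] == 0 else (al == b[0]).all()


def test_identical_ancestry_parents_yield_single_tract(rng):
    gmap = helpers.linear_map(1_000_000, 100.0)  # 1 Morgan: crossovers near-certain
    pos = np.arange(1, 1_000_001, 10_000)
    a = _pure_hap(np.zeros(pos.size), 2, 1_000_001.0)
    b = _pure_hap(np.ones(pos.size), 2, 1_000_001.0)
    for _ in range(20):
        _, bd, an = recombine(a, b, gmap, rng, pos, 0.0, 1_000_001.0)
        assert an.size == 1 and an[0] == 2  # tracts re-maximalized across crossovers


def test_crossover_count_is_poisson_one_on_one_morgan_map(rng):
    # 10,000 gametes on a 1-Morgan chromosome: mean breakpoint count within
    # 3 standard errors of 1.0 (distinct parental ancestries expose every
    # crossover as an ancestry switch)
    gmap = helpers.linear_map(1_000_000, 100.0)
    pos = np.array([1, 1_000_000])
    a = _pure_hap([0, 0], 0, 1_000_001.0)
    b = _pure_hap([1, 1], 1, 1_000_001.0)
    counts = np.empty(10_000)
    for i in range(counts.size):
        _, bd, _ = recombine(a, b, gmap, rng, pos, 0.0, 1_000_001.0)
        counts[i] = bd.size - 1
    se = counts.std(ddof=1) / np.sqrt(counts.size)
    assert abs(counts.mean() - 1.0) <= 3 * se


# ---------------------------------------------------------------------------
# simulate_cohort


def test_single_source_pulse_gives_pure_cohort(flagship_world):
    sched = helpers.pulse_schedule([1.0], extra_generations=4, ancestries=("KhoeSan",))
    cohort = simulate_cohort(flagship_world["founders"], sched, flagship_world["gmap"], n_out=10, pop_size=20, seed=0)
    assert all(an.size == 1 and an[0] == 0 for an in cohort.tract_anc)
    np.testing.assert_array_equal(cohort.true_global, np.ones((10, 1)))


def test_two_way_pulse_without_recombination_is_binomial():
    gmap = helpers.linear_map(1_000_000, 0.0)
    specs = [PopulationSpec("A", 12, 0.1), PopulationSpec("B", 12, 0.1)]
    panel = simulate_panels(specs, 50, helpers.linear_map(1_000_000, 1.0), seed=5)
    sched = helpers.pulse_schedule([0.5, 0.5], extra_generations=0, ancestries=("A", "B"))
    cohort = simulate_cohort(panel, sched, gmap, n_out=200, pop_size=200, seed=8)
    assert all(an.size == 1 for an in cohort.tract_anc)  # zero-cM map: no crossovers
    frac_b = np.mean([an[0] == 1 for an in cohort.tract_anc])
    assert abs(frac_b - 0.5) <= 3 * np.sqrt(0.25 / 200)  # individual-level migration: n = 200 individuals


def test_cohort_is_seed_deterministic(flagship_world):
    w = flagship_world
    c1 = simulate_cohort(w["founders"], w["schedule"], w["gmap"], n_out=20, pop_size=60, seed=13)
    c2 = simulate_cohort(w["founders"], w["schedule"], w["gmap"], n_out=20, pop_size=60, seed=13)
    np.testing.assert_array_equal(c1.haplotypes, c2.haplotypes)
    for b1, b2 in zip(c1.tract_bounds, c2.tract_bounds):
        np.testing.assert_array_equal(b1, b2)
    np.testing.assert_array_equal(c1.true_global, c2.true_global)


def test_tract_genetic_length_is_conserved(flagship_world):
    w = flagship_world
    cohort = simulate_cohort(w["founders"], w["schedule"], w["gmap"], n_out=30, pop_size=80, seed=3)
    gmap = w["gmap"]
    total = gmap.cm_at(cohort.chrom_end) - gmap.cm_at(cohort.chrom_start)
    for bounds in cohort.tract_bounds:
        starts = np.concatenate(([cohort.chrom_start], bounds[:-1]))
        glen = np.sum(np.asarray(gmap.cm_at(bounds)) - np.asarray(gmap.cm_at(starts)))
        assert glen == pytest.approx(total, abs=1e-9)
        assert np.all(np.diff(bounds) > 0)


def test_switch_points_grow_with_time_since_admixture(flagship_world):
    # deeper admixture -> more accumulated crossovers per haplotype
    w = flagship_world
    means = []
    for g in (2, 6, 12):
        sched = helpers.pulse_schedule([0.5, 0.5], extra_generations=g - 1, ancestries=("Bantu", "European"))
        reps = [
            simulate_cohort(w["founders"], sched, w["gmap"], n_out=10, pop_size=24, seed=1000 * g + r)
            .switch_point_counts()
            .mean()
            for r in range(50)
        ]
        means.append(np.mean(reps))
    assert means[0] <= means[1] <= means[2]
    assert means[2] > means[0]


def test_alleles_are_copied_from_tract_source(perfect_world):
    # with one-hot population markers, the allele at each site must equal the
    # indicator "site's marker block == tract ancestry at that site"
    panel, gmap, _ = perfect_world["panel"], perfect_world["gmap"], perfect_world["window_cm"]
    k = len(panel.populations)
    sched = helpers.pulse_schedule(np.ones(k) / k, extra_generations=3)
    cohort = simulate_cohort(panel, sched, gmap, n_out=20, pop_size=40, seed=6)
    block = np.array([i % k for i in range(cohort.n_sites)])
    for h in range(2 * cohort.n_individuals):
        anc_at_site = cohort.tract_anc[h][np.searchsorted(cohort.tract_bounds[h], cohort.positions, side="right")]
        np.testing.assert_array_equal(cohort.haplotypes[h], (block == anc_at_site).astype(np.uint8))


def test_cohort_argument_validation(flagship_world):
    w = flagship_world
    with pytest.raises(ValueError, match="pop_size"):
        simulate_cohort(w["founders"], w["schedule"], w["gmap"], n_out=1, pop_size=1, seed=0)
    with pytest.raises(ValueError, match="n_out"):
        simulate_cohort(w["founders"], w["schedule"], w["gmap"], n_out=50, pop_size=10, seed=0)
    bad = helpers.pulse_schedule([1.0], ancestries=("Martian",))
    with pytest.raises(ValueError, match="Martian"):
        simulate_cohort(w["founders"], bad, w["gmap"], n_out=5, pop_size=10, seed=0)


# ---------------------------------------------------------------------------
# true_global_from_tracts


def test_true_global_single_ancestry_is_indicator():
    gmap = helpers.linear_map(1000, 1.0)
    cohort = helpers.manual_cohort(gmap, ("A", "B"), [[(1001.0, 0)], [(1001.0, 0)]])
    np.testing.assert_allclose(
        true_global_from_tracts(cohort.tracts_dataframe(), gmap, ("A", "B")), [1.0, 0.0]
    )


def test_true_global_opposite_haplotypes_are_half_half():
    gmap = helpers.linear_map(1000, 1.0)
    cohort = helpers.manual_cohort(gmap, ("A", "B", "C"), [[(1001.0, 0)], [(1001.0, 1)]])
    np.testing.assert_allclose(
        true_global_from_tracts(cohort.tracts_dataframe(), gmap, ("A", "B", "C")), [0.5, 0.5, 0.0]
    )


def test_true_global_matches_per_site_brute_force(flagship_world):
    # independent oracle: evaluate ancestry at a dense uniform-in-cM grid of
    # probe points and count, instead of summing tract genetic lengths
    w = flagship_world
    cohort = simulate_cohort(w["founders"], w["schedule"], w["gmap"], n_out=5, pop_size=40, seed=17)
    gmap = w["gmap"]
    probes_cm = np.linspace(1e-9, gmap.total_cm - 1e-9, 20_000)
    probes_bp = np.asarray(gmap.bp_at(probes_cm))
    for i in range(cohort.n_individuals):
        counts = np.zeros(len(cohort.ancestries))
        for h in (2 * i, 2 * i + 1):
            anc = cohort.tract_anc[h][np.searchsorted(cohort.tract_bounds[h], probes_bp, side="right")]
            counts += np.bincount(anc, minlength=len(cohort.ancestries))
        np.testing.assert_allclose(counts / counts.sum(), cohort.true_global[i], atol=2e-3)


def test_true_global_rejects_gaps_and_overlaps():
    gmap = helpers.linear_map(1000, 1.0)
    cohort = helpers.manual_cohort(gmap, ("A", "B"), [[(1001.0, 0)], [(1001.0, 1)]])
    df = cohort.tracts_dataframe()
    import pandas as pd

    gapped = df.copy()
    gapped.loc[0, "end_bp"] = 500  # leaves (500, 600) uncovered
    extra = pd.DataFrame(
        [{"chromosome": "1", "start_bp": 600, "end_bp": 1001, "haplotype_id": "ind_0.0", "ancestry": "B"}]
    )
    gapped = pd.concat([gapped, extra], ignore_index=True)
    with pytest.raises(ValueError, match="gaps"):
        true_global_from_tracts(gapped, gmap, ("A", "B"))
    with pytest.raises(ValueError, match="unknown ancestry"):
        bad = df.copy()
        bad.loc[0, "ancestry"] = "Z"
        true_global_from_tracts(bad, gmap, ("A", "B"))
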