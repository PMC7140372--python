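import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from admixbench import (
    GlobalAncestryMatrix,
    LocalAncestryCalls,
    call_local_ancestry,
    compare_conditions,
    fit_caller,
    gai_rmse,
    lai_overall_accuracy,
    lai_per_ancestry_accuracy,
    match_clusters,
    simulate_cohort,
    split_reference,
    summarize_cohort,
    write_truth_as_calls,
)

import helpers


def random_q(rng, n, k, ids=None, ancestries=None):
    return GlobalAncestryMatrix(
        ids or [f"s{i}" for i in range(n)],
        ancestries or [f"anc{j}" for j in range(k)],
        rng.dirichlet(np.ones(k), size=n),
    )


# ---------------------------------------------------------------------------
# match_clusters


def test_match_clusters_recovers_permutation():
    rng = np.random.default_rng(0)
    truth = random_q(rng, 30, 4).to_dataframe()
    perm = [2, 0, 3, 1]
    est = GlobalAncestryMatrix(
        list(truth.index), [f"cluster{j}" for j in range(4)], truth.to_numpy()[:, perm]
    )
    matched, result = match_clusters(est, truth)
    np.testing.assert_allclose(matched.proportions, truth.to_numpy(), atol=1e-12)
    assert list(matched.ancestries) == list(truth.columns)
    assert not result.tied


def test_match_clusters_agrees_with_exhaustive_search():
    rng = np.random.default_rng(1)
    truth = random_q(rng, 25, 5).to_dataframe()
    est = random_q(rng, 25, 5, ids=list(truth.index))
    _, result = match_clusters(est, truth)
    # independent oracle: score all 120 permutations directly
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(5)):
        score = sum(
            np.corrcoef(est.proportions[:, perm[t]], truth.to_numpy()[:, t])[0, 1] for t in range(5)
        )
        if score > best_score:
            best_perm, best_score = perm, score
    assert result.assignment == best_perm
    assert result.total_correlation == pytest.approx(best_score)


def test_match_clusters_tie_breaks_to_lowest_index():
    # estimate columns c0 and c1 are identical, so the two optimal
    # assignments tie exactly; the lexicographically smallest wins
    x = np.array([0.3, 0.2, 0.25, 0.15])
    props = np.column_stack([x, x, 1 - 2 * x])
    est = GlobalAncestryMatrix([f"s{i}" for i in range(4)], ["c0", "c1", "c2"], props)
    truth = pd.DataFrame(props, index=est.sample_ids, columns=["A", "B", "C"])
    matched, result = match_clusters(est, truth)
    assert result.tied
    assert result.assignment == (0, 1, 2)  # lowest-index estimate column taken first
    with pytest.raises(ValueError, match="K mismatch"):
        match_clusters(est, truth.iloc[:, :2])


# ---------------------------------------------------------------------------
# gai_rmse


def test_gai_rmse_examples_and_oracle():
    rng = np.random.default_rng(2)
    q = random_q(rng, 50, 5)
    truth = q.to_dataframe()
    assert (gai_rmse(q, truth) == 0).all()

    one = GlobalAncestryMatrix(["s"], ["A", "B"], np.array([[0.6, 0.4]]))
    np.testing.assert_allclose(
        gai_rmse(one, pd.DataFrame([[0.5, 0.5]], index=["s"], columns=["A", "B"])), [0.1, 0.1]
    )

    other = random_q(rng, 50, 5, ids=q.sample_ids)
    rmse = gai_rmse(other, truth)
    for j, anc in enumerate(truth.columns):  # direct summation oracle
        acc = 0.0
        for i in range(50):
            acc += (other.proportions[i, j] - truth.iloc[i, j]) ** 2
        assert rmse[anc] == pytest.approx(np.sqrt(acc / 50), abs=1e-12)

    short = random_q(rng, 10, 5)
    with pytest.raises(ValueError, match="sample"):
        gai_rmse(short, truth)
    with pytest.raises(ValueError, match="not aligned"):
        gai_rmse(one, truth)


# ---------------------------------------------------------------------------
# LAI accuracies


def two_ind_calls(call_rows, truth_rows, n_snps=None, labels=("A", "B")):
    n_win = len(call_rows)
    spos = np.arange(n_win) * 100
    common = dict(
        chromosome="1",
        spos=spos,
        epos=spos + 100,
        sgpos=spos * 0.01,
        egpos=(spos + 100) * 0.01,
        n_snps=n_snps if n_snps is not None else np.ones(n_win, dtype=int),
        haplotype_ids=["i0.0", "i0.1", "i1.0", "i1.1"],
        code_map={i: l for i, l in enumerate(labels)},
    )
    return (
        LocalAncestryCalls(calls=np.array(call_rows), **common),
        LocalAncestryCalls(calls=np.array(truth_rows), **common),
    )


def test_overall_accuracy_enumeration():
    calls, truth = two_ind_calls(
        call_rows=[[0, 0, 1, 1], [0, 1, 1, 0], [1, 0, 0, 0], [0, 0, 0, 0]],
        truth_rows=[[0, 0, 1, 1], [0, 0, 1, 0], [1, 1, 0, 0], [0, 0, 1, 0]],
    )
    acc = lai_overall_accuracy(calls, truth)
    # individual 0: haplotypes i0.0 (4/4) and i0.1 (2/4) -> 6/8
    assert acc["i0"] == pytest.approx(6 / 8)
    # individual 1: haplotypes i1.0 (3/4) and i1.1 (4/4) -> 7/8
    assert acc["i1"] == pytest.approx(7 / 8)


def test_overall_accuracy_identity_and_exclusion():
    calls, truth = two_ind_calls(
        call_rows=[[0, 0, -1, -1], [1, 1, -1, -1]],
        truth_rows=[[0, 0, 0, 0], [1, 1, 1, 1]],
    )
    acc = lai_overall_accuracy(calls, truth)
    assert acc.tolist() == [1.0]
    assert acc.attrs["excluded"] == ["i1"]  # zero called windows: excluded, not zero


def test_per_ancestry_accuracy_recall_and_exclusion():
    # truth all-A for individual 0; calls half A half B
    calls, truth = two_ind_calls(
        call_rows=[[0, 0, 0, 0], [1, 1, 0, 0]],
        truth_rows=[[0, 0, 0, 0], [0, 0, 0, 0]],
    )
    acc = lai_per_ancestry_accuracy(calls, truth)
    assert acc.loc["i0", "A"] == pytest.approx(0.5)
    assert np.isnan(acc.loc["i0", "B"])  # no true-B sites: excluded
    series = lai_per_ancestry_accuracy(calls, truth, ancestry="A")
    np.testing.assert_allclose(series.to_numpy(), [0.5, 1.0])
    with pytest.raises(ValueError, match="unknown ancestry"):
        lai_per_ancestry_accuracy(calls, truth, ancestry="Z")


def test_per_ancestry_numerators_partition_overall():
    rng = np.random.default_rng(3)
    n_win = 16
    call_rows = rng.integers(0, 3, size=(n_win, 4))
    truth_rows = rng.integers(0, 3, size=(n_win, 4))
    n_snps = rng.integers(1, 7, size=n_win)
    calls, truth = two_ind_calls(call_rows, truth_rows, n_snps=n_snps, labels=("A", "B", "C"))
    overall = lai_overall_accuracy(calls, truth)
    recall = lai_per_ancestry_accuracy(calls, truth)
    w = n_snps.astype(float)
    for i, ind in enumerate(("i0", "i1")):
        num_overall = 0.0
        num_by_anc = 0.0
        for h in (2 * i, 2 * i + 1):
            num_overall += w @ (call_rows[:, h] == truth_rows[:, h])
            for k in range(3):
                num_by_anc += w @ ((truth_rows[:, h] == k) & (call_rows[:, h] == k))
        assert num_overall == pytest.approx(num_by_anc)  # sum_k d_ca == d_c
        assert overall[ind] == pytest.approx(num_overall / (2 * w.sum()))


def test_precision_style_variant():
    calls, truth = two_ind_calls(
        call_rows=[[0, 0, 0, 0], [0, 0, 0, 0]],
        truth_rows=[[0, 0, 0, 0], [1, 1, 1, 1]],
    )
    prec = lai_per_ancestry_accuracy(calls, truth, style="precision")
    assert prec.loc["i0", "A"] == pytest.approx(0.5)  # half the A-calls are truly A
    assert np.isnan(prec.loc["i0", "B"])  # nothing called B


def test_window_grid_mismatch_rejected():
    calls, truth = two_ind_calls([[0, 0, 0, 0]], [[0, 0, 0, 0]])
    other = LocalAncestryCalls(
        chromosome="1",
        spos=[5],
        epos=[105],
        sgpos=[0.0],
        egpos=[1.0],
        n_snps=[1],
        haplotype_ids=truth.haplotype_ids,
        calls=[[0, 0, 0, 0]],
        code_map={0: "A", 1: "B"},
    )
    with pytest.raises(ValueError, match="window grid"):
        lai_overall_accuracy(calls, other)


# ---------------------------------------------------------------------------
# Wilcoxon comparisons


def test_identical_paired_samples_give_p_one():
    res = compare_conditions([0.8, 0.9, 0.7], [0.8, 0.9, 0.7], paired=True)
    assert res.p_value == 1.0
    assert res.warning is not None


def test_unpaired_exact_rank_sum_enumeration():
    # {1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20 labelings, two-sided
    res = compare_conditions([1, 2, 3], [4, 5, 6], paired=False)
    assert res.method.endswith("exact")
    assert res.p_value == pytest.approx(0.1)
    # independent oracle: enumerate all labelings of the rank-sum statistic
    values = np.array([1, 2, 3, 4, 5, 6], dtype=float)
    ranks = stats.rankdata(values)
    observed = ranks[:3].sum()
    null = [sum(ranks[list(c)]) for c in itertools.combinations(range(6), 3)]
    p_oracle = np.mean([abs(s - 10.5) >= abs(observed - 10.5) for s in null])
    assert res.p_value == pytest.approx(p_oracle)


def test_exact_and_approximate_paths_agree_at_n15():
    rng = np.random.default_rng(4)
    a = rng.normal(0.8, 0.05, size=15)
    b = a + rng.normal(0.02, 0.04, size=15)
    exact = compare_conditions(a, b, paired=True, method="exact")
    approx = compare_conditions(a, b, paired=True, method="approx")
    assert abs(exact.p_value - approx.p_value) < 0.02


def test_paired_length_mismatch_rejected():
    with pytest.raises(ValueError, match="paired"):
        compare_conditions([1, 2], [1, 2, 3], paired=True)


# ---------------------------------------------------------------------------
# cohort summaries


def test_constant_column_has_degenerate_ci():
    props = np.column_stack([np.full(20, 0.3), np.full(20, 0.7)])
    summary = summarize_cohort(props, ancestries=["A", "B"], n_boot=500, seed=0)
    assert summary.loc["A", "mean_pct"] == pytest.approx(30.0)
    assert summary.loc["A", "ci_lo_pct"] == pytest.approx(30.0)
    assert summary.loc["A", "ci_hi_pct"] == pytest.approx(30.0)


def test_bootstrap_ci_brackets_mean_and_is_seeded():
    rng = np.random.default_rng(5)
    props = rng.dirichlet([3, 2, 1], size=40)
    s1 = summarize_cohort(props, n_boot=2000, seed=7)
    s2 = summarize_cohort(props, n_boot=2000, seed=7)
    pd.testing.assert_frame_equal(s1, s2)
    assert (s1["ci_lo_pct"] <= s1["mean_pct"]).all()
    assert (s1["mean_pct"] <= s1["ci_hi_pct"]).all()
    with pytest.raises(ValueError):
        summarize_cohort(props[:1])


# ---------------------------------------------------------------------------
# confusability of closely related references


def test_lower_differentiation_hurts_only_the_confusable_pair():
    # two worlds identical except populations P0/P1 are made nearly
    # indistinguishable in the second; their calling accuracy must drop while
    # the well-separated populations stay put within noise
    def run(diffs, seed):
        panel, gmap = helpers.differentiated_world(diffs, n_per_pop=25, n_sites=500, seed=19)
        founders, holdout = split_reference(panel, 10, seed=3)
        sched = helpers.pulse_schedule([0.25, 0.25, 0.25, 0.25], ancestries=("P0", "P1", "P2", "P3"), extra_generations=4)
        cohort = simulate_cohort(founders, sched, gmap, n_out=40, pop_size=80, seed=seed)
        model = fit_caller(holdout, window_cm=2.0)
        calls = call_local_ancestry(
            cohort.haplotypes, model, gmap, cohort.haplotype_ids(), cohort.chrom_start, cohort.chrom_end
        )
        truth = write_truth_as_calls(cohort, calls)
        return lai_per_ancestry_accuracy(calls, truth).mean()

    separated = run([0.3, 0.3, 0.3, 0.3], seed=23)
    confusable = run([0.02, 0.02, 0.3, 0.3], seed=23)
    drop_p0 = separated["P0"] - confusable["P0"]
    drop_p1 = separated["P1"] - confusable["P1"]
    assert drop_p0 > 0.05 and drop_p1 > 0.05
    for far in ("P2", "P3"):
        assert abs(separated[far] - confusable[far]) < min(drop_p0, drop_p1)
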