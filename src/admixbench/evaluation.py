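"""Scoring of ancestry-inference output against simulated truth.

Global accuracy is the per-ancestry root-mean-squared error between estimated
and true admixture proportions. Local accuracy is computed per individual:
the overall accuracy is (correctly called sites) / (called sites), and the
per-ancestry accuracy is recall-style — of the called sites whose true
ancestry is k, the fraction also called k — with a precision-style variant
(of the sites called k, the fraction truly k) available alongside. "Sites"
means SNPs: windows are weighted by their contained SNP count by default,
with genetic- and physical-length weighting as options. Accuracies are
averaged over individuals; condition contrasts use Wilcoxon rank tests and
cohort proportions are summarised with percentile-bootstrap 95% CIs.

Anonymous cluster columns (unsupervised runs) are aligned to truth ancestries
by :func:`match_clusters` before scoring.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .format_io import MISSING_CODE, GlobalAncestryMatrix, LocalAncestryCalls

__all__ = [
    "AccuracyReport",
    "MatchResult",
    "ComparisonResult",
    "match_clusters",
    "gai_rmse",
    "lai_overall_accuracy",
    "lai_per_ancestry_accuracy",
    "compare_conditions",
    "summarize_cohort",
    "build_report",
]


def _truth_frame(truth, ancestries=None) -> pd.DataFrame:
    if isinstance(truth, GlobalAncestryMatrix):
        return truth.to_dataframe()
    if isinstance(truth, pd.DataFrame):
        return truth
    arr = np.asarray(truth, dtype=np.float64)
    cols = list(ancestries) if ancestries is not None else [f"anc{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


# ---------------------------------------------------------------------------
# cluster matching

@dataclass(frozen=True)
class MatchResult:
    assignment: tuple[int, ...]  # estimate column used for each truth ancestry
    total_correlation: float
    tied: bool


def _column_correlations(est: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """corr[c, k] between estimate column c and truth column k (0 where degenerate)."""
    k = est.shape[1]
    out = np.zeros((k, k))
    for c in range(k):
        for t in range(k):
            sx, sy = est[:, c].std(), truth[:, t].std()
            if sx == 0 or sy == 0:
                continue
            out[c, t] = np.corrcoef(est[:, c], truth[:, t])[0, 1]
    return out


def match_clusters(estimated: GlobalAncestryMatrix, truth, truth_ancestries=None):
    """Resolve anonymous estimate columns to truth ancestries.

    Finds the bijection maximising the total column correlation (brute force
    over permutations for K ≤ 8, with the lexicographically smallest optimal
    assignment on ties; Hungarian assignment for larger K). Returns the
    relabelled, column-reordered matrix together with a :class:`MatchResult`.
    """
    tf = _truth_frame(truth, truth_ancestries)
    k = len(estimated.ancestries)
    if tf.shape[1] != k:
        raise ValueError(f"K mismatch: estimate has {k} columns, truth has {tf.shape[1]}")
    if len(estimated.sample_ids) != len(tf):
        raise ValueError("estimate and truth must cover the same individuals")
    corr = _column_correlations(estimated.proportions, tf.to_numpy(dtype=float))

    tied = False
    if k <= 8:
        best, best_perm = -np.inf, None
        for perm in itertools.permutations(range(k)):  # perm[t] = estimate column for truth t
            total = sum(corr[perm[t], t] for t in range(k))
            if total > best + 1e-12:
                best, best_perm = total, perm
            elif abs(total - best) <= 1e-12:
                tied = True
        assignment = best_perm
    else:
        rows, cols = linear_sum_assignment(-corr)
        assignment = tuple(int(rows[np.argwhere(cols == t)[0, 0]]) for t in range(k))
        best = float(sum(corr[assignment[t], t] for t in range(k)))

    reordered = estimated.proportions[:, list(assignment)]
    relabelled = GlobalAncestryMatrix(
        sample_ids=list(estimated.sample_ids),
        ancestries=list(tf.columns),
        proportions=reordered,
    )
    return relabelled, MatchResult(assignment=tuple(assignment), total_correlation=float(best), tied=tied)


# ---------------------------------------------------------------------------
# global accuracy

def gai_rmse(estimated: GlobalAncestryMatrix, truth, truth_ancestries=None) -> pd.Series:
    """Per-ancestry RMSE: sqrt(mean over individuals of (est − truth)²)."""
    tf = _truth_frame(truth, truth_ancestries)
    if list(tf.columns) != list(estimated.ancestries):
        if set(tf.columns) == set(estimated.ancestries):
            tf = tf[list(estimated.ancestries)]  # same labels, different order
        else:
            raise ValueError("ancestry columns of estimate and truth are not aligned")
    if len(tf) != len(estimated.sample_ids):
        raise ValueError("sample mismatch between estimate and truth")
    if isinstance(tf.index[0], str) and list(tf.index) != list(estimated.sample_ids):
        raise ValueError("sample ids of estimate and truth are not aligned")
    diff = estimated.proportions - tf.to_numpy(dtype=float)
    return pd.Series(np.sqrt(np.mean(diff**2, axis=0)), index=list(estimated.ancestries), name="rmse")


# ---------------------------------------------------------------------------
# local accuracy

def _align_calls(calls: LocalAncestryCalls, truth: LocalAncestryCalls, weighting: str):
    from .format_io import _window_weights

    if not (np.array_equal(calls.spos, truth.spos) and np.array_equal(calls.epos, truth.epos)):
        raise ValueError("calls and truth must share the same window grid")
    if calls.haplotype_ids != truth.haplotype_ids:
        raise ValueError("calls and truth must cover the same haplotypes in the same order")
    if calls.n_haplotypes % 2:
        raise ValueError("haplotype columns must pair into individuals")
    label_to_truth = {lab: code for code, lab in truth.code_map.items()}
    missing_labels = [lab for lab in calls.code_map.values() if lab not in label_to_truth]
    if missing_labels:
        raise ValueError(f"called ancestries absent from truth labels: {missing_labels}")
    # translate call codes into truth codes via shared labels (index shifted by 1
    # so the no-call code -1 passes through)
    lut = np.full(max(calls.code_map) + 2, MISSING_CODE, dtype=np.int16)
    for c, lab in calls.code_map.items():
        lut[c + 1] = label_to_truth[lab]
    called = lut[calls.calls.astype(np.int64) + 1]
    weights = _window_weights(calls, weighting)
    return called, truth.calls, weights


def _individual_ids(calls: LocalAncestryCalls) -> list[str]:
    return [hid.rsplit(".", 1)[0] for hid in calls.haplotype_ids[0::2]]


def lai_overall_accuracy(
    calls: LocalAncestryCalls, truth: LocalAncestryCalls, weighting: str = "snp-count"
) -> pd.Series:
    """Per-individual overall accuracy: correctly called sites / called sites.

    Individuals with zero called sites are excluded and listed in the result's
    ``attrs["excluded"]``; the cohort mean is the unweighted mean over the
    returned individuals.
    """
    called, tru, w = _align_calls(calls, truth, weighting)
    ok = called != MISSING_CODE
    num = w @ (ok & (called == tru))
    den = w @ ok
    num_i = num[0::2] + num[1::2]
    den_i = den[0::2] + den[1::2]
    ids = _individual_ids(calls)
    keep = den_i > 0
    out = pd.Series((num_i[keep] / den_i[keep]), index=[i for i, k in zip(ids, keep) if k], name="overall_accuracy")
    out.attrs["excluded"] = [i for i, k in zip(ids, keep) if not k]
    return out


def lai_per_ancestry_accuracy(
    calls: LocalAncestryCalls,
    truth: LocalAncestryCalls,
    ancestry: str | None = None,
    style: str = "recall",
    weighting: str = "snp-count",
):
    """Per-individual, per-ancestry accuracy.

    ``style="recall"`` (default): of the called sites whose TRUE ancestry is
    k, the fraction also called k. ``style="precision"``: of the sites called
    k, the fraction whose true ancestry is k. Individuals with an empty
    denominator for an ancestry get NaN there and drop out of that ancestry's
    mean. Returns a DataFrame (individuals × ancestries), or a Series when a
    single ``ancestry`` is requested.
    """
    if style not in ("recall", "precision"):
        raise ValueError("style must be 'recall' or 'precision'")
    called, tru, w = _align_calls(calls, truth, weighting)
    labels = [truth.code_map[c] for c in sorted(truth.code_map)]
    if ancestry is not None and ancestry not in labels:
        raise ValueError(f"unknown ancestry label {ancestry!r}")
    ok = called != MISSING_CODE
    ids = _individual_ids(calls)
    cols = {}
    for code, label in zip(sorted(truth.code_map), labels):
        if ancestry is not None and label != ancestry:
            continue
        if style == "recall":
            den_mask = ok & (tru == code)
        else:
            den_mask = ok & (called == code)
        num_mask = den_mask & (called == code) & (tru == code)
        num = w @ num_mask
        den = w @ den_mask
        num_i = num[0::2] + num[1::2]
        den_i = den[0::2] + den[1::2]
        with np.errstate(invalid="ignore", divide="ignore"):
            cols[label] = np.where(den_i > 0, num_i / np.where(den_i > 0, den_i, 1.0), np.nan)
    df = pd.DataFrame(cols, index=ids)
    if ancestry is not None:
        return df[ancestry]
    return df


# ---------------------------------------------------------------------------
# comparisons and summaries

@dataclass(frozen=True)
class ComparisonResult:
    p_value: float
    statistic: float
    method: str
    paired: bool
    warning: str | None = None


_EXACT_MAX_N = 20


def compare_conditions(acc_a, acc_b, paired: bool = True, method: str = "auto") -> ComparisonResult:
    """Two-sided Wilcoxon comparison of two accuracy samples.

    Paired uses the signed-rank test, unpaired the rank-sum (Mann–Whitney)
    test. With ``method="auto"`` the exact null distribution is used when the
    combined sample size is ≤ 20 and the data permit it, and the normal
    approximation with tie correction otherwise; ``"exact"`` / ``"approx"``
    force one code path. All-tied paired differences return p = 1 with a
    warning rather than an error.
    """
    if method not in ("auto", "exact", "approx"):
        raise ValueError("method must be 'auto', 'exact' or 'approx'")
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal-length samples in shared order")
        d = a - b
        if np.all(d == 0):
            return ComparisonResult(1.0, 0.0, "wilcoxon-signed-rank", True, warning="all paired differences are zero")
        if method == "auto":
            nz = d[d != 0]
            exact_ok = a.size <= _EXACT_MAX_N and np.unique(np.abs(nz)).size == nz.size
            method = "exact" if exact_ok else "approx"
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=(method == "approx"), method=method)
        return ComparisonResult(float(res.pvalue), float(res.statistic), f"wilcoxon-signed-rank-{method}", True)
    if method == "auto":
        combined = np.concatenate([a, b])
        exact_ok = combined.size <= _EXACT_MAX_N and np.unique(combined).size == combined.size
        method = "exact" if exact_ok else "approx"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method={"exact": "exact", "approx": "asymptotic"}[method])
    return ComparisonResult(float(res.pvalue), float(res.statistic), f"wilcoxon-rank-sum-{method}", False)


def summarize_cohort(proportions, ancestries=None, n_boot: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Mean ancestry proportions (percent) with 95% percentile-bootstrap CIs.

    Resamples individuals with replacement ``n_boot`` times; needs n ≥ 2.
    """
    tf = _truth_frame(proportions, ancestries)
    arr = tf.to_numpy(dtype=float)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("summaries need at least two individuals")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = arr[idx].mean(axis=1)  # n_boot × K
    lo, hi = np.percentile(boot_means, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "mean_pct": arr.mean(axis=0) * 100.0,
            "ci_lo_pct": lo * 100.0,
            "ci_hi_pct": hi * 100.0,
        },
        index=list(tf.columns),
    )


@dataclass
class AccuracyReport:
    """Bundle of global/local accuracy statistics for one evaluated condition."""

    per_ancestry_rmse: pd.Series = field(repr=False)
    mean_proportions: pd.DataFrame = field(repr=False)
    overall_accuracy: pd.Series = field(repr=False)
    per_ancestry_accuracy: pd.DataFrame = field(repr=False)
    comparisons: list[tuple[str, ComparisonResult]] = field(default_factory=list, repr=False)

    @property
    def overall_mean(self) -> float:
        return float(self.overall_accuracy.mean())

    def per_ancestry_means(self) -> pd.Series:
        return self.per_ancestry_accuracy.mean(axis=0, skipna=True)

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.per_ancestry_rmse.to_csv(d / "gai_rmse.tsv", sep="\t", header=["rmse"])
        self.mean_proportions.to_csv(d / "mean_proportions.tsv", sep="\t")
        self.overall_accuracy.to_csv(d / "lai_overall_accuracy.tsv", sep="\t", header=["accuracy"])
        self.per_ancestry_accuracy.to_csv(d / "lai_per_ancestry_accuracy.tsv", sep="\t")
        summary = {
            "overall_accuracy_mean": self.overall_mean,
            "per_ancestry_accuracy_mean": {k: float(v) for k, v in self.per_ancestry_means().items()},
            "gai_rmse": {k: float(v) for k, v in self.per_ancestry_rmse.items()},
            "comparisons": [
                {"pair": name, "p_value": c.p_value, "method": c.method, "paired": c.paired, "warning": c.warning}
                for name, c in self.comparisons
            ],
        }
        with open(d / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)


def build_report(
    estimated_q: GlobalAncestryMatrix,
    truth_q,
    calls: LocalAncestryCalls,
    truth_calls: LocalAncestryCalls,
    weighting: str = "snp-count",
    seed: int = 0,
) -> AccuracyReport:
    """Score one inference condition end to end and bundle the statistics."""
    return AccuracyReport(
        per_ancestry_rmse=gai_rmse(estimated_q, truth_q),
        mean_proportions=summarize_cohort(estimated_q.to_dataframe(), seed=seed),
        overall_accuracy=lai_overall_accuracy(calls, truth_calls, weighting=weighting),
        per_ancestry_accuracy=lai_per_ancestry_accuracy(calls, truth_calls, weighting=weighting),
    )
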