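"""Meta-comparison of the fifteen analysis methods across comparator datasets.

Within each dataset the fifteen p-values are ranked (1 = smallest p,
mid-ranks for ties).  A tie-adjusted Friedman two-way ANOVA then asks
whether the methods differ in average rank across datasets, and — when it is
significant — Duncan's multiple range test groups methods whose mean ranks
do not differ, producing the letter display and the 1..15 rating tables.
The bootstrap type-I-error assessment checks that the most efficient methods
keep their nominal false-positive rate on resampled null data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .battery import METHODS, BatteryConfig, TestResult, dataset_arrays, run_single
from .trial_model import ComparatorDataset, get_scale

log = logging.getLogger(__name__)

__all__ = [
    "RankMatrix",
    "DuncanGrouping",
    "rank_pvalues",
    "build_rank_matrix",
    "friedman_with_ties",
    "duncan_groups",
    "rating_table",
    "compare_by_subgroup",
    "assess_type1_error",
    "render_rating_table",
]


@dataclass
class RankMatrix:
    """Datasets x methods matrix of within-dataset p-value ranks."""

    datasets: list[str]
    methods: tuple[str, ...]
    ranks: np.ndarray  # (n_datasets, k_methods)

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        n, k = self.ranks.shape
        if n != len(self.datasets) or k != len(self.methods):
            raise ValueError("rank matrix shape mismatch")
        expected = k * (k + 1) / 2
        if not np.allclose(self.ranks.sum(axis=1), expected):
            raise ValueError("row rank sums violated (mid-rank ties conserve them)")

    @property
    def mean_ranks(self) -> np.ndarray:
        return self.ranks.mean(axis=0)


@dataclass
class DuncanGrouping:
    """Mean ranks with Duncan letter groups (methods sharing a letter do not
    differ significantly)."""

    methods: tuple[str, ...]
    mean_ranks: np.ndarray
    letters: dict[str, str]
    friedman_stat: float
    friedman_p: float
    significant: bool
    alpha: float = 0.05
    mse: float = float("nan")
    df_error: int = 0


def rank_pvalues(p: Sequence[float]) -> np.ndarray:
    """Rank p-values within one dataset: 1 = smallest, mid-ranks for ties."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d p-value vector")
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-value; degenerate methods must report p=1")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.rankdata(p, method="average")


def build_rank_matrix(results_by_dataset: Mapping[str, Sequence[TestResult]]) -> RankMatrix:
    ids, rows = [], []
    for ds_id, results in results_by_dataset.items():
        by_method = {r.method: r for r in results}
        if set(by_method) != set(METHODS):
            raise ValueError(f"dataset {ds_id!r}: need one result per method")
        rows.append(rank_pvalues([by_method[m].p_value for m in METHODS]))
        ids.append(ds_id)
    return RankMatrix(ids, METHODS, np.array(rows))


def friedman_with_ties(rm: RankMatrix) -> tuple[float, float]:
    """Friedman chi-square with the tie-correction divisor.

    statistic = [12 sum_j (R_j - n(k+1)/2)^2 / (n k (k+1))] / C with
    C = 1 - sum(t^3 - t) / (n k (k^2 - 1)) over within-row tie groups.
    Fully tied matrices (C = 0) report statistic 0, p 1.
    """
    R = rm.ranks
    n, k = R.shape
    if n < 2:
        raise ValueError("Friedman test needs >= 2 datasets")
    col = R.sum(axis=0)
    S = float(np.sum((col - n * (k + 1) / 2.0) ** 2))
    correction = 0.0
    for row in R:
        _, t = np.unique(row, return_counts=True)
        correction += float(np.sum(t**3 - t))
    C = 1.0 - correction / (n * k * (k**2 - 1))
    if C <= 0:
        return 0.0, 1.0
    stat = 12.0 * S / (n * k * (k + 1)) / C
    return stat, float(stats.chi2.sf(stat, k - 1))


@lru_cache(maxsize=512)
def _duncan_critical(alpha: float, span: int, df: int) -> float:
    """Studentized-range quantile at Duncan's protection level
    alpha_p = 1 - (1 - alpha)^(span - 1)."""
    return float(stats.studentized_range.ppf((1 - alpha) ** (span - 1), span, df))


def duncan_groups(rm: RankMatrix, alpha: float = 0.05) -> DuncanGrouping:
    """Duncan's multiple range test on the method mean ranks.

    The error variance is the residual mean square of the two-way
    (dataset x method) ANOVA of the rank matrix, with (n-1)(k-1) degrees of
    freedom — the only error term internally consistent with ranking within
    datasets.  Applied only when the Friedman test is significant; otherwise
    an explicit not-significant grouping (all methods lettered "A") is
    returned.
    """
    R = rm.ranks
    n, k = R.shape
    fstat, fp = friedman_with_ties(rm)
    means = rm.mean_ranks
    if fp >= alpha:
        letters = {m: "A" for m in rm.methods}
        return DuncanGrouping(rm.methods, means, letters, fstat, fp, False, alpha)
    resid = R - R.mean(axis=1, keepdims=True) - R.mean(axis=0, keepdims=True) + R.mean()
    df_err = (n - 1) * (k - 1)
    mse = float(np.sum(resid**2) / df_err)
    se_mean = np.sqrt(mse / n)
    order = np.argsort(means, kind="stable")
    sorted_means = means[order]

    # step-down ranges with Duncan's protection rule: the largest
    # non-significant range starting at each mean absorbs all sub-ranges
    max_j = np.zeros(k, dtype=int)
    for i in range(k):
        j_best = i
        for j in range(i + 1, k):
            span = j - i + 1
            crit = _duncan_critical(alpha, span, df_err) * se_mean if se_mean > 0 else 0.0
            if sorted_means[j] - sorted_means[i] <= crit:
                j_best = j
        max_j[i] = j_best
    # keep maximal intervals only
    intervals = []
    for i in range(k):
        if intervals and intervals[-1][1] >= max_j[i]:
            continue
        intervals.append((i, max_j[i]))
    letters_sorted = ["" for _ in range(k)]
    for idx, (lo, hi) in enumerate(intervals):
        letter = chr(ord("A") + idx) if idx < 26 else f"L{idx}"
        for pos in range(lo, hi + 1):
            letters_sorted[pos] += letter
    letters = {rm.methods[order[pos]]: letters_sorted[pos] for pos in range(k)}
    return DuncanGrouping(
        rm.methods, means, letters, fstat, fp, True, alpha, mse, df_err
    )


def rating_table(grouping: DuncanGrouping) -> pd.DataFrame:
    """Methods sorted by mean rank with ratings 1..k and the top-group flag.

    The top group is every method sharing a Duncan letter with the rating-1
    method (the bold set of the published rating tables); when the Friedman
    test was not significant no method is flagged.
    """
    order = np.argsort(grouping.mean_ranks, kind="stable")
    methods = [grouping.methods[i] for i in order]
    means = grouping.mean_ranks[order]
    letters = [grouping.letters.get(m, "") for m in methods]
    if grouping.significant and letters:
        best = set(letters[0])
        top = [bool(best & set(let)) for let in letters]
    else:
        top = [False] * len(methods)
    return pd.DataFrame(
        {
            "method": methods,
            "rating": np.arange(1, len(methods) + 1),
            "mean_rank": np.round(means, 4),
            "letters": letters,
            "top_group": top,
        }
    )


def compare_methods(
    results_by_dataset: Mapping[str, Sequence[TestResult]], alpha: float = 0.05
) -> tuple[RankMatrix, DuncanGrouping, pd.DataFrame]:
    """Full rank -> Friedman -> Duncan -> rating pipeline."""
    rm = build_rank_matrix(results_by_dataset)
    grouping = duncan_groups(rm, alpha)
    return rm, grouping, rating_table(grouping)


def compare_by_subgroup(
    results_by_dataset: Mapping[str, Sequence[TestResult]],
    tags_by_dataset: Mapping[str, Mapping[str, str]],
    tag: str,
    alpha: float = 0.05,
    min_datasets: int = 2,
) -> dict[str, pd.DataFrame]:
    """Run the comparison pipeline independently within each value of ``tag``.

    Subgroups with fewer than ``min_datasets`` datasets are skipped with a
    logged note.
    """
    values: dict[str, dict] = {}
    for ds_id in results_by_dataset:
        ds_tags = tags_by_dataset.get(ds_id, {})
        if tag not in ds_tags:
            raise KeyError(f"dataset {ds_id!r} has no tag {tag!r}")
        values.setdefault(ds_tags[tag], {})[ds_id] = results_by_dataset[ds_id]
    out = {}
    for value, group in sorted(values.items()):
        if len(group) < min_datasets:
            log.info("subgroup %s=%s skipped: only %d dataset(s)", tag, value, len(group))
            continue
        _, _, table = compare_methods(group, alpha)
        out[value] = table
    return out


def assess_type1_error(
    dataset: ComparatorDataset,
    scale,
    methods: Iterable[str] = ("MWU", "OLR"),
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, int]:
    """Bootstrap type-I-error counts on a neutral (dummy-arm) dataset.

    ``B`` datasets of the original size are drawn from the pooled rows with
    replacement; within each replicate the neutral dummy arm is re-assigned
    by an independent fair coin, so every replicate is exactly null and a
    well-calibrated test should be significant in about ``alpha * B`` of
    them.  Returns the per-method count of replicates with p < alpha.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    methods = list(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise KeyError(f"unknown methods: {sorted(unknown)}")
    arrays = dataset_arrays(dataset, get_scale(scale))
    n = len(arrays["levels"])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 71]))
    cfg = BatteryConfig(bootstrap_B=200, seed=seed)
    counts = {m: 0 for m in methods}
    for b in range(B):
        idx = rng.integers(0, n, n)
        arm = rng.integers(0, 2, n)
        while arm.sum() < 2 or arm.sum() > n - 2:
            arm = rng.integers(0, 2, n)
        arrs = {
            "arm": arm,
            "levels": arrays["levels"][idx],
            "covs": arrays["covs"][idx],
            "time": None if arrays["time"] is None else arrays["time"][idx],
            "observed": None if arrays["observed"] is None else arrays["observed"][idx],
            "k": arrays["k"],
            "fatal_level": arrays["fatal_level"],
        }
        for m in methods:
            res = run_single(m, arrs, cfg, rng=rng)
            if not res.degenerate and res.p_value < alpha:
                counts[m] += 1
    return counts


def render_rating_table(table: pd.DataFrame, title: str = "") -> str:
    """Monospace rendering of a rating table; top-group methods are
    asterisked (the bold set of the published tables)."""
    lines = []
    if title:
        lines.append(title)
    lines.append(f"{'rating':>6}  {'method':<8} {'mean rank':>9}  letters")
    for row in table.itertuples(index=False):
        star = "*" if row.top_group else " "
        lines.append(
            f"{row.rating:>6}  {row.method:<8}{star}{row.mean_rank:>9.2f}  {row.letters}"
        )
    return "\n".join(lines)
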