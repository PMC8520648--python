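"""Sample-size formulas for binary, ordinal, rank and mean comparisons.

All functions return the TOTAL sample size for a 1:1 allocation, two-sided
significance level ``alpha`` and power ``power``, rounded up to an even
integer so the arms are equal.  The ordinal-vs-binary *multiplier* of a
dataset is each method's required size divided by the binary-proportions
size; medians of those multipliers summarise how much smaller an
ordinal-outcome trial could be.

Formulas
--------
binary proportions (unpooled z):
    N = 2 * ceil( (z_{1-a/2} + z_{1-b})^2 (p1 q1 + p2 q2) / (p1 - p2)^2 )

proportional-odds ordinal (Whitehead), with mean category probabilities
pbar_i across arms and proportional-odds ratio OR:
    N = 12 (z_{1-a/2} + z_{1-b})^2 / [ (log OR)^2 (1 - sum pbar_i^3) ]
The constant 12 makes the two-category collapse agree with the binary
log-odds-ratio sample size (and is confirmed by the simulation calibration
tests).

Mann-Whitney (Noether), with probabilistic index p_win = P(T better) +
0.5 P(tie):
    N = (z_{1-a/2} + z_{1-b})^2 / ( 3 (p_win - 1/2)^2 )

t-test, standardised difference delta/sd:
    N = 2 * ceil( 2 (z_{1-a/2} + z_{1-b})^2 sd^2 / delta^2 )
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from ._ordinal import DegenerateDataError, fit_po_grouped
from .battery import dataset_arrays, mean_rank_difference, win_ratio_counts
from .trial_model import ComparatorDataset, get_scale

__all__ = [
    "EffectSummary",
    "n_binary",
    "n_olr",
    "n_mwu",
    "n_ttest",
    "estimate_effects",
    "multiplier_report",
    "load_table6",
    "round_multiplier",
]


@dataclass
class EffectSummary:
    """Per-dataset effect estimates feeding the four sample-size formulas."""

    p_event: tuple[float, float]      # (treatment, control) any-event proportions
    or_po: float                      # proportional-odds OR (treatment vs control)
    pbar: np.ndarray                  # mean category probabilities across arms
    p_win: float                      # P(T better) + 0.5 P(tie)
    delta: float                      # difference in mean integer score
    sd: float                         # pooled score standard deviation


def _zsum(alpha: float, power: float) -> float:
    return stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)


def _even_ceil(x: float) -> int:
    n = math.ceil(x)
    return n + (n % 2)


def n_binary(p1: float, p2: float, alpha: float = 0.05, power: float = 0.90) -> int:
    """Total N for the unpooled two-proportion z comparison."""
    for p in (p1, p2):
        if not 0 < p < 1:
            raise ValueError("event proportions must lie in (0, 1)")
    if p1 == p2:
        raise ValueError("p1 == p2: effect size undefined")
    per_group = _zsum(alpha, power) ** 2 * (p1 * (1 - p1) + p2 * (1 - p2)) / (p1 - p2) ** 2
    return 2 * math.ceil(per_group)


def n_olr(pbar, or_po: float, alpha: float = 0.05, power: float = 0.90) -> int:
    """Total N for the proportional-odds (cumulative logit) comparison."""
    pbar = np.asarray(pbar, dtype=float)
    pbar = pbar[pbar > 0]
    if len(pbar) < 2:
        raise ValueError("need >= 2 categories with positive mass")
    if or_po <= 0 or or_po == 1:
        raise ValueError("or_po must be positive and != 1")
    denom = (np.log(or_po)) ** 2 * (1.0 - float(np.sum(pbar**3)))
    return _even_ceil(12.0 * _zsum(alpha, power) ** 2 / denom)


def n_mwu(p_win: float, alpha: float = 0.05, power: float = 0.90) -> int:
    """Total N for the Mann-Whitney comparison (Noether's formula)."""
    if not 0 <= p_win <= 1:
        raise ValueError("p_win must lie in [0, 1]")
    if p_win == 0.5:
        raise ValueError("p_win == 0.5: effect size undefined")
    return _even_ceil(_zsum(alpha, power) ** 2 / (3.0 * (p_win - 0.5) ** 2))


def n_ttest(delta: float, sd: float, alpha: float = 0.05, power: float = 0.90) -> int:
    """Total N for the pooled-variance two-sample t comparison."""
    if delta == 0:
        raise ValueError("delta == 0: effect size undefined")
    if sd <= 0:
        raise ValueError("sd must be positive")
    per_group = 2.0 * _zsum(alpha, power) ** 2 * sd**2 / delta**2
    return 2 * math.ceil(per_group)


def estimate_effects(dataset: ComparatorDataset, scale) -> EffectSummary:
    """Estimate the effect quantities the four formulas need from a dataset."""
    a = dataset_arrays(dataset, get_scale(scale))
    arm, levels, k = a["arm"], a["levels"], a["k"]
    if not (levels > 0).any():
        raise ValueError("zero events in the pooled data: effects inestimable")
    lt, lc = levels[arm == 1], levels[arm == 0]
    n1, n2 = len(lt), len(lc)
    p1, p2 = float((lt > 0).mean()), float((lc > 0).mean())
    counts = np.vstack(
        [np.bincount(lc, minlength=k), np.bincount(lt, minlength=k)]
    ).astype(float)
    try:
        or_po = fit_po_grouped(counts).odds_ratio
    except DegenerateDataError:
        or_po = float("nan")
    pbar = (counts[0] / n2 + counts[1] / n1) / 2.0
    nw, nl, nt = win_ratio_counts(lt, lc, k)
    p_win = (nw + 0.5 * nt) / (n1 * n2)
    delta = float(lt.mean() - lc.mean())
    sd = float(
        np.sqrt(((n1 - 1) * lt.var(ddof=1) + (n2 - 1) * lc.var(ddof=1)) / (n1 + n2 - 2))
    )
    return EffectSummary((p1, p2), or_po, pbar, p_win, delta, sd)


def round_multiplier(x: float) -> float:
    """Round a multiplier the way the published comparisons print them:
    two significant figures below 0.1, two decimals otherwise."""
    if not np.isfinite(x):
        return x
    if abs(x) >= 0.1:
        return round(x, 2)
    if x == 0:
        return 0.0
    digits = -int(math.floor(math.log10(abs(x)))) + 1
    return round(x, digits)


def multiplier_report(rows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-dataset sample-size multipliers plus median/quartile summary.

    ``rows`` needs columns ``n_binary, n_ordinal, n_mwu, n_ttest`` (and
    optionally ``dataset``).  Multipliers are each column divided by the
    binary size, rounded at the printed precision; the summary reports the
    median and quartiles (linear interpolation) of the rounded multipliers.
    """
    need = ["n_binary", "n_ordinal", "n_mwu", "n_ttest"]
    missing = [c for c in need if c not in rows.columns]
    if missing:
        raise ValueError(f"missing sample-size columns: {missing}")
    if (rows["n_binary"] <= 0).any() or rows[need].le(0).any().any():
        raise ValueError("sample sizes must be positive")
    out = rows.copy().reset_index(drop=True)
    for col, mult in [("n_binary", "mult_binary"), ("n_ordinal", "mult_ordinal"),
                      ("n_mwu", "mult_mwu"), ("n_ttest", "mult_ttest")]:
        out[mult] = [round_multiplier(v) for v in out[col] / out["n_binary"]]
    summary = pd.DataFrame(
        {
            col: np.percentile(out[col], [25, 50, 75], method="linear")
            for col in ("mult_ordinal", "mult_mwu", "mult_ttest")
        },
        index=["Q1", "median", "Q3"],
    )
    return out, summary


def load_table6() -> pd.DataFrame:
    """The 13 published stroke/TIA 4-level sample-size rows (with the
    multipliers as printed), packaged as an in-repo fixture."""
    with resources.files("ordbench.data").joinpath("table6.csv").open("r") as fh:
        return pd.read_csv(fh)
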