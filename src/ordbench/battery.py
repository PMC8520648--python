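"""The fifteen-method analysis battery for one comparator dataset.

Each method returns a two-sided p-value made comparable across methods (the
2 x k chi-square keeps its omnibus p as-is).  Binary methods analyse the
any-event or fatal-only collapse of the ordinal outcome; ordinal methods
analyse the severity levels directly; time-to-event methods use time to
first qualifying event with administrative censoring.

Methods and their contracts
---------------------------
BLR_adj   logistic regression, any-event ~ treatment + age + sex + diabetes
CPH(_adj) Cox proportional hazards on time to any event (Efron ties)
CSB/CSF   Pearson chi-square (no continuity correction) on the 2x2 table of
          any-event / fatal-event
CSO       Pearson chi-square on the 2xk table of levels (omnibus)
CAT       Cochran-Armitage trend test, equally spaced scores, permutation
          (hypergeometric) variance
OLR(_adj) cumulative-logit proportional-odds model, treatment Wald p
MWU       Mann-Whitney U, mid-ranks, tie-corrected normal approximation
MT        Mood's median test (split at "> pooled median" vs "<= median")
TT        pooled-variance two-sample t-test on integer scores
MLR_adj   linear regression of the integer score on treatment + covariates
WR        win ratio (wins/losses down the severity hierarchy)
BS        bootstrap of the difference in mean mid-rank

Methods that cannot be computed on a given dataset (no events, constant
outcome, missing time data) return ``degenerate=True`` with p = 1 so that
every dataset still ranks all fifteen methods.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._ordinal import DegenerateDataError, fit_po_grouped, po_score_test
from .trial_model import ComparatorDataset, OrdinalScale, TREATMENT, get_scale

log = logging.getLogger(__name__)

#: Canonical method order (fixed; ranking tables follow it for tie-breaks).
METHODS = (
    "BLR_adj", "CPH", "CPH_adj", "CSB", "CSF", "CSO", "CAT",
    "OLR", "OLR_adj", "MWU", "MT", "TT", "MLR_adj", "WR", "BS",
)

COVARIATES = ("age", "sex", "diabetes")


@dataclass
class BatteryConfig:
    alpha: float = 0.05
    bootstrap_B: int = 1000
    covariates: tuple[str, ...] = COVARIATES
    seed: int = 0
    #: attach the proportional-odds score-test p to the OLR diagnostics
    po_check: bool = False


@dataclass
class TestResult:
    method: str
    p_value: float
    estimate: float | None = None
    estimate_label: str = ""
    diagnostics: dict = field(default_factory=dict)
    degenerate: bool = False

    __test__ = False  # keep pytest from collecting this dataclass


def _degenerate(method: str, reason: str) -> TestResult:
    log.warning("method %s degenerate: %s", method, reason)
    return TestResult(method, 1.0, degenerate=True, diagnostics={"reason": reason})


def _counts(arm: np.ndarray, levels: np.ndarray, k: int) -> np.ndarray:
    """2 x k contingency table; row 0 = control, row 1 = treatment."""
    return np.vstack(
        [np.bincount(levels[arm == 0], minlength=k),
         np.bincount(levels[arm == 1], minlength=k)]
    ).astype(float)


def _chi2_table(table: np.ndarray, method: str) -> TestResult:
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or np.any(table.sum(axis=1) == 0):
        return _degenerate(method, "contingency table has no variation")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(method, float(p), diagnostics={"statistic": float(stat), "df": int(dof)})


# ---------------------------------------------------------------------------
# individual methods (array interface)
# ---------------------------------------------------------------------------


def chi2_binary(arm: np.ndarray, indicator: np.ndarray, method: str = "CSB") -> TestResult:
    tab = _counts(arm, indicator.astype(int), 2)
    return _chi2_table(tab, method)


def chi2_ordinal(arm: np.ndarray, levels: np.ndarray, k: int) -> TestResult:
    return _chi2_table(_counts(arm, levels, k), "CSO")


def cochran_armitage(arm: np.ndarray, levels: np.ndarray) -> TestResult:
    """Trend test with equally spaced scores and hypergeometric variance."""
    s = levels.astype(float)
    N = len(s)
    n1 = int(arm.sum())
    n2 = N - n1
    if n1 == 0 or n2 == 0:
        return _degenerate("CAT", "empty arm")
    sbar = s.mean()
    ss = float(((s - sbar) ** 2).sum())
    if ss == 0:
        return _degenerate("CAT", "no score variation")
    T = float(s[arm == 1].sum())
    var = n1 * n2 * ss / (N * (N - 1))
    z = (T - n1 * sbar) / np.sqrt(var)
    return TestResult(
        "CAT", float(2 * stats.norm.sf(abs(z))), diagnostics={"z": float(z)}
    )


def _mwu_exact_permutation_p(xt: np.ndarray, xc: np.ndarray) -> float:
    """Two-sided exact permutation p for U, valid under ties (midranks).

    Enumerates every assignment of the pooled ranks to the treatment arm;
    feasible for the small arms (<= 10 each) where the tie-corrected normal
    approximation is unreliable.
    """
    from itertools import combinations

    n1, n2 = len(xt), len(xc)
    pooled = np.concatenate([xt, xc])
    ranks = stats.rankdata(pooled)
    obs_u = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    combs = np.fromiter(
        (i for c in combinations(range(n1 + n2), n1) for i in c), dtype=np.intp
    ).reshape(-1, n1)
    us = ranks[combs].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return float(np.mean(np.abs(us - mu) >= abs(obs_u - mu) - 1e-9))


def mann_whitney(arm: np.ndarray, levels: np.ndarray) -> TestResult:
    xt, xc = levels[arm == 1], levels[arm == 0]
    if len(xt) == 0 or len(xc) == 0:
        return _degenerate("MWU", "empty arm")
    if np.all(levels == levels[0]):
        return _degenerate("MWU", "all observations tied")
    res = stats.mannwhitneyu(
        xt, xc, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    n1, n2 = len(xt), len(xc)
    if n1 <= 10 and n2 <= 10:
        # the normal approximation is off by far more than 0.01 here;
        # enumerate the exact permutation distribution instead
        p = _mwu_exact_permutation_p(xt, xc)
        exact = True
    else:
        p = float(res.pvalue)
        exact = False
    p_win = 1.0 - float(res.statistic) / (n1 * n2)  # P(treatment lower) + 0.5 P(tie)
    return TestResult(
        "MWU", p, estimate=p_win, estimate_label="probabilistic index",
        diagnostics={"U": float(res.statistic), "exact": exact},
    )


def median_test(arm: np.ndarray, levels: np.ndarray) -> TestResult:
    med = np.median(levels)
    above = levels > med
    if above.sum() == 0 or above.sum() == len(levels):
        return _degenerate("MT", "median split has an empty side")
    return _chi2_table(_counts(arm, above.astype(int), 2), "MT")


def t_test(arm: np.ndarray, levels: np.ndarray) -> TestResult:
    xt, xc = levels[arm == 1].astype(float), levels[arm == 0].astype(float)
    if len(xt) < 2 or len(xc) < 2 or (np.ptp(xt) == 0 and np.ptp(xc) == 0):
        return _degenerate("TT", "no score variation")
    res = stats.ttest_ind(xt, xc, equal_var=True)
    return TestResult(
        "TT", float(res.pvalue), estimate=float(xt.mean() - xc.mean()),
        estimate_label="mean score difference",
    )


def olr_unadjusted(arm: np.ndarray, levels: np.ndarray, k: int) -> TestResult:
    try:
        fit = fit_po_grouped(_counts(arm, levels, k))
    except DegenerateDataError as e:
        return _degenerate("OLR", str(e))
    return TestResult(
        "OLR", fit.p_value, estimate=fit.odds_ratio, estimate_label="proportional-odds OR",
        diagnostics={"logOR": fit.beta, "se": fit.se},
    )


def win_ratio_counts(levels_t: np.ndarray, levels_c: np.ndarray, k: int):
    """Pairwise win/loss/tie counts down the severity hierarchy.

    Comparing two participants down the hierarchy of severity dichotomies
    (fatal first, then each lower grade) is equivalent to comparing their
    ordinal levels, the lower level winning; counts are accumulated from the
    per-level frequencies in O(k) rather than O(n^2).
    """
    tc = np.bincount(levels_t, minlength=k).astype(float)
    cc = np.bincount(levels_c, minlength=k).astype(float)
    c_above = cc[::-1].cumsum()[::-1] - cc          # controls with level > j
    c_below = cc.cumsum() - cc                      # controls with level < j
    nw = float(np.sum(tc * c_above))                # treatment wins
    nl = float(np.sum(tc * c_below))
    nt = float(np.sum(tc * cc))
    return nw, nl, nt


def win_ratio_test(
    arm: np.ndarray, levels: np.ndarray, k: int,
    B: int = 1000, rng: np.random.Generator | None = None,
) -> TestResult:
    """Win ratio on all treatment x control pairs, normal-approximation p.

    The variance of (win, loss) proportions is the two-sample U-statistic
    projection estimate; when either count is small (< 10) the normal
    approximation is replaced by a within-arm bootstrap of log(win ratio).
    A dataset with wins but no losses reports an infinite ratio and a sign
    (binomial) test on the win/loss counts.
    """
    lt, lc = levels[arm == 1], levels[arm == 0]
    n1, n2 = len(lt), len(lc)
    if n1 == 0 or n2 == 0:
        return _degenerate("WR", "empty arm")
    nw, nl, nt = win_ratio_counts(lt, lc, k)
    diag = {"Nw": nw, "Nl": nl, "Nt": nt}
    if nw == 0 and nl == 0:
        return _degenerate("WR", "no discordant pairs")
    if nw == 0 or nl == 0:
        bt = stats.binomtest(int(nw), int(nw + nl), 0.5)
        est = np.inf if nl == 0 else 0.0
        return TestResult("WR", float(bt.pvalue), estimate=est,
                          estimate_label="win ratio", diagnostics=diag)
    est = nw / nl
    if min(nw, nl) < 10:
        rng = rng or np.random.default_rng(0)
        tc = np.bincount(lt, minlength=k) / n1
        cc = np.bincount(lc, minlength=k) / n2
        draws_t = rng.multinomial(n1, tc, size=B)
        draws_c = rng.multinomial(n2, cc, size=B)
        lo = hi = 0
        valid = 0
        for b in range(B):
            bt_ = np.repeat(np.arange(k), draws_t[b])
            bc_ = np.repeat(np.arange(k), draws_c[b])
            w, l, _ = win_ratio_counts(bt_, bc_, k)
            if w == 0 and l == 0:
                continue
            valid += 1
            ratio_log = np.log(w / l) if (w > 0 and l > 0) else (np.inf if l == 0 else -np.inf)
            lo += ratio_log <= 0
            hi += ratio_log >= 0
        if valid == 0:
            return _degenerate("WR", "bootstrap produced no discordant pairs")
        p = max(2.0 / valid, 2 * min(lo / valid, hi / valid))
        diag["bootstrap_B"] = valid
        return TestResult("WR", float(min(1.0, p)), estimate=est,
                          estimate_label="win ratio", diagnostics=diag)
    # U-statistic projection variance for (theta_w, theta_l)
    tc = np.bincount(lt, minlength=k).astype(float)
    cc = np.bincount(lc, minlength=k).astype(float)
    w_t = (cc[::-1].cumsum()[::-1] - cc) / n2       # per treatment level: win prob
    l_t = (cc.cumsum() - cc) / n2
    w_c = (tc.cumsum() - tc) / n1                   # per control level: treatment-win prob
    l_c = (tc[::-1].cumsum()[::-1] - tc) / n1
    thw, thl = nw / (n1 * n2), nl / (n1 * n2)

    def wcov(a, b, wts, ma, mb):
        wsum = wts.sum()
        return float(np.sum(wts * (a - ma) * (b - mb)) / wsum)

    S1 = np.array([
        [wcov(w_t, w_t, tc, thw, thw), wcov(w_t, l_t, tc, thw, thl)],
        [wcov(w_t, l_t, tc, thw, thl), wcov(l_t, l_t, tc, thl, thl)],
    ])
    S2 = np.array([
        [wcov(w_c, w_c, cc, thw, thw), wcov(w_c, l_c, cc, thw, thl)],
        [wcov(w_c, l_c, cc, thw, thl), wcov(l_c, l_c, cc, thl, thl)],
    ])
    Sigma = S1 / n1 + S2 / n2
    g = np.array([1.0 / thw, -1.0 / thl])
    var_log = float(g @ Sigma @ g)
    if var_log <= 0:
        return _degenerate("WR", "non-positive variance estimate")
    z = np.log(est) / np.sqrt(var_log)
    diag["z"] = float(z)
    return TestResult("WR", float(2 * stats.norm.sf(abs(z))), estimate=est,
                      estimate_label="win ratio", diagnostics=diag)


def _pooled_midranks(counts: np.ndarray) -> np.ndarray:
    """Mid-rank of each level in the pooled sample, from pooled counts."""
    before = np.concatenate([[0.0], counts.cumsum()[:-1]])
    return before + (counts + 1) / 2.0


def mean_rank_difference(arm: np.ndarray, levels: np.ndarray, k: int) -> float:
    tc = np.bincount(levels[arm == 1], minlength=k).astype(float)
    cc = np.bincount(levels[arm == 0], minlength=k).astype(float)
    mr = _pooled_midranks(tc + cc)
    return float(np.sum(tc * mr) / tc.sum() - np.sum(cc * mr) / cc.sum())


def bootstrap_mean_rank_test(
    arm: np.ndarray, levels: np.ndarray, k: int,
    B: int = 1000, rng: np.random.Generator | None = None,
) -> TestResult:
    """Bootstrap the treatment-control difference in mean mid-rank.

    Within-arm resampling (B replicates); the two-sided p inverts the
    percentile interval: p = 2 min{ P*(d <= 0), P*(d >= 0) }, capped at 1 and
    floored at 2/B.  The observed rank difference is reported descriptively.
    """
    if B < 100:
        raise ValueError("bootstrap_B must be >= 100 for a stable tail estimate")
    rng = rng or np.random.default_rng(0)
    lt, lc = levels[arm == 1], levels[arm == 0]
    n1, n2 = len(lt), len(lc)
    if n1 == 0 or n2 == 0:
        return _degenerate("BS", "empty arm")
    if np.all(levels == levels[0]):
        return _degenerate("BS", "all observations tied")
    d_obs = mean_rank_difference(arm, levels, k)
    pt = np.bincount(lt, minlength=k) / n1
    pc = np.bincount(lc, minlength=k) / n2
    draws_t = rng.multinomial(n1, pt, size=B).astype(float)
    draws_c = rng.multinomial(n2, pc, size=B).astype(float)
    pooled = draws_t + draws_c
    before = np.concatenate([np.zeros((B, 1)), np.cumsum(pooled, axis=1)[:, :-1]], axis=1)
    mr = before + (pooled + 1) / 2.0
    d = (draws_t * mr).sum(axis=1) / n1 - (draws_c * mr).sum(axis=1) / n2
    p = 2 * min(float(np.mean(d <= 0)), float(np.mean(d >= 0)))
    p = min(1.0, max(p, 2.0 / B))
    return TestResult(
        "BS", p, estimate=d_obs, estimate_label="mean-rank difference",
        diagnostics={"bootstrap_B": B},
    )


def _sm_wald(model_fit, name_idx: int, method: str, label: str, exp: bool) -> TestResult:
    p = float(np.asarray(model_fit.pvalues)[name_idx])
    coef = float(np.asarray(model_fit.params)[name_idx])
    if not np.isfinite(p):
        return _degenerate(method, "non-finite Wald p")
    est = float(np.exp(coef)) if exp else coef
    return TestResult(method, p, estimate=est, estimate_label=label)


def logistic_adjusted(arm, indicator, covs: np.ndarray) -> TestResult:
    import statsmodels.api as sm

    y = indicator.astype(float)
    if y.min() == y.max():
        return _degenerate("BLR_adj", "constant outcome")
    X = sm.add_constant(np.column_stack([arm.astype(float), covs]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as e:  # perfect separation, singular matrix
        return _degenerate("BLR_adj", f"logit fit failed: {e}")
    return _sm_wald(fit, 1, "BLR_adj", "odds ratio", exp=True)


def linear_adjusted(arm, levels, covs: np.ndarray) -> TestResult:
    import statsmodels.api as sm

    y = levels.astype(float)
    if np.ptp(y) == 0:
        return _degenerate("MLR_adj", "constant outcome")
    X = sm.add_constant(np.column_stack([arm.astype(float), covs]))
    fit = sm.OLS(y, X).fit()
    return _sm_wald(fit, 1, "MLR_adj", "score coefficient", exp=False)


def olr_adjusted(arm, levels, covs: np.ndarray) -> TestResult:
    from ._ordinal import fit_po_individual

    if len(np.unique(levels)) < 2:
        return _degenerate("OLR_adj", "constant outcome")
    X = np.column_stack([arm.astype(float), covs])
    try:
        fit = fit_po_individual(levels, X)
    except (DegenerateDataError, Exception) as e:  # noqa: B014
        return _degenerate("OLR_adj", f"ordered logit fit failed: {e}")
    return TestResult("OLR_adj", fit.p_value, estimate=fit.odds_ratio,
                      estimate_label="proportional-odds OR",
                      diagnostics={"logOR": fit.beta, "se": fit.se})


def cox_model(arm, time, observed, covs: np.ndarray | None, method: str) -> TestResult:
    from ._cox import CoxError, fit_cox

    if time is None or observed is None:
        return _degenerate(method, "time-to-event data missing")
    if observed.sum() == 0:
        return _degenerate(method, "no observed events")
    X = arm.astype(float)[:, None]
    if covs is not None:
        X = np.column_stack([X, covs])
    try:
        fit = fit_cox(time, observed, X)
    except (CoxError, np.linalg.LinAlgError) as e:
        return _degenerate(method, f"Cox fit failed: {e}")
    p = float(fit.p_values[0])
    if not np.isfinite(p):
        return _degenerate(method, "non-finite Wald p")
    return TestResult(method, p, estimate=float(np.exp(fit.beta[0])),
                      estimate_label="hazard ratio")


# ---------------------------------------------------------------------------
# battery orchestration
# ---------------------------------------------------------------------------


def dataset_arrays(dataset: ComparatorDataset, scale: OrdinalScale) -> dict:
    """Extract the numpy arrays the battery operates on."""
    scale = get_scale(scale)
    recs = dataset.records
    arm = np.array([1 if r.arm == TREATMENT else 0 for r in recs])
    if set(np.unique(arm)) != {0, 1}:
        # generic two-arm data: first arm seen = treatment
        first = recs[0].arm
        arm = np.array([1 if r.arm == first else 0 for r in recs])
    levels = np.array([scale.level_of(r) for r in recs])
    covs = np.column_stack(
        [[r.age for r in recs], [r.sex for r in recs], [r.diabetes for r in recs]]
    ).astype(float)
    # standardise covariates: treatment Wald p is invariant to affine
    # covariate transforms and the fits condition far better
    sd = covs.std(axis=0)
    covs = (covs - covs.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if all(r.time is not None for r in recs):
        time = np.array([r.time for r in recs], dtype=float)
        observed = np.array([r.observed for r in recs], dtype=int)
    else:
        time = observed = None
    return {"arm": arm, "levels": levels, "covs": covs, "time": time,
            "observed": observed, "k": scale.n_levels,
            "fatal_level": scale.fatal_level}


def run_single(
    method: str, arrays: dict, config: BatteryConfig, rng=None
) -> TestResult:
    """Run one named method on prepared arrays."""
    arm, levels, k = arrays["arm"], arrays["levels"], arrays["k"]
    if method == "CSB":
        return chi2_binary(arm, (levels > 0), "CSB")
    if method == "CSF":
        return chi2_binary(arm, (levels == arrays["fatal_level"]), "CSF")
    if method == "CSO":
        return chi2_ordinal(arm, levels, k)
    if method == "CAT":
        return cochran_armitage(arm, levels)
    if method == "MWU":
        return mann_whitney(arm, levels)
    if method == "MT":
        return median_test(arm, levels)
    if method == "TT":
        return t_test(arm, levels)
    if method == "OLR":
        return olr_unadjusted(arm, levels, k)
    if method == "OLR_adj":
        return olr_adjusted(arm, levels, arrays["covs"])
    if method == "BLR_adj":
        return logistic_adjusted(arm, (levels > 0), arrays["covs"])
    if method == "MLR_adj":
        return linear_adjusted(arm, levels, arrays["covs"])
    if method == "CPH":
        return cox_model(arm, arrays["time"], arrays["observed"], None, "CPH")
    if method == "CPH_adj":
        return cox_model(arm, arrays["time"], arrays["observed"], arrays["covs"], "CPH_adj")
    if method == "WR":
        return win_ratio_test(arm, levels, k, B=config.bootstrap_B, rng=rng)
    if method == "BS":
        return bootstrap_mean_rank_test(arm, levels, k, B=config.bootstrap_B, rng=rng)
    raise KeyError(f"unknown method {method!r}")


def run_battery(
    dataset: ComparatorDataset,
    scale: OrdinalScale | str,
    config: BatteryConfig | None = None,
) -> list[TestResult]:
    """Apply all fifteen methods to one comparator dataset.

    Returns exactly 15 results in canonical :data:`METHODS` order.  The
    resampling-based methods (WR fallback, BS) draw from a stream derived
    from ``config.seed`` and the dataset id, so battery results do not
    depend on execution order.
    """
    config = config or BatteryConfig()
    scale = get_scale(scale)
    arrays = dataset_arrays(dataset, scale)
    # stable across processes (str hash is salted per interpreter run)
    stream = zlib.crc32(dataset.id.encode("utf-8")) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, stream]))
    results = [run_single(m, arrays, config, rng=rng) for m in METHODS]
    if config.po_check:
        # proportional-odds assumption check attached to the OLR diagnostics
        try:
            stat, p, df = po_score_test(arrays["levels"], arrays["arm"].astype(float))
            for r in results:
                if r.method == "OLR":
                    r.diagnostics["po_score_p"] = p
                    r.diagnostics["po_score_df"] = df
        except Exception as e:  # pragma: no cover - diagnostic only
            log.warning("proportional-odds score test failed: %s", e)
    return results


def proportional_odds_score_test(
    dataset: ComparatorDataset, scale, adjusted: bool = False
) -> float:
    """Score-test p-value for the proportional-odds assumption.

    With ``adjusted=True`` the constrained model includes the standard
    covariates and the alternative frees every slope per cut.  Returns NaN
    for outcomes with fewer than three observed levels (assumption vacuous).
    """
    arrays = dataset_arrays(dataset, get_scale(scale))
    X = arrays["arm"].astype(float)[:, None]
    if adjusted:
        X = np.column_stack([X, arrays["covs"]])
    _, p, _ = po_score_test(arrays["levels"], X)
    return p


def results_to_frame(results_by_dataset: dict[str, list[TestResult]]) -> pd.DataFrame:
    """Tidy CSV-ready table: one row per dataset x method."""
    rows = []
    for ds_id, results in results_by_dataset.items():
        for r in results:
            rows.append(
                {"dataset": ds_id, "method": r.method, "p_value": r.p_value,
                 "estimate": r.estimate, "degenerate": r.degenerate}
            )
    return pd.DataFrame(rows)
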