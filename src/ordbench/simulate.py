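"""Synthetic comparator datasets for low-event-rate prevention trials.

The generator emulates the statistical structure the downstream analyses
assume: an ordered severity outcome whose cumulative odds are shifted by a
single common treatment log odds ratio (proportional odds by construction),
covariates (age, sex, diabetes) that shift the odds of having any event,
and exponential event times administratively censored at the end of
follow-up.

Construction per participant with covariates x in arm a (a = 1 treatment):

    lambda_j(x) = logit( p_event(x) * Q_j )        j = 1..k-1
    P(level >= j | x, a) = expit( lambda_j(x) + a * treatment_logOR )

where ``p_event(x)`` is the baseline event probability shifted by the
covariate log-odds effects and ``Q_j`` is the baseline probability of
severity >= j given an event (Q_1 = 1).  Because the same shift is applied
to every cut, the treatment effect is exactly proportional-odds given x,
while covariates act on event occurrence only.

Randomness contract: every public operation takes an integer seed and uses
``numpy.random.SeedSequence([seed, stream])`` internally, so replicate
streams are reproducible independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping

import numpy as np
import yaml
from scipy import special

from .trial_model import (
    CONTROL,
    TREATMENT,
    ComparatorDataset,
    OrdinalScale,
    ParticipantRecord,
    get_scale,
)

__all__ = [
    "SimulationConfig",
    "simulate_comparator",
    "simulate_null",
    "resample_with_replacement",
    "simulate_level_arrays",
    "BASELINE_PROBS",
    "load_simulation_config",
]

#: Baseline (control-arm) category probabilities used in the study scenarios,
#: index 0 = no event.  Event rates sit in the 6-12% range typical of the
#: prevention trials being emulated.
BASELINE_PROBS: dict[str, tuple[float, ...]] = {
    "stroke3": (0.90, 0.07, 0.03),
    "strokeTIA4": (0.88, 0.04, 0.05, 0.03),
    "stroke5": (0.90, 0.04, 0.03, 0.02, 0.01),
    "stroke8": (0.90, 0.030, 0.022, 0.016, 0.012, 0.008, 0.007, 0.005),
    "mi3": (0.92, 0.05, 0.03),
    "bleed4": (0.94, 0.03, 0.02, 0.01),
}


@dataclass
class SimulationConfig:
    """Parameters of one simulated two-arm comparison.

    ``treatment_logOR`` is the common log odds ratio on the "level >= j"
    cumulative scale; negative values mean benefit (fewer, less severe
    events).  ``covariate_effects`` are per-unit log-odds effects on event
    occurrence; age enters centred at ``age_mean`` so the marginal event rate
    stays close to ``baseline_probs``.
    """

    scale: str | OrdinalScale = "stroke3"
    n_per_arm: int = 2000
    baseline_probs: tuple[float, ...] | None = None
    treatment_logOR: float = 0.0
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.03, "sex": -0.2, "diabetes": 0.5}
    )
    age_mean: float = 65.0
    age_sd: float = 10.0
    sex_prob: float = 0.45
    diabetes_prob: float = 0.20
    followup_days: float = 1825.0
    event_rate_hazard: float = 1.0 / 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.scale = get_scale(self.scale)
        if self.baseline_probs is None:
            self.baseline_probs = BASELINE_PROBS.get(
                self.scale.name, _default_probs(self.scale.n_levels)
            )
        p = np.asarray(self.baseline_probs, dtype=float)
        if len(p) != self.scale.n_levels:
            raise ValueError(
                f"baseline_probs length {len(p)} != {self.scale.n_levels} levels"
            )
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("baseline_probs must be >= 0 and sum to 1")
        if np.any(p >= 1.0):
            raise ValueError("degenerate baseline_probs: a category has mass 1")
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        self.baseline_probs = tuple(p)


def _default_probs(k: int) -> tuple[float, ...]:
    sev = np.array([0.5 ** i for i in range(1, k)])
    sev = 0.10 * sev / sev.sum()
    return tuple(np.concatenate([[0.90], sev]))


def _rng_for(seed: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _draw_arm(cfg: SimulationConfig, rng: np.random.Generator, n: int, arm: int):
    """Vectorised draw of covariates, levels and times for ``n`` participants."""
    p = np.asarray(cfg.baseline_probs)
    k = len(p)
    age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    sex = (rng.random(n) < cfg.sex_prob).astype(int)
    diab = (rng.random(n) < cfg.diabetes_prob).astype(int)
    eff = cfg.covariate_effects
    xb = (
        eff.get("age", 0.0) * (age - cfg.age_mean)
        + eff.get("sex", 0.0) * (sex - cfg.sex_prob)
        + eff.get("diabetes", 0.0) * (diab - cfg.diabetes_prob)
    )
    p_event0 = special.expit(special.logit(1.0 - p[0]) + xb)       # (n,)
    tail = p[1:][::-1].cumsum()[::-1]                               # P0(level >= j), j=1..k-1
    Q = tail / (1.0 - p[0])                                         # P0(sev >= j | event), Q_1 = 1
    lam = special.logit(np.clip(p_event0[:, None] * Q[None, :], 1e-12, 1 - 1e-12))
    cum = special.expit(lam + arm * cfg.treatment_logOR)            # (n, k-1), decreasing in j
    u = rng.random(n)
    level = (u[:, None] < cum).sum(axis=1)
    # exponential event times truncated at follow-up; censored otherwise
    h, T = cfg.event_rate_hazard, cfg.followup_days
    ev = level > 0
    t = np.full(n, float(T))
    if ev.any():
        v = rng.random(int(ev.sum()))
        t[ev] = -np.log1p(-v * (1.0 - np.exp(-h * T))) / h
    return {
        "age": age, "sex": sex, "diabetes": diab, "level": level,
        "time": t, "observed": ev.astype(int),
    }


def _records_from_arrays(cfg: SimulationConfig, arrays, arm_labels) -> list[ParticipantRecord]:
    scale: OrdinalScale = cfg.scale  # type: ignore[assignment]
    recs = []
    for i, lab in enumerate(arm_labels):
        lev = int(arrays["level"][i])
        event, fatal, attr = scale.attributes_for_level(lev)
        recs.append(
            ParticipantRecord(
                arm=lab,
                age=float(arrays["age"][i]),
                sex=int(arrays["sex"][i]),
                diabetes=int(arrays["diabetes"][i]),
                event=event,
                fatal=fatal,
                severity_attr=attr,
                time=float(arrays["time"][i]),
                observed=int(arrays["observed"][i]),
            )
        )
    return recs


def simulate_comparator(
    config: SimulationConfig, dataset_id: str = "sim", tags=None, stream: int = 0
) -> ComparatorDataset:
    """Simulate one comparator dataset under the configured treatment effect.

    Deterministic given ``config.seed`` and ``stream`` (replicate index).
    """
    rng = _rng_for(config.seed, stream)
    at = _draw_arm(config, rng, config.n_per_arm, arm=1)
    ac = _draw_arm(config, rng, config.n_per_arm, arm=0)
    merged = {key: np.concatenate([at[key], ac[key]]) for key in at}
    labels = [TREATMENT] * config.n_per_arm + [CONTROL] * config.n_per_arm
    return ComparatorDataset(
        id=dataset_id,
        records=_records_from_arrays(config, merged, labels),
        tags=dict(tags or {}),
    )


def simulate_null(
    config: SimulationConfig, dataset_id: str = "null", tags=None, stream: int = 0
) -> ComparatorDataset:
    """Simulate a dataset with a neutral dummy treatment.

    The treatment effect is forced to zero and the arm label is assigned by
    an independent fair coin per participant, so any apparent treatment
    difference can only occur by chance.  Labels are redrawn in the rare case
    a tiny sample leaves an arm with fewer than two participants.
    """
    cfg = dc_replace(config, treatment_logOR=0.0)
    rng = _rng_for(config.seed, stream)
    n = 2 * cfg.n_per_arm
    arrays = _draw_arm(cfg, rng, n, arm=0)
    while True:
        coin = rng.integers(0, 2, n)
        if 2 <= coin.sum() <= n - 2:
            break
    labels = [TREATMENT if c else CONTROL for c in coin]
    return ComparatorDataset(
        id=dataset_id,
        records=_records_from_arrays(cfg, arrays, labels),
        tags=dict(tags or {}),
    )


def simulate_level_arrays(config: SimulationConfig, null: bool = False, stream: int = 0):
    """Array fast path: return ``(arm, level)`` without building records.

    Produces the same joint distribution as :func:`simulate_comparator` /
    :func:`simulate_null` (covariates and times are drawn but discarded);
    used where only the ordinal outcome is needed, e.g. resampling studies.
    """
    if null:
        cfg = dc_replace(config, treatment_logOR=0.0)
        rng = _rng_for(config.seed, stream)
        n = 2 * cfg.n_per_arm
        arrays = _draw_arm(cfg, rng, n, arm=0)
        while True:
            coin = rng.integers(0, 2, n)
            if 2 <= coin.sum() <= n - 2:
                break
        return coin, arrays["level"]
    rng = _rng_for(config.seed, stream)
    at = _draw_arm(config, rng, config.n_per_arm, arm=1)
    ac = _draw_arm(config, rng, config.n_per_arm, arm=0)
    arm = np.concatenate([np.ones(config.n_per_arm, int), np.zeros(config.n_per_arm, int)])
    return arm, np.concatenate([at["level"], ac["level"]])


def resample_with_replacement(
    dataset: ComparatorDataset, seed: int, stream: int = 0
) -> ComparatorDataset:
    """Draw a bootstrap replicate: same total size, rows i.i.d. from the pool.

    Rows keep their arm labels; the draw is repeated in the (tiny-sample)
    case where it fails the two-arm validity invariants.
    """
    if not dataset.records:
        raise ValueError("cannot resample an empty dataset")
    rng = _rng_for(seed, stream)
    n = len(dataset.records)
    while True:
        idx = rng.integers(0, n, n)
        arms = {dataset.records[i].arm for i in idx}
        if len(arms) == 2 and all(
            sum(dataset.records[i].arm == a for i in idx) >= 2 for a in arms
        ):
            break
    return ComparatorDataset(
        id=f"{dataset.id}_boot{stream}",
        records=[dataset.records[i] for i in idx],
        tags=dict(dataset.tags),
    )


def load_simulation_config(path) -> SimulationConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if "baseline_probs" in raw and raw["baseline_probs"] is not None:
        raw["baseline_probs"] = tuple(raw["baseline_probs"])
    return SimulationConfig(**raw)
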