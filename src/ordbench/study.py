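"""End-to-end study replica: simulate -> battery -> compare -> reports.

A :class:`StudyConfig` describes one or more simulation scenarios (each a
simulation configuration plus a replicate count).  :func:`run_study`
produces, per scenario, the tidy battery results, the overall rating table,
optional subgroup tables, sample-size multipliers estimated from the
simulated datasets, and a bootstrap type-I-error table, all written as CSV
with a manifest that records every seed so the bundle is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .battery import BatteryConfig, run_battery, results_to_frame
from .compare import assess_type1_error, compare_by_subgroup, compare_methods, render_rating_table
from .samplesize import estimate_effects, multiplier_report, n_binary, n_mwu, n_olr, n_ttest
from .simulate import SimulationConfig, simulate_comparator, simulate_null
from .trial_model import get_scale

log = logging.getLogger(__name__)


@dataclass
class Scenario:
    name: str
    sim: SimulationConfig
    n_datasets: int = 10
    tags_cycle: tuple[dict, ...] = ()  # optional per-dataset metadata tags


@dataclass
class StudyConfig:
    scenarios: list[Scenario]
    battery: BatteryConfig = field(default_factory=BatteryConfig)
    subgroup_tags: tuple[str, ...] = ()
    type1_B: int = 1000
    type1_methods: tuple[str, ...] = ("MWU", "OLR")
    seed: int = 0
    out_dir: str = "study_out"

    def __post_init__(self) -> None:
        for sc in self.scenarios:
            if sc.n_datasets < 1:
                raise ValueError("replicate counts must be >= 1")
            get_scale(sc.sim.scale)  # raises on undefined scales


def load_study_config(path) -> StudyConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    scenarios = []
    for s in raw["scenarios"]:
        sim = dict(s.get("sim", {}))
        if "baseline_probs" in sim and sim["baseline_probs"] is not None:
            sim["baseline_probs"] = tuple(sim["baseline_probs"])
        scenarios.append(
            Scenario(
                name=s["name"],
                sim=SimulationConfig(**sim),
                n_datasets=int(s.get("n_datasets", 10)),
                tags_cycle=tuple(s.get("tags_cycle", ())),
            )
        )
    battery = BatteryConfig(**raw.get("battery", {}))
    return StudyConfig(
        scenarios=scenarios,
        battery=battery,
        subgroup_tags=tuple(raw.get("subgroup_tags", ())),
        type1_B=int(raw.get("type1_B", 1000)),
        type1_methods=tuple(raw.get("type1_methods", ("MWU", "OLR"))),
        seed=int(raw.get("seed", 0)),
        out_dir=raw.get("out_dir", "study_out"),
    )


def run_study(config: StudyConfig) -> dict:
    """Run the full pipeline; returns a manifest of what was written.

    Datasets whose battery fails are excluded with a logged error and
    counted in the manifest (never silently dropped).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "scenarios": {},
    }
    for scen in config.scenarios:
        sdir = out / scen.name
        sdir.mkdir(exist_ok=True)
        scale = get_scale(scen.sim.scale)
        sim = replace(scen.sim, seed=config.seed)
        results, tags_by_ds, datasets = {}, {}, {}
        failures = 0
        for i in range(scen.n_datasets):
            ds_id = f"{scen.name}_{i:03d}"
            tags = dict(scen.tags_cycle[i % len(scen.tags_cycle)]) if scen.tags_cycle else {}
            try:
                ds = simulate_comparator(sim, dataset_id=ds_id, tags=tags, stream=i)
                results[ds_id] = run_battery(ds, scale, config.battery)
                tags_by_ds[ds_id] = tags
                datasets[ds_id] = ds
            except Exception as e:
                failures += 1
                log.error("dataset %s failed and was excluded: %s", ds_id, e)
        if len(results) < 2:
            raise RuntimeError(f"scenario {scen.name}: fewer than 2 usable datasets")
        tidy = results_to_frame(results)
        tidy.to_csv(sdir / "battery.csv", index=False)
        rm, grouping, table = compare_methods(results, alpha=config.battery.alpha)
        table.to_csv(sdir / "rating.csv", index=False)
        (sdir / "rating.txt").write_text(
            render_rating_table(table, title=f"{scen.name} (Friedman p={grouping.friedman_p:.3g})")
        )
        for tag in config.subgroup_tags:
            try:
                sub = compare_by_subgroup(results, tags_by_ds, tag, alpha=config.battery.alpha)
            except KeyError:
                log.warning("scenario %s: tag %r absent, subgroup table skipped", scen.name, tag)
                continue
            for value, st in sub.items():
                st.to_csv(sdir / f"rating_{tag}_{value}.csv", index=False)
        # sample-size multipliers from the simulated datasets
        rows = []
        for ds_id, ds in datasets.items():
            try:
                eff = estimate_effects(ds, scale)
                rows.append(
                    {
                        "dataset": ds_id,
                        "n_binary": n_binary(*eff.p_event),
                        "n_ordinal": n_olr(eff.pbar, eff.or_po),
                        "n_mwu": n_mwu(eff.p_win),
                        "n_ttest": n_ttest(eff.delta, eff.sd),
                    }
                )
            except ValueError as e:
                log.warning("dataset %s: sample sizes skipped (%s)", ds_id, e)
        if rows:
            per_row, summary = multiplier_report(pd.DataFrame(rows))
            per_row.to_csv(sdir / "samplesize.csv", index=False)
            summary.to_csv(sdir / "samplesize_summary.csv")
        # bootstrap type-I error on a matching null dataset
        null_ds = simulate_null(replace(scen.sim, seed=config.seed), stream=10_000)
        counts = assess_type1_error(
            null_ds, scale, methods=config.type1_methods,
            B=config.type1_B, alpha=config.battery.alpha, seed=config.seed,
        )
        pd.DataFrame(
            [{"method": m, "significant": c, "B": config.type1_B} for m, c in counts.items()]
        ).to_csv(sdir / "type1.csv", index=False)
        manifest["scenarios"][scen.name] = {
            "n_datasets": scen.n_datasets,
            "failed_datasets": failures,
            "friedman_p": grouping.friedman_p,
            "scale": scale.name,
            "sim": {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(sim).items() if k != "scale"},
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
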