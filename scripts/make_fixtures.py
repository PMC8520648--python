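"""Regenerate the small seeded fixtures under fixtures/.

Run from the repository root:

    python scripts/make_fixtures.py

Everything is deterministic (fixed seeds), so re-running must reproduce the
committed files byte-for-byte.
"""

from __future__ import annotations

from pathlib import Path

from ordbench.simulate import SimulationConfig, simulate_comparator, simulate_null
from ordbench.trial_model import OrdinalScale, dump_scale_yaml, write_participants_csv

ROOT = Path(__file__).resolve().parents[1]
FIX = ROOT / "fixtures"

STUDY_YAML = """\
# Minimal example study configuration (see `ordbench study --help`).
seed: 11
out_dir: study_out
type1_B: 200
type1_methods: [MWU, OLR]
subgroup_tags: [prevention]
battery:
  bootstrap_B: 300
scenarios:
  - name: stroke3_benefit
    n_datasets: 6
    tags_cycle:
      - {prevention: primary}
      - {prevention: secondary}
    sim:
      scale: stroke3
      n_per_arm: 400
      treatment_logOR: -0.3
"""


def main() -> None:
    FIX.mkdir(exist_ok=True)

    effect = simulate_comparator(
        SimulationConfig(scale="stroke3", n_per_arm=150, treatment_logOR=-0.5, seed=42),
        dataset_id="effect_stroke3",
    )
    write_participants_csv(effect.records, FIX / "effect_stroke3.csv")

    null = simulate_null(
        SimulationConfig(scale="stroke3", n_per_arm=150, treatment_logOR=0.0, seed=42),
        dataset_id="null_stroke3",
    )
    write_participants_csv(null.records, FIX / "null_stroke3.csv")

    # very rare events: most methods should declare the data degenerate
    rare = simulate_comparator(
        SimulationConfig(
            scale="mi3",
            n_per_arm=40,
            baseline_probs=(0.995, 0.004, 0.001),
            treatment_logOR=0.0,
            seed=42,
        ),
        dataset_id="rare_mi3",
    )
    write_participants_csv(rare.records, FIX / "rare_mi3.csv")

    dump_scale_yaml(
        OrdinalScale(
            name="stroke4_custom",
            levels=("none", "minor stroke", "major stroke", "fatal stroke"),
            mapping={"minor": 1, "major": 2},
            nonfatal_default=1,
        ),
        FIX / "scale_example.yaml",
    )

    (FIX / "study_example.yaml").write_text(STUDY_YAML)
    print(f"fixtures written to {FIX}")


if __name__ == "__main__":
    main()
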