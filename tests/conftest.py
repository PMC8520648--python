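"""Shared fixtures: seeded datasets and paths to the committed CSV fixtures."""

from __future__ import annotations

from pathlib import Path

import pytest

from ordbench.simulate import SimulationConfig, simulate_comparator, simulate_null
from ordbench.trial_model import ComparatorDataset, read_participants_csv

FIXTURES = Path(__file__).resolve().parents[1] / "fixtures"


@pytest.fixture(scope="session")
def fixtures_dir() -> Path:
    return FIXTURES


def _load(name: str, ds_id: str) -> ComparatorDataset:
    return ComparatorDataset(id=ds_id, records=read_participants_csv(FIXTURES / name))


@pytest.fixture(scope="session")
def effect_dataset() -> ComparatorDataset:
    """150/arm stroke3 dataset with a real benefit (log OR -0.5), seed 42."""
    return _load("effect_stroke3.csv", "effect_stroke3")


@pytest.fixture(scope="session")
def null_dataset() -> ComparatorDataset:
    """150+150 stroke3 dataset with a coin-flip dummy arm, seed 42."""
    return _load("null_stroke3.csv", "null_stroke3")


@pytest.fixture(scope="session")
def rare_dataset() -> ComparatorDataset:
    """80-participant mi3 dataset with zero events: every method degenerate."""
    return _load("rare_mi3.csv", "rare_mi3")


@pytest.fixture(scope="session")
def sim_500() -> ComparatorDataset:
    """Freshly simulated 500/arm stroke3 dataset with benefit, for power-ish
    checks that want more events than the small committed fixtures."""
    cfg = SimulationConfig(scale="stroke3", n_per_arm=500, treatment_logOR=-0.5, seed=7)
    return simulate_comparator(cfg, dataset_id="sim500")


@pytest.fixture(scope="session")
def null_2000() -> ComparatorDataset:
    """2000/arm neutral stroke3 dataset matching the published bootstrap setup."""
    cfg = SimulationConfig(scale="stroke3", n_per_arm=2000, treatment_logOR=0.0, seed=3)
    return simulate_null(cfg, dataset_id="null2000")
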