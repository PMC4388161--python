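"""Shared fixtures: deterministic RNGs and a small cached sweep."""

from __future__ import annotations

import numpy as np
import pytest

from coopnet.evolve import EvolutionConfig
from coopnet.experiments import SweepConfig, run_sweep, structure_table


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


# A compact sweep shared by the analysis-layer tests: three structures that
# span the modularity range, enough runs for stable medians.
SMALL_SWEEP_STRUCTURES = ("1-Full", "15-Lattice2D", "14-BA")


@pytest.fixture(scope="session")
def small_sweep():
    config = SweepConfig(
        structures=SMALL_SWEEP_STRUCTURES,
        runs_per_batch=8,
        max_batches=1,
        base_seed=2024,
        evolution=EvolutionConfig(max_generations=20_000),
    )
    return run_sweep(config)


@pytest.fixture(scope="session")
def small_sweep_metrics():
    return structure_table(list(SMALL_SWEEP_STRUCTURES))
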