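"""Shared fixtures.

The expensive fixtures (trained networks) are session-scoped and lazy:
only the tests that need them trigger training.  Problem sizes are the
desk-scale defaults documented in docs/methods.md, chosen so the full
suite trains every network on one CPU core.
"""

import numpy as np
import pytest

from gridmind.env import Arena, SelfMotionSpec
from gridmind.maps import SMCSpec
from gridmind.models import (
    HCMECModel,
    PathIntegratorModel,
    PlannerConfig,
    PlannerModel,
    TrainConfig,
    World,
)


@pytest.fixture(scope="session")
def pi_world():
    """Two grid modules (periods 30 and 49.5 cm) of 64 cells each."""
    return World.build(0, arena=Arena(150.0, 150.0, 2.0),
                       n_modules=2, cells_per_module=64)


@pytest.fixture(scope="session")
def pi_results(pi_world):
    """Path integrator trained on 5-s trajectories."""
    model = PathIntegratorModel(pi_world, n_hidden=128)
    return model.fit(TrainConfig(variant="GC_ONLY", n_steps=9000,
                                 learning_rate=2e-3, seed=0))


@pytest.fixture(scope="session")
def hcmec_world():
    return World.build(
        5, arena=Arena(150.0, 150.0, 2.0), n_modules=2, cells_per_module=32,
        smc_spec=SMCSpec(n_cells=64, correlation_length=10.0),
    )


@pytest.fixture(scope="session")
def hcmec_results(hcmec_world):
    """Full loop trained with masking ratio 0.9."""
    model = HCMECModel(hcmec_world, n_hidden=192)
    return model.fit(TrainConfig(variant="HCMEC", r_mask=0.9, n_steps=6000,
                                 learning_rate=2e-3, seed=0))


@pytest.fixture(scope="session")
def gc6_world():
    """Six-module hierarchy (largest period 3.7 m) for planner pretraining."""
    return World.build(11, arena=Arena(150.0, 150.0, 2.0),
                       n_modules=6, cells_per_module=16)


@pytest.fixture(scope="session")
def gc6_results(gc6_world):
    model = PathIntegratorModel(gc6_world, n_hidden=128)
    return model.fit(TrainConfig(variant="GC_ONLY", n_steps=4000,
                                 learning_rate=2e-3, seed=0))


@pytest.fixture(scope="session")
def planner_gc_results(gc6_results):
    """Planner subnetwork on the frozen grid-only network."""
    model = PlannerModel(gc6_results, PlannerConfig(planner_dim=64,
                                                    train_horizon=80,
                                                    n_pairs=128))
    return model.fit(TrainConfig(variant="PLANNER_GC", n_steps=1500,
                                 learning_rate=2e-3, seed=0))


@pytest.fixture(scope="session")
def planner_hcmec_results(hcmec_results):
    """Planner on the frozen full loop (reconstructs SMC along the path)."""
    model = PlannerModel(hcmec_results, PlannerConfig(planner_dim=64,
                                                      train_horizon=60,
                                                      n_pairs=128))
    return model.fit(TrainConfig(variant="PLANNER_HCMEC", n_steps=800,
                                 learning_rate=2e-3, seed=0))


def small_hcmec_world(seed: int) -> World:
    return World.build(
        seed,
        arena=Arena(150.0, 150.0, 2.0),
        n_modules=2,
        cells_per_module=24,
        smc_spec=SMCSpec(n_cells=48, correlation_length=10.0),
        selfmotion=SelfMotionSpec(n_dir_cells=16, n_speed_cells=6),
    )


@pytest.fixture(scope="session")
def mask_trend_runs():
    """Small full-loop networks at low and high masking, three seeds."""
    out = {}
    for seed in (0, 1, 2):
        world = small_hcmec_world(100 + seed)
        for r_mask in (0.1, 0.9):
            model = HCMECModel(world, n_hidden=96)
            out[(seed, r_mask)] = model.fit(
                TrainConfig(variant="HCMEC", r_mask=r_mask, n_steps=3500,
                            learning_rate=2e-3, seed=seed)
            )
    return out
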