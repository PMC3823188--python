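import numpy as np
import pytest

import crossfeed as cf
from crossfeed.config import MediumSpec, SimulationConfig
from crossfeed.protocols import Protocol, run_spatial

#: seeds shared by the replicate-averaged community experiments
SEEDS = (3, 11, 19)


def small_sim(seed, **kw):
    """Reduced-scale spatial setup used across the slower tests: a
    240x240 um periodic pad, stopping by generation count."""
    defaults = dict(
        domain_um=(240.0, 240.0),
        community_height_um=180.0,
        max_hours=110.0,
        rng_seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def panel():
    return list(cf.default_panel(0.02, 0.0))


@pytest.fixture(scope="session")
def comp_runs():
    """Competition control: supplemented medium, 2% cheater advantage,
    random 1:1:1 lawn at 3000 cells/mm^2, to generation 7."""
    proto = Protocol(init="random_lawn", density=3000.0)
    runs = []
    for seed in SEEDS:
        strains = list(cf.default_panel(0.02, 0.0))
        sim = small_sim(seed, target_generations=7.0)
        runs.append(run_spatial(strains, MediumSpec.supplemented(), sim, proto))
    return runs


@pytest.fixture(scope="session")
def coch_runs():
    """Cooperation & cheating: no supplements, 2% advantage, generation 6."""
    proto = Protocol(init="random_lawn", density=3000.0)
    runs = []
    for seed in SEEDS:
        strains = list(cf.default_panel(0.02, 0.0))
        sim = small_sim(seed, target_generations=6.0)
        runs.append(run_spatial(strains, MediumSpec.unsupplemented(), sim, proto))
    return runs


@pytest.fixture(scope="session")
def coch8_runs():
    """Cooperation & cheating with the larger (8%) intrinsic advantage
    (also the baseline for the delocalization variants)."""
    proto = Protocol(init="random_lawn", density=3000.0)
    runs = []
    for seed in SEEDS[:2]:
        strains = list(cf.default_panel(0.08, 0.0))
        sim = small_sim(seed, target_generations=5.5)
        runs.append(run_spatial(strains, MediumSpec.unsupplemented(), sim, proto))
    return runs


def final_ratio(traj):
    return float(traj.series["ratio"].iloc[-1])


def final_a3d(traj):
    return float(traj.series["association_3d"].iloc[-1])
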