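import numpy as np
import pytest

from gazegraph import (AOIGrid, FixationEvent, ScanPath, SimulationConfig,
                       simulate_cohort)


@pytest.fixture(scope="session")
def grid() -> AOIGrid:
    return AOIGrid()


@pytest.fixture(scope="session")
def fig1_edges() -> list[tuple[int, int]]:
    """The worked 144-node example graph: four unit-weight links."""
    return [(1, 73), (2, 72), (72, 73), (72, 144)]


def make_scanpath(fixations, green_side="left", participant="P001", trial=1):
    """Build a ScanPath from (onset, dur, x, y) tuples."""
    return ScanPath(
        participant, trial,
        [FixationEvent(participant, trial, *f) for f in fixations],
        green_side=green_side)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced simulated cohort shared by pipeline-level tests."""
    cfg = SimulationConfig(n_per_group=4, trials_per_participant=6, seed=20240)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(987)
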