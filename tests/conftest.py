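"""Shared fixtures: scenarios, fast solver configs, cached field runs.

FDTD runs are the expensive part of this suite, so multistatic sweeps used
by several tests are computed once per session.  The "fast" configuration
(2 mm grid, lean padding, looser ring-down threshold) is accurate to a few
permille on probe values — plenty for every qualitative check; quantitative
oracle comparisons configure their own grids.
"""

import numpy as np
import pytest

from mwtomo.acquisition import simulate_dataset
from mwtomo.forward import SimConfig
from mwtomo.media import MATERIALS, DebyeMedium
from mwtomo.scenario import CylinderTarget, Scenario, default_single_target


@pytest.fixture(scope="session")
def glycerine():
    return MATERIALS["glycerine_water_90"]


@pytest.fixture(scope="session")
def fast_sim():
    return SimConfig(dx=2e-3, convergence_rtol=1e-7, margin=0.012)


@pytest.fixture(scope="session")
def empty_scenario():
    return Scenario()


@pytest.fixture(scope="session")
def pec_scenario():
    from mwtomo.scenario import PEC

    return Scenario().with_targets(default_single_target(medium=PEC))


TEST_FREQS = [1.5e9, 2.0e9]


@pytest.fixture(scope="session")
def ds_empty(empty_scenario, fast_sim):
    """Target-free 8-antenna sweep at 1.5 / 2.0 GHz (fast grid)."""
    return simulate_dataset(empty_scenario, TEST_FREQS, fast_sim)


@pytest.fixture(scope="session")
def ds_pec(pec_scenario, fast_sim):
    """Same sweep with a 16 mm PEC cylinder at the default offset position."""
    return simulate_dataset(pec_scenario, TEST_FREQS, fast_sim)


@pytest.fixture(scope="session")
def ds_water(fast_sim):
    scen = Scenario().with_targets(default_single_target(MATERIALS["water"]))
    return simulate_dataset(scen, TEST_FREQS, fast_sim)
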