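"""Shared fixtures: compiled-kernel warmup and small reusable networks."""

import logging

import numpy as np
import pytest

from burdendmf import (
    DMFParameters,
    FICWeights,
    StructuralConnectome,
    integrate,
    log_normalize,
)
from burdendmf.bold import rates_to_bold
from burdendmf.dmf import simulate_mean_rates
from burdendmf.synthetic import gen_connectome


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Trigger numba compilation once so test timings reflect the tests."""
    sc = StructuralConnectome(np.zeros((2, 2)))
    p = DMFParameters()
    fic = FICWeights(np.ones(2))
    sim = integrate(sc, fic, None, p, 50.0, seed=0)
    simulate_mean_rates(sc, fic, None, p, 10.0, 20.0, seed=0)
    rates_to_bold(sim.r_E, p.dt)


@pytest.fixture(scope="session", autouse=True)
def _quiet_logs():
    """Silence expected-warning chatter (gain clamps, FC zero-variance)."""
    logging.getLogger("burdendmf").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_sc():
    """An 8-node normalized connectome used across unit tests."""
    return log_normalize(gen_connectome(8, seed=0))


@pytest.fixture(scope="session")
def single_node_sc():
    return StructuralConnectome(np.zeros((1, 1)))
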