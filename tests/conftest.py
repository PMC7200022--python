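import numpy as np
import pytest

import adexfield as af


@pytest.fixture(scope="session")
def eif():
    """Default neuron parameters without adaptation."""
    return af.NeuronParams().without_adaptation()


@pytest.fixture(scope="session")
def adex():
    """Default neuron parameters with adaptation (a=15 nS, b=40 pA)."""
    return af.NeuronParams()


@pytest.fixture(scope="session")
def table(eif):
    """Default transfer table (built once per machine, then disk-cached)."""
    return af.default_table(eif)


@pytest.fixture(scope="session")
def small_table(eif):
    """Coarse transfer table for tests that only need qualitative accuracy."""
    grid = af.GridSpec(np.arange(-1.0, 3.0 + 1e-9, 0.1),
                       np.logspace(np.log10(0.5), np.log10(4.0), 8))
    return af.build_tables(eif, grid)


def constant_rate_table(rate_kHz: float, vmean: float = -60.0,
                        tau: float = 10.0) -> af.TransferTable:
    """Degenerate transfer table returning fixed outputs everywhere; lets the
    mean-field synapse/adaptation equations be probed at a pinned rate."""
    grid = af.GridSpec(np.array([-100.0, 100.0]), np.array([0.01, 100.0]))
    shape = (2, 2)
    return af.TransferTable(grid, np.full(shape, rate_kHz),
                            np.full(shape, vmean), np.full(shape, tau))
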