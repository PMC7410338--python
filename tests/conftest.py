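"""Shared fixtures: default model objects and the (expensive) full sweep."""

from __future__ import annotations

import pytest

from thermaxon import (
    AxonSpec,
    ChannelSet,
    MembraneSpec,
    RobustnessCriterion,
    SolverSettings,
    SweepGrid,
    run_sweep,
)


@pytest.fixture(scope="session")
def axon():
    return AxonSpec()


@pytest.fixture(scope="session")
def membrane():
    return MembraneSpec()


@pytest.fixture(scope="session")
def channels():
    return ChannelSet()


@pytest.fixture(scope="session")
def full_table():
    """The complete velocity database: 256 models x 3 diameters x 6 temperatures.

    Computed once per session (a few minutes) and shared by every sweep-level
    statistic test.
    """
    return run_sweep(SweepGrid())


@pytest.fixture(scope="session")
def tiny_grid():
    """A 16-model grid for fast sweep-machinery tests."""
    return SweepGrid(
        q10_values=(1.5, 4.0),
        diameters_um=(3.0, 6.0),
        temperatures=(10.0, 20.0),
    )


@pytest.fixture(scope="session")
def tiny_table(tiny_grid):
    return run_sweep(tiny_grid)


@pytest.fixture(scope="session")
def criterion():
    return RobustnessCriterion()
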