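"""Shared fixtures: all test data is generated programmatically at run time."""

from __future__ import annotations

import numpy as np
import pytest

import modemdwi as m


@pytest.fixture(scope="session")
def protocol13() -> m.AcquisitionProtocol:
    """The default 13-b-value simulation protocol."""
    return m.AcquisitionProtocol()


@pytest.fixture(scope="session")
def cellsize_sets(protocol13):
    """Small/large cell-size substrates simulated at reduced scale.

    Two substrates per class (radii 3 and 5 um vs 8 and 10 um), three walker
    repeats each -- big enough for classification tests, small enough to
    simulate in a few seconds.
    """
    specs = [s for s in m.enumerate_substrates()
             if s.group_id == "cell_size" and s.level_index in (1, 3, 6, 8)]
    walkers = m.WalkerConfig(n_walkers=600, n_steps=400, seed=11)
    return m.generate_dataset(specs, protocol13, walkers,
                              n_sim_repeats=3, box_cells=36)


@pytest.fixture(scope="session")
def cellsize_table(cellsize_sets):
    """Cell-size signal table doped at 5% noise, 25 reps per decay."""
    return m.add_rician_noise(cellsize_sets,
                              m.NoiseSpec(level=0.05, n_reps=25, seed=3))
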