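"""Shared fixtures: default configs and one cached coarse detonation."""

from __future__ import annotations

import numpy as np
import pytest

from blasthead.blast_source import ChargeSpec, detonate_1d
from blasthead.materials import load_materials
from blasthead.tissue_column import load_columns


@pytest.fixture(scope="session")
def materials():
    return load_materials()


@pytest.fixture(scope="session")
def columns(materials):
    return load_columns(materials=materials)


@pytest.fixture(scope="session")
def coarse_blast():
    """250 g TNT at 1 m on a coarse (4 mm) grid, with the final state."""
    trace, state = detonate_1d(
        ChargeSpec(0.25), 1.0, cell_size=4.0e-3, end_time=5.0e-3, return_state=True
    )
    return trace, state


@pytest.fixture()
def rng():
    return np.random.default_rng(20140)
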