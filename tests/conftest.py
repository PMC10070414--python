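"""Shared fixtures: small precomputed trajectories and structures.

Everything is generated at run time from seeds; module- and session-scoped
fixtures keep the expensive solver runs shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from spinodal import (CHParams, GridSpec, UniformInitSpec, VoxelStructure,
                      filter_artifacts, init_uniform, simulate,
                      threshold_extract)


@pytest.fixture(scope="session")
def default_params() -> CHParams:
    return CHParams()


@pytest.fixture(scope="session")
def traj32(default_params):
    """32^3 symmetric-mixture trajectory, 25 saves (shared, read-only)."""
    grid = default_params.make_grid((32, 32, 32))
    params = CHParams(n_saves=25)
    init = init_uniform(grid, UniformInitSpec(mu=0.0, seed=7))
    return simulate(init, params)


@pytest.fixture(scope="session")
def spinodal32(traj32) -> VoxelStructure:
    """Filtered late-save structure from the shared 32^3 trajectory."""
    return filter_artifacts(threshold_extract(traj32[25]), min_volume=250)

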