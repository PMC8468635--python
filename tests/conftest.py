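"""Shared fixtures: the default device, its steady states, and the 30-min
transient are expensive, so they are solved once per session."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import oxychip as oc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

DEFAULT_SPACING = 25.0e-6


@pytest.fixture(scope="session")
def default_geom():
    return oc.build_geometry({})


@pytest.fixture(scope="session")
def default_params():
    return oc.KineticsParams()


@pytest.fixture(scope="session")
def default_grid(default_geom):
    return oc.rasterize(default_geom, DEFAULT_SPACING)


@pytest.fixture(scope="session")
def grid_without_channel(default_geom):
    return oc.rasterize(default_geom.without_channel(), DEFAULT_SPACING)


@pytest.fixture(scope="session")
def steady_with(default_grid, default_params):
    return oc.solve_steady_state(default_grid, default_params)


@pytest.fixture(scope="session")
def steady_without(grid_without_channel, default_params):
    return oc.solve_steady_state(grid_without_channel, default_params)


@pytest.fixture(scope="session")
def transient_default(default_grid, default_params):
    """30 simulated minutes from a uniform normoxic start, dt = 1 s."""
    return oc.run_transient(default_grid, default_params, dt=1.0, t_end=1800.0)


def make_slab_grid(n_nodes: int, spacing: float, dirichlet_both_ends: bool = True):
    """1-D planar slab of tumor gel with Dirichlet atmosphere at the ends."""
    labels = np.full((n_nodes, 1), int(oc.Region.TUMOR_GEL), dtype=np.int8)
    dirichlet = np.zeros_like(labels, dtype=bool)
    dirichlet[0, 0] = True
    if dirichlet_both_ends:
        dirichlet[-1, 0] = True
    return oc.RegionGrid(
        labels=labels, spacing=spacing, mode="planar", dirichlet=dirichlet
    )
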