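"""Shared fixtures. Expensive objects (FDM leadfields) are session-scoped
and shared between the forward-accuracy and localization tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from headperturb.forward import analytic_sphere_leadfield, compute_fdm_leadfield
from headperturb.head_model import assign_conductivities, build_source_grid
from headperturb.synthetic import make_montage, make_network_definition, make_phantom
from headperturb.types import SourceGrid

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

# thick-shelled spherical head: representable from 8 mm down to 4 mm voxels
SHELLS = (("scalp", 92.0), ("skull", 82.0), ("brain", 72.0))
RADII_IN = np.array([72.0, 82.0, 92.0])
SIGMAS_IN = np.array([0.33, 0.0063, 0.43])
COND_TABLE = {"scalp": 0.43, "skull": 0.0063, "brain": 0.33}


@pytest.fixture(scope="session")
def phantom4():
    return make_phantom(92.0, SHELLS, voxel_mm=4.0)


@pytest.fixture(scope="session")
def phantom4_12():
    return make_phantom(92.0, SHELLS, voxel_mm=4.0, twelve_tissue=True)


@pytest.fixture(scope="session")
def montage64(phantom4):
    return make_montage(64, phantom4)


@pytest.fixture(scope="session")
def grid18(phantom4):
    return build_source_grid(phantom4, 18.0)


@pytest.fixture(scope="session")
def network21(phantom4):
    return make_network_definition(phantom4)


@pytest.fixture(scope="session")
def fdm_leadfield4(phantom4, montage64, grid18):
    """FDM leadfield at 4 mm voxels on the full 18 mm brain grid."""
    sigma = assign_conductivities(phantom4, COND_TABLE)
    return compute_fdm_leadfield(sigma, montage64, grid18)


@pytest.fixture(scope="session")
def oracle_nodes(grid18):
    """50 random grid nodes far enough from the brain boundary for the
    analytic series (and their indices into the full grid)."""
    r = np.linalg.norm(grid18.positions, axis=1)
    rng = np.random.default_rng(0)
    valid = np.flatnonzero(r <= 0.95 * 72.0)
    pick = np.sort(rng.choice(valid, 50, replace=False))
    sub = SourceGrid(grid18.positions[pick], grid18.spacing, grid18.generating_labels)
    return pick, sub


@pytest.fixture(scope="session")
def analytic_leadfield4(montage64, oracle_nodes):
    _, sub = oracle_nodes
    return analytic_sphere_leadfield(RADII_IN, SIGMAS_IN, montage64, sub)


# --- small analytic setup for inverse-solution tests -----------------------

@pytest.fixture(scope="session")
def small_sphere():
    shells = (("scalp", 46.0), ("skull", 41.0), ("brain", 36.0))
    ph = make_phantom(46.0, shells, voxel_mm=4.0)
    mon = make_montage(32, ph)
    grid = build_source_grid(ph, 12.0)
    r = np.linalg.norm(grid.positions, axis=1)
    keep = r <= 0.9 * 36.0
    grid = SourceGrid(grid.positions[keep], grid.spacing, grid.generating_labels)
    lf = analytic_sphere_leadfield([36.0, 41.0, 46.0], [0.33, 0.0063, 0.43], mon, grid)
    return ph, mon, grid, lf
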