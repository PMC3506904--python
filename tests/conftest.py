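"""Shared fixtures: small synthetic setups for unit tests and the full-size
cardiac phantom reused by the acceptance suite."""

import numpy as np
import pytest

import dualspect as d


@pytest.fixture(scope="session")
def small_geometry():
    return d.Geometry.circular(n_views=16, orbit_radius_mm=200.0,
                               detector_shape=(32, 32), pixel_mm=6.6)


@pytest.fixture(scope="session")
def collimator():
    return d.CollimatorModel()


@pytest.fixture(scope="session")
def delta_collimator():
    return d.CollimatorModel(0.0, 0.0)


@pytest.fixture(scope="session")
def ball_phantom():
    """Warm ball in an attenuating sphere on a 32^3 grid."""
    n = 32
    idx = np.arange(n) - (n - 1) / 2
    xx, yy, zz = np.meshgrid(idx, idx, idx, indexing="ij")
    r2 = xx ** 2 + yy ** 2 + zz ** 2
    act = np.where(r2 < 8 ** 2, 1.0, 0.0).astype(np.float32)
    labels = np.where(r2 < 12 ** 2, 1, 0).astype(np.int8)
    table = d.default_material_table()
    mu = np.where(labels == 1, table.mu_at("soft_tissue", 140.0), 0.0)
    mu_map = d.AttenuationMap(mu.astype(np.float32), 6.6, 140.0,
                              labels=labels, materials=("", "soft_tissue"))
    return d.ActivityVolume(act, 6.6), mu_map


@pytest.fixture(scope="session")
def cardiac_phantom():
    """Full-size 64^3 Phantom-3 analogue (anterior 20% + septal 40% defects)."""
    return d.build_cardiac_phantom(d.cardiac_phantom_spec(3))
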