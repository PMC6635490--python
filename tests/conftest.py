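"""Shared fixtures: small phantoms and Monte-Carlo artifacts reused across tests."""

import numpy as np
import pytest

from deepdose import (
    OrganSpec,
    PhantomSpec,
    Volume,
    generate_vsv_kernel,
    make_phantom,
    simulate_dose,
)
from deepdose.mc import dose_to_rate

VOXEL = (2.67, 2.67, 5.0)


@pytest.fixture(scope="session")
def small_kernel():
    """VSV kernel sized to cover a 32x32x16 phantom, moderate statistics."""
    return generate_vsv_kernel(VOXEL, (33, 33, 17), n_histories=2_000_000, seed=301)


@pytest.fixture(scope="session")
def water_phantom():
    """Uniform-water phantom with two hot ellipsoids inside a warm body."""
    dims = (32, 32, 16)
    organs = [
        OrganSpec(1, "ellipsoid", (15.5, 15.5, 7.5), (12, 12, 6), "soft",
                  activity=5000.0, name="body"),
        OrganSpec(2, "ellipsoid", (10, 10, 7.5), (4, 4, 3), "soft",
                  activity=20000.0, name="hot1"),
        OrganSpec(3, "ellipsoid", (21, 20, 8), (3, 3, 2), "soft",
                  activity=40000.0, name="hot2"),
    ]
    return make_phantom(PhantomSpec(dims, VOXEL, organs, background_material="soft"))


@pytest.fixture(scope="session")
def water_mc_rate(water_phantom):
    dose = simulate_dose(water_phantom.activity, water_phantom.density,
                         n_histories=4_000_000, seed=311)
    return dose_to_rate(dose, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def unit_volume():
    def _make(data, units="Gy/s", voxel=VOXEL):
        return Volume(np.asarray(data, dtype=float), voxel, units)

    return _make
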