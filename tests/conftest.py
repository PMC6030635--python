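"""Shared fixtures: seeded phantoms and analytic voxelized shells."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from crownct.phantom import PhantomSpec, build_attenuation_model, generate_phantom
from crownct.volume import DENTINE, ENAMEL, TissueLabelMap

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def neutron_model():
    return build_attenuation_model("neutron")


@pytest.fixture(scope="session")
def xray_model():
    return build_attenuation_model("xray")


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default crown, neutron windows, no noise or speckle."""
    spec = PhantomSpec(seed=1, noise_sd=0.0, speckle_fraction=0.0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default crown with the standard noise and speckle levels."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def small_spec():
    """A small crown that fits a 64^3 grid, for fast stage tests."""
    return PhantomSpec(shape=(64, 64, 64), crown_height_mm=1.0,
                       half_width_labiolingual_mm=0.5,
                       half_width_mesiodistal_mm=0.4,
                       apex_thickness_mm=0.06, basal_thickness_mm=0.10,
                       ridge_amplitude_mm=0.08, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


def make_sphere_shell(outer_r: float, inner_r: float, voxel: float,
                      offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
                      pad: int = 4) -> TissueLabelMap:
    """Voxelized spherical enamel shell around a dentine core."""
    n = int(2 * (outer_r / voxel) + 2 * pad + 4)
    idx = (np.arange(n) + 0.5) * voxel
    c = n * voxel / 2
    z, y, x = np.meshgrid(idx, idx, idx, indexing="ij")
    r_out = np.sqrt((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2)
    oz, oy, ox = offset
    r_in = np.sqrt((z - c - oz) ** 2 + (y - c - oy) ** 2 + (x - c - ox) ** 2)
    labels = np.zeros((n, n, n), dtype=np.uint8)
    labels[r_out <= outer_r] = ENAMEL
    labels[r_in <= inner_r] = DENTINE
    return TissueLabelMap(labels, voxel)


@pytest.fixture(scope="session")
def concentric_shell():
    """Outer radius 1.0 mm, inner 0.8 mm, 0.04 mm voxels."""
    return make_sphere_shell(1.0, 0.8, 0.04)


@pytest.fixture(scope="session")
def eccentric_shell():
    """Inner sphere offset 0.1 mm: shell thickness ranges 0.1-0.3 mm."""
    return make_sphere_shell(1.0, 0.8, 0.04, offset=(0.0, 0.0, 0.1))
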