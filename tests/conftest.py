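"""Shared fixtures: digitized spheres, small phantoms, trained smoke nets."""

from __future__ import annotations

import numpy as np
import pytest

from learngc.phantom import PhantomConfig, make_phantom
from learngc.surface import extract_surface
from learngc.volume import ImageVolume


def digitized_sphere(radius_mm: float, spacing: float = 1.0, margin: int = 3):
    """Binary sphere volume centered on the grid; returns (seg, spacing, origin)."""
    n = int(2 * (radius_mm / spacing + margin)) + 1
    c = (n - 1) / 2.0 * spacing
    ax = np.arange(n) * spacing - c
    rho2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return rho2 < radius_mm**2, np.full(3, spacing), np.zeros(3)


@pytest.fixture(scope="session")
def sphere_seg_10mm():
    return digitized_sphere(10.0, 1.0)


@pytest.fixture(scope="session")
def sphere_mesh_10mm(sphere_seg_10mm):
    seg, sp, origin = sphere_seg_10mm
    return extract_surface(seg, sp, origin)


def tiny_phantom_config(seed: int = 0, **overrides) -> PhantomConfig:
    """A fast 40^3 phantom used by unit tests (sub-second to generate)."""
    kw = dict(grid_shape=(40, 40, 40), spacing_mm=(1.25, 1.25, 1.25),
              cavity_radius_mm=11.0, wall_thickness_mm=2.5,
              noise_sigma=5.0, seg_error_mm=1.5, seed=seed)
    kw.update(overrides)
    return PhantomConfig(**kw)


@pytest.fixture(scope="session")
def tiny_phantom():
    return make_phantom(tiny_phantom_config(seed=4))


@pytest.fixture(scope="session")
def tiny_mesh(tiny_phantom):
    ph = tiny_phantom
    return extract_surface(ph.la_seg_auto, ph.image.spacing, ph.image.origin)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def linear_z_volume(n: int = 21, spacing: float = 1.0) -> ImageVolume:
    """Image whose value equals the world z coordinate (mm)."""
    data = np.broadcast_to(np.arange(n) * spacing, (n, n, n)).astype(float)
    return ImageVolume(data.copy(), np.full(3, spacing), np.zeros(3))
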