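import numpy as np
import pytest

from arraysta.simulator import (
    make_tilt_scheme,
    place_hex_array,
    plane_surface,
    pseudo_csu_motif,
    sphere_cap_surface,
)


@pytest.fixture(scope="session")
def tilt60():
    return make_tilt_scheme(60, 2, 5)


@pytest.fixture(scope="session")
def motif():
    return pseudo_csu_motif(voxel_size=4.5)


@pytest.fixture(scope="session")
def plane_lattice():
    """Jitter-free honeycomb on a plane, spacing 120 A."""
    return place_hex_array(plane_surface(half_extent=600.0), 120.0, 0.0, seed=0)


@pytest.fixture(scope="session")
def sphere_lattice():
    return place_hex_array(sphere_cap_surface((0, 0, 0), 2000.0, extent_deg=40.0),
                           74.0, 0.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def masked_corr(a, b, mask=None):
    """Pearson correlation inside an optional boolean mask."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if mask is None:
        mask = np.ones(a.shape, bool)
    av = a[mask] - a[mask].mean()
    bv = b[mask] - b[mask].mean()
    return float(av @ bv / np.sqrt((av @ av) * (bv @ bv)))


def central_sphere_mask(n, radius_frac=0.33):
    c = n // 2
    idx = np.arange(n) - c
    z, y, x = np.meshgrid(idx, idx, idx, indexing="ij")
    return (x * x + y * y + z * z) < (n * radius_frac) ** 2
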