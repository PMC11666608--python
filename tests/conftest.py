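"""Shared fixtures: analytic shapes and session-cached synthetic bones."""

import numpy as np
import pytest
import trimesh

from bisym import TriSurface
from bisym.synthetic import SyntheticPairSpec, canonical_right_tibia, generate_pair


@pytest.fixture
def tetra() -> TriSurface:
    """Unit tetrahedron with outward winding; signed volume = 1/6."""
    v = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    mesh = TriSurface(v, f)
    assert mesh.signed_volume() > 0
    return mesh


@pytest.fixture(scope="session")
def icosphere() -> TriSurface:
    """Unit sphere tessellation with 642 vertices."""
    tm = trimesh.creation.icosphere(subdivisions=3)
    return TriSurface(np.asarray(tm.vertices), np.asarray(tm.faces))


def open_cylinder(radius: float, height: float, n_seg: int = 128, n_ring: int = 21,
                  z0: float = 0.0) -> TriSurface:
    """Open-ended vertical cylinder (lateral surface only), axis = z."""
    theta = np.linspace(0.0, 2 * np.pi, n_seg, endpoint=False)
    zs = np.linspace(z0, z0 + height, n_ring)
    verts = np.array([[radius * np.cos(t), radius * np.sin(t), z]
                      for z in zs for t in theta])
    faces = []
    for r in range(n_ring - 1):
        for s in range(n_seg):
            a = r * n_seg + s
            b = r * n_seg + (s + 1) % n_seg
            c = a + n_seg
            d = b + n_seg
            faces.append([a, b, d])
            faces.append([a, d, c])
    return TriSurface(verts, np.array(faces))


@pytest.fixture(scope="session")
def tibia_default():
    """Canonical right tibia at the default 1.5 mm resolution."""
    return canonical_right_tibia(SyntheticPairSpec())


@pytest.fixture(scope="session")
def sym_pair_coarse():
    """Perfectly symmetric pair (no asymmetry, no noise) at 2 mm resolution."""
    spec = SyntheticPairSpec(seed=5, noise_sd_mm=0.0, asymmetry_sites=[],
                             mesh_resolution=2.0)
    return generate_pair(spec)


@pytest.fixture(scope="session")
def default_pair():
    """One specimen under the default study conditions (asymmetry + noise)."""
    return generate_pair(SyntheticPairSpec(seed=42))
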