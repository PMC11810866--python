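from __future__ import annotations

import numpy as np
import pytest
import trimesh

from skinfuse import (
    CameraSimSpec,
    PhantomSpec,
    SegmentationConfig,
    TriangleMesh,
    VolumetricImage,
    make_phantom_volume,
    segment_skin_surface,
    vertex_normals,
)


@pytest.fixture(scope="session")
def abdomen_phantom():
    """Default abdomen-like phantom volume with its analytic shape."""
    spec = PhantomSpec()
    vol, shape = make_phantom_volume(spec, seed=1)
    return spec, vol, shape


@pytest.fixture(scope="session")
def abdomen_skin(abdomen_phantom):
    """Segmented skin surface of the default phantom, with normals."""
    spec, vol, _ = abdomen_phantom
    mesh = segment_skin_surface(vol, SegmentationConfig(iso_value=spec.iso_value))
    return vertex_normals(mesh)


@pytest.fixture(scope="session")
def anterior_landmark(abdomen_skin):
    """Anterior apex of the phantom skin, the natural virtual landmark."""
    return abdomen_skin.vertices[
        np.argmax(abdomen_skin.vertices @ np.array([0.0, 1.0, 0.0]))
    ]


@pytest.fixture(scope="session")
def icosphere():
    """Unit-ish icosphere mesh (radius 50 mm) as a TriangleMesh with normals."""
    sph = trimesh.creation.icosphere(subdivisions=3, radius=50.0)
    return vertex_normals(
        TriangleMesh(vertices=np.asarray(sph.vertices), triangles=np.asarray(sph.faces))
    )


@pytest.fixture()
def sphere_volume():
    """Binary-intensity sphere of radius 20 mm on a 1 mm grid, centred at 0."""
    n = 48
    idx = np.arange(n) - (n - 1) / 2
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
    inside = X**2 + Y**2 + Z**2 <= 20.0**2
    data = np.where(inside, 100.0, -1000.0)
    return VolumetricImage(data=data, origin=-np.ones(3) * (n - 1) / 2)


def random_volume(rng: np.random.Generator, shape=(32, 32, 8), iso: float = 0.0):
    """Random binary volume with values {iso-1, iso} and background corners."""
    data = np.where(rng.random(shape) < 0.5, iso - 1.0, iso).astype(float)
    return VolumetricImage(data=data)
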