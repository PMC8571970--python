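"""Shared fixtures: small analytic meshes and synthetic tooth factories."""

from __future__ import annotations

import numpy as np
import pytest

from toothkit.mesh import TriangleMesh, repair_winding
from toothkit.synthetic import default_spec, make_tooth


def _subdivide(vertices: np.ndarray, faces: np.ndarray, levels: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint subdivision (1 face -> 4), keeping the surface planar."""
    for _ in range(levels):
        verts = list(map(tuple, vertices))
        index = {v: i for i, v in enumerate(verts)}

        def mid(a, b):
            m = tuple((np.asarray(verts[a]) + np.asarray(verts[b])) / 2.0)
            if m not in index:
                index[m] = len(verts)
                verts.append(m)
            return index[m]

        new_faces = []
        for f in faces:
            ab, bc, ca = mid(f[0], f[1]), mid(f[1], f[2]), mid(f[2], f[0])
            new_faces += [(f[0], ab, ca), (ab, f[1], bc),
                          (ca, bc, f[2]), (ab, bc, ca)]
        vertices = np.array(verts, dtype=float)
        faces = np.array(new_faces, dtype=np.int64)
    return vertices, faces


@pytest.fixture
def tetrahedron() -> TriangleMesh:
    V = np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    F = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
    return TriangleMesh(V, F, name="tetrahedron").validate()


@pytest.fixture
def tilted_plane() -> TriangleMesh:
    """Planar sheet of 32 triangles tilted 30 degrees from horizontal.

    All normals share one azimuth (due north), so the sheet is a single
    orientation patch in every rotation trial.
    """
    xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
    V = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(25)])
    F = []
    for i in range(4):
        for j in range(4):
            a = i * 5 + j
            F += [(a, a + 1, a + 5), (a + 1, a + 6, a + 5)]
    tilt = np.radians(30.0)
    R = np.array([[1, 0, 0],
                  [0, np.cos(tilt), -np.sin(tilt)],
                  [0, np.sin(tilt), np.cos(tilt)]])
    return TriangleMesh(V @ R.T, np.array(F), name="tilted_plane").validate()


@pytest.fixture
def square_pyramid() -> TriangleMesh:
    """Closed square pyramid, apex on +Z, each wall subdivided into 16
    coplanar triangles; wall azimuths 0/90/180/270, base faces vertical
    (UNDEFINED)."""
    apex = np.array([0.0, 0.0, 1.0])
    corners = np.array([[1., 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0]])
    V_list = [apex] + list(corners) + [np.zeros(3)]
    F_list = []
    for k in range(4):
        c1, c2 = 1 + k, 1 + (k + 1) % 4
        F_list.append((0, c1, c2))
    base_centre = 5
    for k in range(4):
        c1, c2 = 1 + k, 1 + (k + 1) % 4
        F_list.append((base_centre, c2, c1))
    V, F = _subdivide(np.array(V_list), np.array(F_list, np.int64), 2)
    return repair_winding(TriangleMesh(V, F, name="square_pyramid")).validate()


@pytest.fixture
def small_tooth():
    """Factory: low-resolution synthetic tooth (a few hundred faces)."""
    def build(family: str = "cusped", seed: int = 0, resolution: int = 400,
              **overrides) -> TriangleMesh:
        spec = default_spec(family, resolution=resolution, seed=seed,
                            **overrides)
        return make_tooth(spec)
    return build
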