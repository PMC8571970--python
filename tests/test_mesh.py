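"""Mesh containers, validation, geometry primitives, and PLY/OBJ I/O."""

import numpy as np
import pytest
import trimesh

from toothkit.mesh import (
    MeshFormatError,
    MeshIOError,
    MeshValidationError,
    TriangleMesh,
    face_adjacency,
    face_normals,
    read_mesh,
    write_mesh,
)

ASCII_PLY_TETRA = """ply
format ascii 1.0
element vertex 4
property float x
property float y
property float z
element face 4
property list uchar int vertex_indices
end_header
0 0 0
1 0 0
0 1 0
0 0 1
3 0 2 1
3 0 1 3
3 1 2 3
3 0 3 2
"""


class TestReadMesh:
    def test_ascii_ply_tetrahedron(self, tmp_path):
        p = tmp_path / "tet.ply"
        p.write_text(ASCII_PLY_TETRA)
        mesh = read_mesh(p)
        assert mesh.n_vertices == 4
        assert mesh.n_faces == 4

    def test_obj_quad_face_rejected(self, tmp_path):
        p = tmp_path / "quad.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n")
        with pytest.raises(MeshFormatError, match="face 0"):
            read_mesh(p)

    def test_ascii_ply_quad_face_rejected(self, tmp_path):
        p = tmp_path / "quad.ply"
        p.write_text(ASCII_PLY_TETRA.replace(
            "element vertex 4", "element vertex 4").replace(
            "3 0 2 1", "4 0 2 1 3").replace("element face 4",
                                            "element face 4"))
        with pytest.raises(MeshFormatError, match="triangles"):
            read_mesh(p)

    def test_unsupported_ply_dialect_rejected(self, tmp_path):
        p = tmp_path / "big_endian.ply"
        p.write_bytes(ASCII_PLY_TETRA.replace(
            "format ascii 1.0", "format binary_big_endian 1.0").encode())
        with pytest.raises(MeshFormatError, match="dialect"):
            read_mesh(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(MeshIOError):
            read_mesh(tmp_path / "nope.ply")

    def test_winding_repaired_on_flipped_face(self, tmp_path, tetrahedron):
        faces = tetrahedron.faces.copy()
        faces[2] = faces[2][::-1]  # break consistency on one face
        broken = TriangleMesh(tetrahedron.vertices, faces)
        p = tmp_path / "broken.ply"
        write_mesh(broken, p)
        mesh = read_mesh(p)
        assert mesh.is_winding_consistent()
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        assert tm.volume > 0  # outward orientation on the closed surface


class TestWriteMesh:
    @pytest.mark.parametrize("fmt,binary", [("ply", False), ("ply", True),
                                            ("obj", False)])
    def test_round_trip_exact(self, tmp_path, small_tooth, fmt, binary):
        mesh = small_tooth("spatulate", seed=3, resolution=1000)
        p = tmp_path / f"tooth.{fmt}"
        write_mesh(mesh, p, binary=binary)
        back = read_mesh(p)
        assert np.array_equal(back.faces, mesh.faces)
        assert np.array_equal(back.vertices, mesh.vertices)

    def test_empty_mesh_rejected(self, tmp_path):
        empty = TriangleMesh(np.zeros((3, 3)), np.empty((0, 3), np.int64))
        with pytest.raises(MeshValidationError):
            write_mesh(empty, tmp_path / "empty.ply")


class TestValidation:
    def test_out_of_range_index(self):
        mesh = TriangleMesh(np.eye(3), np.array([[0, 1, 5]]))
        with pytest.raises(MeshValidationError, match="outside"):
            mesh.validate()

    def test_repeated_index(self):
        mesh = TriangleMesh(np.eye(3), np.array([[0, 1, 1]]))
        with pytest.raises(MeshValidationError, match="repeats"):
            mesh.validate()

    def test_zero_area_face(self):
        V = np.array([[0., 0, 0], [1, 0, 0], [2, 0, 0]])
        mesh = TriangleMesh(V, np.array([[0, 1, 2]]))
        with pytest.raises(MeshValidationError, match="zero area"):
            mesh.validate()


class TestFaceNormals:
    def test_planar_ccw(self):
        V = np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0]])
        n = face_normals(TriangleMesh(V, np.array([[0, 1, 2]]))).normals
        assert np.allclose(n, [[0, 0, 1]])

    def test_reversed_winding_flips(self):
        V = np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0]])
        n = face_normals(TriangleMesh(V, np.array([[0, 2, 1]]))).normals
        assert np.allclose(n, [[0, 0, -1]])

    def test_sphere_normals_near_radial(self):
        sphere = trimesh.creation.icosphere(subdivisions=3)
        mesh = TriangleMesh(np.asarray(sphere.vertices),
                            np.asarray(sphere.faces))
        normals = face_normals(mesh).normals
        centroids = mesh.vertices[mesh.faces].mean(axis=1)
        radial = centroids / np.linalg.norm(centroids, axis=1)[:, None]
        cosang = np.einsum("ij,ij->i", normals, radial)
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))).max() < 15.0

    def test_direction_invariant_under_scale_and_shift(self, small_tooth):
        mesh = small_tooth("peg", seed=1)
        base = face_normals(mesh).normals
        moved = TriangleMesh(mesh.vertices * 3.5 + np.array([10., -4, 2]),
                             mesh.faces)
        assert np.allclose(face_normals(moved).normals, base, atol=1e-9)


class TestFaceAdjacency:
    def test_tetrahedron_all_three_neighbours(self, tetrahedron):
        adj = face_adjacency(tetrahedron)
        assert all(len(adj.neighbours(f)) == 3 for f in range(4))

    def test_shared_edge_vs_shared_vertex(self):
        V = np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
                      [2, 0, 0]])
        edge_pair = TriangleMesh(V, np.array([[0, 1, 2], [1, 3, 2]]))
        vertex_pair = TriangleMesh(V, np.array([[0, 1, 2], [1, 4, 3]]))
        assert len(face_adjacency(edge_pair).neighbours(0)) == 1
        assert face_adjacency(vertex_pair).neighbours(0) == set()

    def test_symmetry_and_bound(self, small_tooth):
        adj = face_adjacency(small_tooth("blade", seed=2))
        for f, nbrs in adj.pairs.items():
            assert len(nbrs) <= 3
            for g in nbrs:
                assert f in adj.pairs[g]

    def test_non_manifold_edge_warns_not_fails(self, caplog):
        V = np.array([[0., 0, 0], [1, 0, 0], [0, 1, 0], [0, -1, 0],
                      [0, 0, 1]])
        F = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])  # edge 0-1 x3
        with caplog.at_level("WARNING", logger="toothkit.mesh"):
            adj = face_adjacency(TriangleMesh(V, F))
        assert adj.non_manifold_edges == 1
        assert len(adj.neighbours(0)) == 2
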