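"""Triangle-mesh containers, validation, geometry primitives and PLY/OBJ I/O.

All tooth meshes in this package follow one orientation convention: **+Z is
the occlusal (apex) direction** and the XY plane is the horizontal reference
against which compass orientations are binned.  Vertex indices are 0-based
internally; OBJ's 1-based indices are converted at the file boundary.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

logger = logging.getLogger("toothkit.mesh")

__all__ = [
    "TriangleMesh",
    "FaceAdjacency",
    "FaceNormals",
    "MeshError",
    "MeshIOError",
    "MeshFormatError",
    "MeshValidationError",
    "read_mesh",
    "write_mesh",
    "face_normals",
    "face_adjacency",
]


class MeshError(Exception):
    """Base class for mesh-related failures."""


class MeshIOError(MeshError):
    """File could not be read or written."""


class MeshFormatError(MeshError):
    """File parsed but violates the supported format contract."""


class MeshValidationError(MeshError):
    """Mesh content violates a structural invariant."""


@dataclass
class TriangleMesh:
    """An indexed triangle surface of one tooth crown.

    Parameters
    ----------
    vertices:
        ``(n, 3)`` float array of coordinates.  The length unit is arbitrary
        but internally consistent; +Z points toward the occlusal apex.
    faces:
        ``(m, 3)`` integer array of 0-based vertex indices with
        counter-clockwise winding (outward normals on closed components).
    name:
        Free-text identifier carried through the pipeline.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array")

    # -- basic properties -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self, name: str | None = None) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(),
            self.name if name is None else name,
        )

    def bounding_box_diagonal(self) -> float:
        if self.n_vertices == 0:
            return 0.0
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    # -- validation -------------------------------------------------------
    def validate(self, check_winding: bool = False) -> "TriangleMesh":
        """Check structural invariants, raising :class:`MeshValidationError`.

        Verifies index bounds, absence of repeated indices within a face,
        strictly positive face areas and (optionally) globally consistent
        winding.  Returns ``self`` so calls can be chained.
        """
        if self.n_faces == 0:
            raise MeshValidationError(f"mesh {self.name!r} has no faces")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= self.n_vertices:
            bad = np.where(
                (self.faces < 0).any(axis=1) | (self.faces >= self.n_vertices).any(axis=1)
            )[0]
            raise MeshValidationError(
                f"face {bad[0]} references a vertex outside [0, {self.n_vertices})"
            )
        rep = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if rep.any():
            raise MeshValidationError(
                f"face {int(np.where(rep)[0][0])} repeats a vertex index"
            )
        areas = _double_areas(self.vertices, self.faces)
        tol = 1e-12 * max(self.bounding_box_diagonal(), 1.0) ** 2
        degenerate = areas <= tol
        if degenerate.any():
            raise MeshValidationError(
                f"face {int(np.where(degenerate)[0][0])} has zero area"
            )
        if check_winding and not self.is_winding_consistent():
            raise MeshValidationError(
                f"mesh {self.name!r} has inconsistent face winding"
            )
        return self

    def is_winding_consistent(self) -> bool:
        return bool(self._as_trimesh().is_winding_consistent)

    def _as_trimesh(self) -> "_trimesh.Trimesh":
        return _trimesh.Trimesh(self.vertices, self.faces, process=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TriangleMesh):
            return NotImplemented
        return (
            self.vertices.shape == other.vertices.shape
            and self.faces.shape == other.faces.shape
            and np.array_equal(self.vertices, other.vertices)
            and np.array_equal(self.faces, other.faces)
        )


@dataclass
class FaceNormals:
    """Per-face outward unit normals, index-aligned with the face array."""

    normals: np.ndarray


@dataclass
class FaceAdjacency:
    """Full-edge face adjacency.

    Two faces are adjacent iff they share exactly one complete edge (two
    vertex indices).  Faces touching only at a vertex are *not* contiguous.
    """

    pairs: dict[int, set[int]]
    #: (k, 2) array of adjacent face-id pairs, convenient for graph libraries.
    edge_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    non_manifold_edges: int = 0

    def neighbours(self, face_id: int) -> set[int]:
        return self.pairs.get(face_id, set())


def _double_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return np.linalg.norm(cross, axis=1)


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def face_normals(mesh: TriangleMesh) -> FaceNormals:
    """Unit normals from counter-clockwise winding (outward when repaired).

    Raises :class:`MeshValidationError` on zero-area faces, for which no
    normal direction exists.
    """
    mesh.validate()
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(cross, axis=1)
    return FaceNormals(cross / norms[:, None])


def face_adjacency(mesh: TriangleMesh) -> FaceAdjacency:
    """Build full-edge adjacency; non-manifold edges warn but do not fail.

    An edge shared by more than two faces (a common defect in fossil scans)
    is logged and all its face pairs are connected, so patch contiguity
    degrades gracefully rather than splitting the surface.
    """
    faces = mesh.faces
    m = len(faces)
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    owner = np.tile(np.arange(m, dtype=np.int64), 3)
    # group by undirected edge key
    keys = edges[:, 0].astype(np.int64) * (mesh.n_vertices + 1) + edges[:, 1]
    order = np.argsort(keys, kind="stable")
    keys_s, owner_s = keys[order], owner[order]
    boundaries = np.flatnonzero(np.diff(keys_s)) + 1
    groups = np.split(owner_s, boundaries)

    pair_list: list[tuple[int, int]] = []
    non_manifold = 0
    for g in groups:
        if len(g) == 2:
            pair_list.append((int(g[0]), int(g[1])))
        elif len(g) > 2:
            non_manifold += 1
            for i in range(len(g)):
                for j in range(i + 1, len(g)):
                    pair_list.append((int(g[i]), int(g[j])))
    if non_manifold:
        logger.warning(
            "mesh %r: %d non-manifold edge(s) (shared by >2 faces)",
            mesh.name, non_manifold,
        )
    pairs: dict[int, set[int]] = {i: set() for i in range(m)}
    for a, b in pair_list:
        pairs[a].add(b)
        pairs[b].add(a)
    edge_pairs = (
        np.array(pair_list, dtype=np.int64)
        if pair_list else np.empty((0, 2), np.int64)
    )
    return FaceAdjacency(pairs=pairs, edge_pairs=edge_pairs,
                         non_manifold_edges=non_manifold)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_SUPPORTED_PLY_FORMATS = {"ascii 1.0", "binary_little_endian 1.0"}


def _sniff_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("ply", "obj"):
        return suffix
    raise MeshFormatError(
        f"cannot infer mesh format from extension {path.suffix!r}; pass format="
    )


def _check_ply_header(raw: bytes, path: Path) -> str:
    if not raw.startswith(b"ply"):
        raise MeshFormatError(f"{path}: not a PLY file (missing 'ply' magic)")
    head = raw[:4096].decode("ascii", errors="replace")
    for line in head.splitlines():
        if line.startswith("format "):
            fmt = line[len("format "):].strip()
            if fmt not in _SUPPORTED_PLY_FORMATS:
                raise MeshFormatError(
                    f"{path}: unsupported PLY dialect {fmt!r}; supported: "
                    + ", ".join(sorted(_SUPPORTED_PLY_FORMATS))
                )
            return fmt
    raise MeshFormatError(f"{path}: PLY header has no 'format' line")


def _scan_ascii_ply_faces(text: str, path: Path) -> None:
    """Reject non-triangular faces in an ASCII PLY before the engine
    silently triangulates them."""
    lines = text.splitlines()
    n_vertex = n_face = 0
    header_end = 0
    current = None
    for i, line in enumerate(lines):
        tok = line.split()
        if tok[:2] == ["element", "vertex"]:
            n_vertex = int(tok[2])
            current = "vertex"
        elif tok[:2] == ["element", "face"]:
            n_face = int(tok[2])
            current = "face"
        elif tok[:1] == ["element"]:
            current = tok[1]
        elif tok[:1] == ["end_header"]:
            header_end = i + 1
            break
    face_start = header_end + n_vertex
    for k in range(n_face):
        row = lines[face_start + k].split()
        if not row or int(row[0]) != 3:
            raise MeshFormatError(
                f"{path}: face {k} has {row[0] if row else 0} vertices; "
                "only triangles are supported"
            )


def _scan_obj_faces(text: str, path: Path) -> None:
    face_idx = 0
    for line in text.splitlines():
        if line.startswith("f ") or line.startswith("f\t"):
            n = len(line.split()) - 1
            if n != 3:
                raise MeshFormatError(
                    f"{path}: face {face_idx} has {n} vertices; "
                    "only triangles are supported"
                )
            face_idx += 1


def read_mesh(path: str | Path, format: str = "auto") -> TriangleMesh:
    """Read a PLY (ASCII or binary little-endian) or ASCII OBJ tooth mesh.

    The mesh is validated and its winding repaired to a globally consistent,
    outward orientation where the surface is orientable.  Non-triangular
    faces are a format error; non-orientable surfaces a validation error.
    """
    path = Path(path)
    fmt = _sniff_format(path, format)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise MeshIOError(f"cannot read {path}: {exc}") from exc

    if fmt == "ply":
        ply_dialect = _check_ply_header(raw, path)
        if ply_dialect == "ascii 1.0":
            _scan_ascii_ply_faces(raw.decode("ascii"), path)
        engine_file: io.IOBase = io.BytesIO(raw)
    elif fmt == "obj":
        _scan_obj_faces(raw.decode("utf-8", errors="replace"), path)
        engine_file = io.BytesIO(raw)
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")

    try:
        tm = _trimesh.load(engine_file, file_type=fmt, process=False,
                           maintain_order=True)
    except Exception as exc:  # engine parse failure
        raise MeshFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if not isinstance(tm, _trimesh.Trimesh) or tm.faces.shape[1] != 3:
        raise MeshFormatError(f"{path}: does not contain a triangle mesh")

    mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                        name=path.stem)
    mesh.validate()
    return repair_winding(mesh)


def repair_winding(mesh: TriangleMesh) -> TriangleMesh:
    """Make face winding globally consistent (outward on closed components).

    Raises :class:`MeshValidationError` if the surface is non-orientable.
    """
    tm = mesh._as_trimesh()
    if not tm.is_winding_consistent:
        _trimesh.repair.fix_normals(tm, multibody=True)
        if not tm.is_winding_consistent:
            raise MeshValidationError(
                f"mesh {mesh.name!r} is non-orientable; cannot repair winding"
            )
        return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                            name=mesh.name)
    if tm.is_watertight and tm.volume < 0:
        return TriangleMesh(mesh.vertices, mesh.faces[:, ::-1], name=mesh.name)
    return mesh


def write_mesh(mesh: TriangleMesh, path: str | Path, format: str = "auto",
               binary: bool = False) -> None:
    """Write a validated mesh as ASCII OBJ, ASCII PLY, or binary LE PLY.

    ASCII coordinates are printed with 17 significant digits so a round trip
    through :func:`read_mesh` reproduces float64 coordinates exactly.
    """
    path = Path(path)
    fmt = _sniff_format(path, format)
    mesh.validate()
    try:
        if fmt == "obj":
            path.write_text(_format_obj(mesh))
        elif fmt == "ply" and not binary:
            path.write_text(_format_ascii_ply(mesh))
        elif fmt == "ply":
            path.write_bytes(_format_binary_ply(mesh))
        else:
            raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    except OSError as exc:
        raise MeshIOError(f"cannot write {path}: {exc}") from exc


def _format_obj(mesh: TriangleMesh) -> str:
    out = [f"# {mesh.name}" if mesh.name else "# toothkit mesh"]
    for v in mesh.vertices:
        out.append(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
    for f in mesh.faces + 1:  # OBJ is 1-based
        out.append(f"f {f[0]} {f[1]} {f[2]}")
    return "\n".join(out) + "\n"


def _ply_header(mesh: TriangleMesh, fmt_line: str) -> str:
    return (
        "ply\n"
        f"format {fmt_line}\n"
        f"comment {mesh.name or 'toothkit mesh'}\n"
        f"element vertex {mesh.n_vertices}\n"
        "property double x\n"
        "property double y\n"
        "property double z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )


def _format_ascii_ply(mesh: TriangleMesh) -> str:
    out = [_ply_header(mesh, "ascii 1.0")]
    for v in mesh.vertices:
        out.append(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
    for f in mesh.faces:
        out.append(f"3 {f[0]} {f[1]} {f[2]}\n")
    return "".join(out)


def _format_binary_ply(mesh: TriangleMesh) -> bytes:
    header = _ply_header(mesh, "binary_little_endian 1.0").encode("ascii")
    vbuf = mesh.vertices.astype("<f8").tobytes()
    face_dtype = np.dtype([("n", "u1"), ("idx", "<i4", (3,))])
    frec = np.empty(mesh.n_faces, dtype=face_dtype)
    frec["n"] = 3
    frec["idx"] = mesh.faces
    return header + vbuf + frec.tobytes()
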