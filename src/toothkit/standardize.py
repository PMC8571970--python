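"""Two-stage mesh standardization for dental-topography analysis.

Tooth scans arrive at wildly different resolutions depending on tooth size
and scanner, and orientation-patch counts increase with triangle count.  The
pipeline therefore standardizes every crown the same way before complexity
is measured: decimate to a first common resolution (default 10,000 faces,
±1), apply three steps of uniform Laplacian smoothing, then decimate to the
final analysis resolution (default 1,000 faces).

Decimation is quadric edge collapse (Garland–Heckbert plane quadrics,
area-weighted, boundary edges constrained) with a deterministic tie-break:
on equal quadric error the edge with the lowest vertex indices collapses
first.  No randomness is used anywhere in this module, so standardization
is exactly reproducible.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .mesh import MeshError, TriangleMesh

logger = logging.getLogger("toothkit.standardize")

__all__ = [
    "StandardizationConfig",
    "DecimationError",
    "decimate",
    "laplacian_smooth",
    "standardize_tooth",
]


class DecimationError(MeshError):
    """Decimation could not reach the requested face count."""


@dataclass
class StandardizationConfig:
    """Parameters of the two-stage standardization pipeline.

    Defaults reproduce the protocol used throughout this package:
    10,000-face first pass (±1), 3 smoothing steps, 1,000-face final pass.
    """

    first_target_faces: int = 10_000
    face_tolerance: int = 1
    smooth_steps: int = 3
    final_target_faces: int = 1_000

    def __post_init__(self) -> None:
        if not (self.first_target_faces > self.final_target_faces > 0):
            raise ValueError(
                "require first_target_faces > final_target_faces > 0, got "
                f"{self.first_target_faces} / {self.final_target_faces}"
            )
        if self.smooth_steps < 0 or self.face_tolerance < 0:
            raise ValueError("smooth_steps and face_tolerance must be >= 0")


# ---------------------------------------------------------------------------
# quadric edge collapse
# ---------------------------------------------------------------------------

def _plane_quadrics(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex 4x4 quadrics: area-weighted sum of incident face planes."""
    V, F = mesh.vertices, mesh.faces
    tri = V[F]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    double_area = np.linalg.norm(cross, axis=1)
    n = cross / double_area[:, None]
    d = -np.einsum("ij,ij->i", n, tri[:, 0])
    p = np.concatenate([n, d[:, None]], axis=1)  # (m, 4) plane coefficients
    Kf = p[:, :, None] * p[:, None, :] * (0.5 * double_area)[:, None, None]
    Q = np.zeros((len(V), 4, 4))
    for c in range(3):
        np.add.at(Q, F[:, c], Kf)
    return Q


def _boundary_quadrics(mesh: TriangleMesh, weight: float) -> np.ndarray:
    """Constraint quadrics pinning boundary edges (edges with one face)."""
    V, F = mesh.vertices, mesh.faces
    edges = np.concatenate([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
    owner = np.tile(np.arange(len(F)), 3)
    se = np.sort(edges, axis=1)
    keys = se[:, 0] * (len(V) + 1) + se[:, 1]
    order = np.argsort(keys, kind="stable")
    ks = keys[order]
    uniq, start, counts = np.unique(ks, return_index=True, return_counts=True)
    Q = np.zeros((len(V), 4, 4))
    single = np.where(counts == 1)[0]
    if len(single) == 0:
        return Q
    for s in single:
        idx = order[start[s]]
        a, b = edges[idx]
        f = owner[idx]
        tri = V[F[f]]
        fn = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        e = V[b] - V[a]
        # plane containing the edge, perpendicular to the face
        n = np.cross(e, fn)
        nn = np.linalg.norm(n)
        if nn < 1e-30:
            continue
        n = n / nn
        p = np.append(n, -n @ V[a])
        K = np.outer(p, p) * weight
        Q[a] += K
        Q[b] += K
    return Q


def _optimal_collapse(Q: np.ndarray, va: np.ndarray, vb: np.ndarray
                      ) -> tuple[np.ndarray, float]:
    """Optimal contraction point and its quadric error for quadric ``Q``."""
    A = Q[:3, :3]
    b = Q[:3, 3]
    try:
        v = np.linalg.solve(A + 1e-12 * np.trace(A) * np.eye(3), -b)
        ok = np.isfinite(v).all()
    except np.linalg.LinAlgError:
        ok = False
    candidates = [v] if ok else []
    candidates += [0.5 * (va + vb), va, vb]
    best, best_err = None, np.inf
    for c in candidates:
        h = np.append(c, 1.0)
        err = float(h @ Q @ h)
        if err < best_err:
            best, best_err = c, err
    return best, max(best_err, 0.0)


def decimate(mesh: TriangleMesh, target_faces: int, tolerance: int = 1
             ) -> TriangleMesh:
    """Quadric edge-collapse decimation to ``target_faces`` (± ``tolerance``).

    Boundary edges carry high-weight constraint planes so open rims are
    preserved.  Collapses that would invert a surviving face normal are
    rejected.  Deterministic: equal-error edges collapse lowest-index first.

    Raises
    ------
    DecimationError
        If the mesh has fewer faces than the target (skip decimation
        instead), or if collapsing stalls before reaching the tolerance.
    """
    mesh.validate()
    if target_faces < 4:
        raise ValueError("target_faces must be >= 4")
    if mesh.n_faces < target_faces:
        raise DecimationError(
            f"mesh {mesh.name!r} has {mesh.n_faces} faces, fewer than target "
            f"{target_faces}; skip decimation for this mesh"
        )
    if mesh.n_faces <= target_faces + tolerance:
        return mesh.copy()

    V = mesh.vertices.copy()
    F = mesh.faces.copy()
    n_v, n_f = len(V), len(F)
    scale = mesh.bounding_box_diagonal()
    Q = _plane_quadrics(mesh) + _boundary_quadrics(mesh, weight=scale**2 * 1e3)

    face_alive = np.ones(n_f, bool)
    vertex_faces: list[set[int]] = [set() for _ in range(n_v)]
    for fid, f in enumerate(F):
        for v in f:
            vertex_faces[v].add(fid)
    version = np.zeros(n_v, np.int64)

    def neighbours(v: int) -> set[int]:
        out: set[int] = set()
        for fid in vertex_faces[v]:
            out.update(F[fid])
        out.discard(v)
        return out

    push_counter = 0

    def push_edge(heap: list, a: int, b: int) -> None:
        nonlocal push_counter
        if a > b:
            a, b = b, a
        pos, err = _optimal_collapse(Q[a] + Q[b], V[a], V[b])
        push_counter += 1
        heapq.heappush(heap, (err, a, b, push_counter, version[a], version[b], pos))

    heap: list = []
    seen: set[tuple[int, int]] = set()
    for f in F:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                push_edge(heap, *key)
    del seen

    alive_faces = n_f
    while alive_faces > target_faces + tolerance:
        if not heap:
            raise DecimationError(
                f"collapse stalled at {alive_faces} faces "
                f"(target {target_faces} ± {tolerance})"
            )
        err, a, b, _count, va, vb, pos = heapq.heappop(heap)
        if version[a] != va or version[b] != vb:
            continue
        shared = vertex_faces[a] & vertex_faces[b]
        if not shared or len(shared) > 2:
            continue  # stale or non-manifold configuration
        if alive_faces - len(shared) < target_faces - tolerance:
            # this collapse would overshoot below tolerance; look for another
            continue
        # reject collapses that flip a surviving face
        surviving = (vertex_faces[a] | vertex_faces[b]) - shared
        flip = False
        for fid in surviving:
            f = F[fid]
            tri_old = V[f]
            n_old = np.cross(tri_old[1] - tri_old[0], tri_old[2] - tri_old[0])
            tri_new = np.where((f == a) | (f == b), 0, 1)[:, None] * V[f] \
                + np.where((f == a) | (f == b), 1, 0)[:, None] * pos
            n_new = np.cross(tri_new[1] - tri_new[0], tri_new[2] - tri_new[0])
            if n_old @ n_new <= 1e-14 * (n_old @ n_old):
                flip = True
                break
        if flip:
            continue

        # commit: b merges into a at the optimal position
        V[a] = pos
        Q[a] = Q[a] + Q[b]
        for fid in shared:
            face_alive[fid] = False
            for v in F[fid]:
                vertex_faces[v].discard(fid)
        alive_faces -= len(shared)
        for fid in vertex_faces[b].copy():
            F[fid][F[fid] == b] = a
            vertex_faces[a].add(fid)
            vertex_faces[b].discard(fid)
        # only costs of edges incident to the moved vertex change
        version[a] += 1
        version[b] += 1
        for nb in neighbours(a):
            push_edge(heap, a, nb)

    if not (target_faces - tolerance <= alive_faces <= target_faces + tolerance):
        raise DecimationError(
            f"achieved {alive_faces} faces, outside target "
            f"{target_faces} ± {tolerance}"
        )

    new_F = F[face_alive]
    used = np.unique(new_F)
    remap = np.full(n_v, -1, np.int64)
    remap[used] = np.arange(len(used))
    out = TriangleMesh(V[used], remap[new_F], name=mesh.name)
    return out.validate()


# ---------------------------------------------------------------------------
# Laplacian smoothing
# ---------------------------------------------------------------------------

def laplacian_smooth(mesh: TriangleMesh, steps: int) -> TriangleMesh:
    """Uniform-weight Laplacian smoothing.

    Each step synchronously replaces every vertex by the arithmetic mean of
    its edge-connected neighbours.  Connectivity is unchanged; ``steps=0``
    returns a copy of the input.  Isolated vertices (no neighbours) are left
    unmoved with a logged warning.
    """
    mesh.validate()
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if steps == 0:
        return mesh.copy()
    F = mesh.faces
    n = mesh.n_vertices
    edges = np.concatenate([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.asarray(A.sum(axis=1)).ravel()
    isolated = deg == 0
    if isolated.any():
        logger.warning("mesh %r: %d isolated vertex(es) left unmoved",
                       mesh.name, int(isolated.sum()))
    inv_deg = np.where(isolated, 1.0, 1.0 / np.maximum(deg, 1.0))
    V = mesh.vertices.copy()
    for _ in range(steps):
        mean = A @ V * inv_deg[:, None]
        V = np.where(isolated[:, None], V, mean)
    return TriangleMesh(V, F.copy(), name=mesh.name)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def standardize_tooth(mesh: TriangleMesh,
                      config: StandardizationConfig | None = None
                      ) -> TriangleMesh:
    """Full standardization: decimate → smooth → decimate.

    If the input already has fewer faces than ``first_target_faces`` the
    first decimation is skipped with a warning (small teeth / coarse scans).
    """
    config = config or StandardizationConfig()
    mesh.validate()
    if mesh.n_faces >= config.first_target_faces:
        stage1 = decimate(mesh, config.first_target_faces, config.face_tolerance)
    else:
        logger.warning(
            "mesh %r has %d faces < first target %d; skipping first decimation",
            mesh.name, mesh.n_faces, config.first_target_faces,
        )
        stage1 = mesh
    smoothed = laplacian_smooth(stage1, config.smooth_steps)
    return decimate(smoothed, config.final_target_faces, config.face_tolerance)
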