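"""Independent brute-force oracles, deliberately coded from scratch.

These reimplement the orientation binning, patch flood fill, and the
pairwise rank statistics with different algorithms and formulas than the
package, so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# OPCR oracle: per-face normals, compass bins, BFS flood fill
# ---------------------------------------------------------------------------

def oracle_face_normal(vertices, face):
    a, b, c = (np.asarray(vertices[i], float) for i in face)
    n = np.cross(b - a, c - a)
    return n / np.linalg.norm(n)


def oracle_bin(normal, rotation_deg: float):
    """Compass bin via math-convention angle and explicit sector scan."""
    nx, ny = float(normal[0]), float(normal[1])
    if math.hypot(nx, ny) < 1e-9:
        return None
    math_deg = math.degrees(math.atan2(ny, nx))      # CCW from +X
    compass = (90.0 - math_deg + rotation_deg) % 360.0
    for b in range(8):
        lo = (45.0 * b - 22.5) % 360.0
        if (compass - lo) % 360.0 < 45.0:
            return b
    raise AssertionError("unreachable")


def oracle_adjacency(faces):
    """Edge -> faces map; two faces touch iff they share a full edge."""
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fid, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edge_faces.setdefault((min(a, b), max(a, b)), []).append(fid)
    adj: dict[int, set[int]] = {fid: set() for fid in range(len(faces))}
    for flist in edge_faces.values():
        for i, j in itertools.combinations(flist, 2):
            adj[i].add(j)
            adj[j].add(i)
    return adj


def oracle_patches(bins, adj):
    """BFS flood fill over same-bin neighbours; None bins join nothing."""
    seen: set[int] = set()
    patches = []
    for start in range(len(bins)):
        if start in seen or bins[start] is None:
            continue
        queue, comp = [start], set()
        seen.add(start)
        while queue:
            f = queue.pop()
            comp.add(f)
            for g in adj[f]:
                if g not in seen and bins[g] == bins[f]:
                    seen.add(g)
                    queue.append(g)
        patches.append(comp)
    return patches


def oracle_trial_counts(mesh, min_patch_size, n_trials=8, step=5.625):
    normals = [oracle_face_normal(mesh.vertices, f) for f in mesh.faces]
    adj = oracle_adjacency(mesh.faces)
    counts = []
    for k in range(n_trials):
        bins = [oracle_bin(n, k * step) for n in normals]
        patches = oracle_patches(bins, adj)
        counts.append(sum(1 for p in patches if len(p) >= min_patch_size))
    return counts


# ---------------------------------------------------------------------------
# covariance oracle: root-to-tip path intersection
# ---------------------------------------------------------------------------

def oracle_phylo_covariance(tree):
    """Shared path length via explicit root-to-tip edge paths."""
    dtree = tree.tree
    paths: dict[str, list] = {}
    for leaf in dtree.leaf_node_iter():
        node, path = leaf, []
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = path
    labels = tree.tip_labels
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = set(id(x) for x in paths[a]) \
                & set(id(x) for x in paths[b])
            C[i, j] = sum(node.edge.length or 0.0 for node in paths[a]
                          if id(node) in shared)
    return C, labels


# ---------------------------------------------------------------------------
# rank-statistic oracles: exhaustive pair counting
# ---------------------------------------------------------------------------

def oracle_kendall_tau_b(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) // 2
    return (conc - disc) / math.sqrt((n0 - tx) * (n0 - ty))


def oracle_mann_whitney_u(a, b):
    """U statistic of the first sample by direct pair counting."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def oracle_permutation_t_p(a, b):
    """Exact two-sided permutation p over all label assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na, n = len(a), len(a) + len(b)

    def tstat(x, y):
        sp2 = ((len(x) - 1) * np.var(x, ddof=1)
               + (len(y) - 1) * np.var(y, ddof=1)) / (len(x) + len(y) - 2)
        if sp2 == 0:
            return 0.0
        return (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / len(x) + 1 / len(y)))

    t_obs = abs(tstat(a, b))
    hits = total = 0
    for comb in itertools.combinations(range(n), na):
        mask = np.zeros(n, bool)
        mask[list(comb)] = True
        if abs(tstat(pooled[mask], pooled[~mask])) >= t_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total
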