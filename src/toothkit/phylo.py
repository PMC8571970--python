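"""Time-calibrated trees, phylogenetic covariance, and trait simulation.

Trees are rooted, with branch lengths in millions of years (Myr).  The
packaged fixture tree covers the thirteen genera of a Late Jurassic
assemblage (four ornithischians, two theropods, five diplodocoids, two
macronarians) with every tip calibrated to 152 Ma (the
Kimmeridgian–Tithonian boundary); its internal-node ages are package
conventions, editable via :func:`calibrate_tips`.

Trait evolution models supported for covariance construction and
simulation:

``bm``      Brownian motion: cov(i,j) = σ² · shared path length to the MRCA.
``lambda``  Pagel's λ: off-diagonal covariances scaled by λ (λ may exceed 1
            up to the positive-semidefiniteness limit).
``ou``      Ornstein–Uhlenbeck, stationary form: corr(i,j) = exp(−α·d_ij)
            with d_ij the patristic distance.
"""

from __future__ import annotations

import importlib.resources
import io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("toothkit.phylo")

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "TraitVector",
    "TreeError",
    "read_newick",
    "write_newick",
    "load_fixture_tree",
    "calibrate_tips",
    "phylo_covariance",
    "transform_covariance",
    "lambda_max",
    "simulate_traits",
    "prune_to_common",
]

ULTRAMETRIC_TOL_MYR = 1e-6


class TreeError(Exception):
    """Tree input or calibration failure."""


@dataclass
class PhyloTree:
    """A rooted, branch-length-bearing tree with unique tip labels."""

    tree: dendropy.Tree
    name: str = ""

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise TreeError("tip labels are not unique")
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeError("tree contains an unlabeled tip")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue  # root edge length is optional (treated as 0)
            if edge.length is None:
                raise TreeError(
                    "missing branch length; time calibration requires "
                    "lengths on every branch"
                )
            if edge.length < 0:
                raise TreeError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length (Myr) per tip label."""
        self.tree.calc_node_root_distances(
            return_leaf_distances_only=False)
        return {
            leaf.taxon.label: float(leaf.root_distance)
            for leaf in self.tree.leaf_node_iter()
        }

    def is_ultrametric(self, tol: float = ULTRAMETRIC_TOL_MYR) -> bool:
        d = np.array(list(self.depths().values()))
        return bool(d.max() - d.min() <= tol)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.tree.clone(depth=1), name=self.name)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick",
                                   suppress_rooting=True).strip()


@dataclass
class PhyloCovariance:
    """Shared-path-length matrix (taxa × taxa, Myr) under a trait model."""

    matrix: np.ndarray
    taxon_order: list[str]
    model: str = "bm"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.taxon_order),) * 2:
            raise ValueError("matrix shape does not match taxon_order")


@dataclass
class TraitVector:
    """One real value per tip, aligned with an explicit taxon order."""

    values: np.ndarray
    taxon_order: list[str]
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.taxon_order):
            raise ValueError("values and taxon_order length mismatch")
        if np.isnan(self.values).any():
            raise ValueError("TraitVector may not contain missing values")

    def reordered(self, order: list[str]) -> "TraitVector":
        idx = {t: i for i, t in enumerate(self.taxon_order)}
        missing = [t for t in order if t not in idx]
        if missing:
            raise KeyError(f"taxa absent from trait vector: {missing}")
        return TraitVector(self.values[[idx[t] for t in order]], list(order),
                           self.units)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_newick(source: str, name: str) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(
            data=source, schema="newick",
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:
        raise TreeError(f"cannot parse Newick {name!r}: {exc}") from exc
    return PhyloTree(tree, name=name)


def read_newick(path) -> PhyloTree:
    """Read a rooted Newick tree; every branch must carry a length (Myr)."""
    with open(path) as fh:
        return _parse_newick(fh.read(), name=str(path))


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")


def load_fixture_tree() -> PhyloTree:
    """The packaged 13-genus Late Jurassic tree, tips at 152 Ma."""
    src = importlib.resources.files("toothkit.data") \
        .joinpath("late_jurassic_tree.nwk").read_text()
    return _parse_newick(src, name="late_jurassic_fixture")


def random_ultrametric_tree(n_tips: int, seed: int = 0,
                            total_depth: float | None = None) -> PhyloTree:
    """Random coalescent-style ultrametric tree with strictly positive
    branch lengths (all tips at the present).

    Lineages merge pairwise at strictly increasing node heights with
    exponential waiting times; heights are optionally rescaled so the root
    sits at ``total_depth`` Myr.  Deterministic per seed.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    rng = np.random.default_rng(seed)
    nodes = [(f"t{i}", 0.0) for i in range(n_tips)]  # (newick, height)
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += float(rng.exponential(1.0 / k)) + 1e-6
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (nw_i, h_i), (nw_j, h_j) = nodes[i], nodes[j]
        merged = (f"({nw_i}:{height - h_i:.10f},{nw_j}:{height - h_j:.10f})",
                  height)
        nodes = [nodes[m] for m in range(k) if m not in (i, j)] + [merged]
    newick = nodes[0][0] + ";"
    tree = _parse_newick(newick, name=f"random_{n_tips}_{seed}")
    if total_depth is not None:
        factor = total_depth / height
        for edge in tree.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
    return tree


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_tips(tree: PhyloTree, tip_age_ma: dict[str, float]) -> PhyloTree:
    """Adjust terminal branches so each tip sits at its stated age (Ma).

    The root age is anchored at ``max(depth) + min(age)`` — the youngest
    requested tip keeps the tree's current maximum depth — so a calibration
    the tree already satisfies is a no-op, and all-equal tip ages (e.g.
    152 Ma for every tip) yield an ultrametric tree.  A requested age older
    than the tip's parent node is infeasible and raises :class:`TreeError`
    naming the tip.
    """
    missing = set(tree.tip_labels) - set(tip_age_ma)
    if missing:
        raise TreeError(f"no age provided for tips: {sorted(missing)}")
    out = tree.copy()
    out.tree.calc_node_root_distances(return_leaf_distances_only=False)
    root_age = max(
        leaf.root_distance for leaf in out.tree.leaf_node_iter()
    ) + min(tip_age_ma[label] for label in tree.tip_labels)
    for leaf in out.tree.leaf_node_iter():
        label = leaf.taxon.label
        parent_depth = leaf.root_distance - leaf.edge.length
        new_len = (root_age - tip_age_ma[label]) - parent_depth
        if new_len < -ULTRAMETRIC_TOL_MYR:
            parent_age = root_age - parent_depth
            raise TreeError(
                f"tip {label!r} requested at {tip_age_ma[label]} Ma but its "
                f"parent node is younger ({parent_age:.6g} Ma)"
            )
        leaf.edge.length = max(new_len, 0.0)
    return PhyloTree(out.tree, name=tree.name)


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------

def phylo_covariance(tree: PhyloTree) -> PhyloCovariance:
    """Brownian-motion covariance: entry (i,j) is the root-to-MRCA path
    length shared by tips i and j; the diagonal holds root-to-tip depths."""
    labels = tree.tip_labels
    depths = tree.depths()
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        C[i, i] = depths[a]
        for j in range(i + 1, n):
            b = labels[j]
            d = pdm.patristic_distance(taxa[a], taxa[b])
            C[i, j] = C[j, i] = 0.5 * (depths[a] + depths[b] - d)
    return PhyloCovariance(C, list(labels), model="bm")


def lambda_max(C: PhyloCovariance, upper: float = 10.0) -> float:
    """Largest λ keeping the λ-transformed matrix positive semidefinite."""
    def psd(lam: float) -> bool:
        M = _lambda_transform(C.matrix, lam)
        return bool(np.linalg.eigvalsh(M).min() >= -1e-9 * M.diagonal().max())

    lo, hi = 1.0, upper
    if not psd(lo):
        lo = 0.0
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if psd(mid):
            lo = mid
        else:
            hi = mid
    return lo


def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    M = lam * C
    np.fill_diagonal(M, C.diagonal())
    return M


def transform_covariance(C: PhyloCovariance, model: str,
                         lam: float | None = None,
                         alpha: float | None = None) -> PhyloCovariance:
    """Apply a trait-evolution model to a BM covariance.

    ``lambda`` multiplies off-diagonals by λ (diagonal kept), erroring if
    the result is not positive semidefinite; ``ou`` returns the stationary
    correlation exp(−α·d_ij) with unit diagonal.
    """
    if model == "bm":
        return PhyloCovariance(C.matrix.copy(), list(C.taxon_order), "bm")
    if model == "lambda":
        if lam is None or lam < 0:
            raise ValueError("lambda model requires lam >= 0")
        M = _lambda_transform(C.matrix, lam)
        if np.linalg.eigvalsh(M).min() < -1e-9 * M.diagonal().max():
            raise ValueError(
                f"lambda={lam:.6g} makes the covariance non-PSD; "
                f"admissible maximum is {lambda_max(C):.6g}"
            )
        return PhyloCovariance(M, list(C.taxon_order), "lambda")
    if model == "ou":
        if alpha is None or alpha < 0:
            raise ValueError("ou model requires alpha >= 0")
        diag = C.matrix.diagonal()
        D = diag[:, None] + diag[None, :] - 2.0 * C.matrix  # patristic
        M = np.exp(-alpha * D)
        np.fill_diagonal(M, 1.0)
        return PhyloCovariance(M, list(C.taxon_order), "ou")
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_traits(tree: PhyloTree, model: str = "bm", sigma2: float = 1.0,
                    root_value: float = 0.0, lam: float | None = None,
                    alpha: float | None = None, seed: int | None = 0,
                    units: str = "") -> TraitVector:
    """Draw one trait vector from the multivariate normal implied by the
    tree and model: mean ``root_value``, covariance σ²·C(model)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    C = transform_covariance(phylo_covariance(tree), model, lam=lam,
                             alpha=alpha)
    rng = np.random.default_rng(seed)
    n = len(C.taxon_order)
    if sigma2 == 0:
        values = np.full(n, root_value)
    else:
        M = sigma2 * C.matrix
        jitter = 1e-12 * max(M.diagonal().max(), 1.0)
        L = np.linalg.cholesky(M + jitter * np.eye(n))
        values = root_value + L @ rng.standard_normal(n)
    return TraitVector(values, list(C.taxon_order), units=units)


# ---------------------------------------------------------------------------
# pruning / alignment
# ---------------------------------------------------------------------------

def prune_to_common(tree: PhyloTree, data: "TraitVector | pd.DataFrame",
                    taxon_col: str = "taxon"
                    ) -> tuple[PhyloTree, "TraitVector | pd.DataFrame",
                               dict[str, list[str]]]:
    """Restrict tree and data to their shared taxa.

    Returns the pruned tree, the data reordered to the pruned tree's tip
    order, and a report of dropped labels
    (``{"tree": [...], "data": [...]}``).  Raises on empty intersection.
    """
    if isinstance(data, TraitVector):
        data_taxa = list(data.taxon_order)
    else:
        data_taxa = list(data[taxon_col])
    tree_taxa = tree.tip_labels
    shared = [t for t in tree_taxa if t in set(data_taxa)]
    if not shared:
        raise TreeError("tree and data share no taxa")
    dropped = {
        "tree": [t for t in tree_taxa if t not in set(shared)],
        "data": [t for t in data_taxa if t not in set(shared)],
    }
    if dropped["tree"] or dropped["data"]:
        logger.info("prune_to_common dropped %d tree tip(s), %d data row(s)",
                    len(dropped["tree"]), len(dropped["data"]))
    pruned = tree.copy()
    if dropped["tree"]:
        pruned.tree.retain_taxa_with_labels(shared)
    pruned = PhyloTree(pruned.tree, name=tree.name)
    order = pruned.tip_labels
    if isinstance(data, TraitVector):
        aligned: TraitVector | pd.DataFrame = data.reordered(order)
    else:
        sub = data[data[taxon_col].isin(set(order))]
        aligned = (
            sub.set_index(taxon_col).loc[order].reset_index()
        )
    return pruned, aligned, dropped
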