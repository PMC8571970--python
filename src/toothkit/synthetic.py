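"""Parametric synthetic tooth crowns for pipeline testing and calibration.

Real tooth scans for this problem live in museum repositories; this module
generates closed crown meshes that emulate the four gross morphotypes of a
Late Jurassic dinosaur assemblage:

``peg``
    narrow, elongate, sub-circular cone with a rounded tip (diplodocoid-like
    sauropod teeth, the simplest morphology);
``spatulate``
    labiolingually broad crown with a convex labial and flatter lingual
    margin and optional sinusoidal enamel wrinkles (macronarian-like);
``cusped``
    mesiodistally elongate, labiolingually compressed leaf-shaped crown with
    up to ten cusps along the margin (ornithischian-like, the most complex);
``blade``
    recurved, mediolaterally compressed cutting crown (theropod-like).

Crowns are built on a cylindrical parameter grid (azimuth × height) with a
family-specific cross-section, taper, and feature field, then closed with a
base fan and an apex cap.  The apex points toward +Z, matching the package's
occlusal-up convention.  Gaussian radial vertex noise (seeded) emulates
scan roughness and enamel texture.  All randomness flows through an explicit
seed; generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mesh import TriangleMesh, repair_winding

__all__ = [
    "FAMILIES",
    "ToothSpec",
    "default_spec",
    "make_tooth",
    "apply_wear",
    "AssemblageConfig",
    "make_assemblage",
]

import logging

logger = logging.getLogger("toothkit.synthetic")

FAMILIES = ("peg", "spatulate", "cusped", "blade")

#: clade analogue each morphotype family stands in for
FAMILY_CLADE = {
    "peg": "diplodocoid",
    "spatulate": "macronarian",
    "cusped": "ornithischian",
    "blade": "theropod",
}

#: replacement interval scale per family, in days.  Pegs are replaced
#: fastest (about a month), spatulate crowns at about two months, cusped
#: herbivore teeth slowest; blades are carnivore-like and slow.
FAMILY_RATE_DAYS = {"peg": 35.0, "spatulate": 62.0, "cusped": 96.0,
                    "blade": 104.0}


@dataclass(frozen=True)
class ToothSpec:
    """Full parameterization of one synthetic tooth crown.

    Lengths are in arbitrary consistent units (think millimetres).
    ``resolution`` is the approximate face count of the generated mesh,
    before any standardization.
    """

    family: str
    n_cusps: int = 0
    base_radius: float = 1.0
    crown_height: float = 2.5
    wrinkle_amplitude: float = 0.0
    noise_sd: float = 0.0
    resolution: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "peg" and self.n_cusps != 0:
            raise ValueError("peg teeth have no cusps")
        if self.family == "cusped" and not (0 <= self.n_cusps <= 10):
            raise ValueError("cusped teeth carry between 0 and 10 cusps")
        if self.base_radius <= 0 or self.crown_height <= 0:
            raise ValueError("lengths must be positive")
        if self.noise_sd < 0 or self.wrinkle_amplitude < 0:
            raise ValueError("noise_sd and wrinkle_amplitude must be >= 0")
        if self.resolution < 100:
            raise ValueError("resolution must be >= 100 faces")


def default_spec(family: str, **overrides) -> ToothSpec:
    """A realistic default parameterization for each morphotype family."""
    base = {
        "peg": dict(base_radius=0.45, crown_height=3.0, n_cusps=0,
                    wrinkle_amplitude=0.0, noise_sd=0.01),
        "spatulate": dict(base_radius=1.1, crown_height=2.6, n_cusps=0,
                          wrinkle_amplitude=0.14, noise_sd=0.01),
        "cusped": dict(base_radius=1.2, crown_height=2.0, n_cusps=6,
                       wrinkle_amplitude=0.0, noise_sd=0.01),
        "blade": dict(base_radius=0.8, crown_height=2.8, n_cusps=0,
                      wrinkle_amplitude=0.0, noise_sd=0.01),
    }[family]
    base.update(overrides)
    return ToothSpec(family=family, **base)


# ---------------------------------------------------------------------------
# crown construction
# ---------------------------------------------------------------------------

def _grid_shape(resolution: int) -> tuple[int, int]:
    """Azimuth × height sampling giving ≈ ``resolution`` faces."""
    n_theta = max(16, int(round(np.sqrt(resolution / 2.0))))
    n_t = max(6, int(round(resolution / (2.0 * n_theta))) - 1)
    return n_theta, n_t


def _ellipse_radius(theta: np.ndarray, ax: float, ay: float) -> np.ndarray:
    return 1.0 / np.sqrt((np.cos(theta) / ax) ** 2 + (np.sin(theta) / ay) ** 2)


def _circular_gaussians(theta: np.ndarray, centers: np.ndarray,
                        width: float) -> np.ndarray:
    """Sum of wrapped Gaussian bumps around the azimuth circle."""
    out = np.zeros_like(theta)
    for c in centers:
        d = np.angle(np.exp(1j * (theta - c)))  # wrapped difference
        out += np.exp(-0.5 * (d / width) ** 2)
    return out


def make_tooth(spec: ToothSpec) -> TriangleMesh:
    """Generate one closed crown mesh from its spec (deterministic per seed).

    The surface is a generalized cone: rings of vertices at increasing
    height with a family-specific cross-section and taper, closed by a base
    fan at z=0 and an apex cap at the top.  Features (cusps, wrinkles,
    recurvature) are analytic displacement fields; noise is seeded Gaussian
    radial jitter.
    """
    rng = np.random.default_rng(spec.seed)
    n_theta, n_t = _grid_shape(spec.resolution)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    t = np.linspace(0.0, 1.0, n_t + 1)
    TH, T = np.meshgrid(theta, t)  # (n_t+1, n_theta)

    br, ch = spec.base_radius, spec.crown_height
    cx = np.zeros_like(T)
    cy = np.zeros_like(T)
    z = ch * T

    if spec.family == "peg":
        shape = _ellipse_radius(TH, 1.0, 1.0)
        taper = 1.0 - 0.88 * T ** 1.4  # rounded elongate cone
    elif spec.family == "spatulate":
        shape = _ellipse_radius(TH, 1.0, 0.45)
        # convex labial (+y) / flatter lingual margin
        shape = shape * (1.0 + 0.25 * np.sin(TH) * np.sin(np.pi * T))
        taper = 1.0 - 0.8 * T ** 1.6
        if spec.wrinkle_amplitude > 0:
            # enamel rugosity: a few bold folds (finer ripples would fall
            # below the 1000-face analysis resolution)
            folds = np.sin(5.0 * TH) * np.sin(np.pi * T) \
                + 0.6 * np.sin(3.0 * TH + 1.0) * np.sin(2 * np.pi * T)
            shape = shape + (spec.wrinkle_amplitude / br) * folds
    elif spec.family == "cusped":
        shape = _ellipse_radius(TH, 1.0, 0.35)
        taper = 1.0 - 0.85 * T ** 1.3
        if spec.n_cusps > 0:
            # cusps are spaced along the mesial-distal (x) margin in real
            # space, so labiolingual compression does not squeeze them
            rho0 = br * shape * taper
            x0 = rho0 * np.cos(TH)  # pre-feature x position on the grid
            half_span = 0.8 * br
            centers = np.linspace(-half_span, half_span, spec.n_cusps) \
                if spec.n_cusps > 1 else np.array([0.0])
            width = max(0.28 * 2 * half_span / spec.n_cusps, 0.05 * br)
            bumps = np.zeros_like(T)
            for c in centers:
                bumps += np.exp(-0.5 * ((x0 - c) / width) ** 2)
            z = z + 0.45 * ch * (T ** 3) * bumps
    else:  # blade
        shape = _ellipse_radius(TH, 0.8, 0.28)
        taper = 1.0 - 0.92 * T ** 1.1
        cx = cx + 0.55 * br * T ** 2  # distal recurvature

    rho = br * shape * taper
    if spec.noise_sd > 0:
        rho = rho + rng.normal(0.0, spec.noise_sd, rho.shape)
    rho = np.maximum(rho, 0.02 * br)

    X = cx + rho * np.cos(TH)
    Y = cy + rho * np.sin(TH)

    # assemble vertices: rings, then base centre, then apex
    ring_v = np.stack([X.ravel(), Y.ravel(), z.ravel()], axis=1)
    base_centre = np.array([[0.0, 0.0, 0.0]])
    apex = np.array([[float(cx[-1].mean()), float(cy[-1].mean()),
                      float(z[-1].max()) + 0.06 * ch]])
    vertices = np.concatenate([ring_v, base_centre, apex])
    i_base = len(ring_v)
    i_apex = i_base + 1

    def vid(i: int, j: int) -> int:
        return i * n_theta + (j % n_theta)

    faces: list[tuple[int, int, int]] = []
    for i in range(n_t):
        for j in range(n_theta):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j + 1), vid(i + 1, j)
            faces.append((a, b, c))
            faces.append((a, c, d))
    for j in range(n_theta):  # base fan, outward is -Z
        faces.append((i_base, vid(0, j + 1), vid(0, j)))
    for j in range(n_theta):  # apex cap
        faces.append((i_apex, vid(n_t, j), vid(n_t, j + 1)))

    mesh = TriangleMesh(vertices, np.array(faces, dtype=np.int64),
                        name=f"{spec.family}_c{spec.n_cusps}_s{spec.seed}")
    mesh = repair_winding(mesh)
    return mesh.validate()


# ---------------------------------------------------------------------------
# wear
# ---------------------------------------------------------------------------

def apply_wear(mesh: TriangleMesh, plane_point: np.ndarray,
               plane_normal: np.ndarray) -> TriangleMesh:
    """Model a planar wear facet: vertices above the plane are projected
    onto it.

    ``plane_normal`` points away from the preserved side (for occlusal wear,
    +Z with the plane below the cusp tips).  If no vertex lies strictly
    above the plane, the mesh does not intersect it and a copy of the input
    is returned with a warning.
    """
    p = np.asarray(plane_point, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    d = (mesh.vertices - p) @ n
    above = d > 0
    if not above.any() or above.all():
        logger.warning(
            "wear plane does not intersect mesh %r; returning input unchanged",
            mesh.name,
        )
        return mesh.copy()
    V = mesh.vertices.copy()
    V[above] -= d[above, None] * n
    worn = TriangleMesh(V, mesh.faces.copy(), name=mesh.name + "_worn")
    return worn.validate()


# ---------------------------------------------------------------------------
# assemblage factory
# ---------------------------------------------------------------------------

@dataclass
class AssemblageConfig:
    """Knobs of the assemblage generator.

    ``rate_link`` scales how strongly the replacement interval (days)
    follows the complexity-driving parameter within each family; its sign
    sets the direction of the built-in rate–complexity association.  The
    default (+1) matches the empirical pattern that simple, rapidly worn
    teeth are replaced after fewer days, so the interval in days *increases*
    with complexity.  ``rate_noise_sd`` is lognormal-scale noise on the
    interval.
    """

    teeth_per_taxon: int = 1
    resolution: int = 4000
    rate_link: float = 1.0
    rate_noise_sd: float = 0.08
    noise_sd: float = 0.01


def _randomized_spec(family: str, rng: np.random.Generator,
                     config: AssemblageConfig) -> ToothSpec:
    spec = default_spec(family, resolution=config.resolution,
                        noise_sd=config.noise_sd,
                        seed=int(rng.integers(0, 2**31 - 1)))
    jitter = lambda v, f: float(v * rng.uniform(1 - f, 1 + f))  # noqa: E731
    overrides: dict = dict(
        base_radius=jitter(spec.base_radius, 0.15),
        crown_height=jitter(spec.crown_height, 0.15),
    )
    if family == "cusped":
        overrides["n_cusps"] = int(rng.integers(4, 11))
    if family == "spatulate":
        overrides["wrinkle_amplitude"] = float(rng.uniform(0.10, 0.18))
    return replace(spec, **overrides)


def _complexity_driver(spec: ToothSpec) -> float:
    """Unitless within-family proxy for how complex a spec will measure."""
    if spec.family == "cusped":
        return spec.n_cusps / 10.0
    if spec.family == "spatulate":
        return spec.wrinkle_amplitude / 0.18
    return 0.0


def make_assemblage(n_per_family: int, seed: int,
                    config: AssemblageConfig | None = None
                    ) -> tuple[list[tuple[ToothSpec, TriangleMesh]], pd.DataFrame]:
    """Balanced synthetic assemblage: ``n_per_family`` taxa per morphotype.

    Returns the (spec, mesh) pairs plus a metadata table with one row per
    tooth: taxon label, family, clade analogue, and a synthetic replacement
    interval in days constructed with a monotone link to the family's
    complexity scale plus lognormal noise (ground truth for
    parameter-recovery tests).
    """
    if n_per_family < 1:
        raise ValueError("n_per_family must be >= 1")
    config = config or AssemblageConfig()
    rng = np.random.default_rng(seed)
    teeth: list[tuple[ToothSpec, TriangleMesh]] = []
    rows = []
    for family in FAMILIES:
        for k in range(n_per_family):
            taxon = f"{family}{k + 1:02d}"
            spec0 = _randomized_spec(family, rng, config)
            base_days = FAMILY_RATE_DAYS[family]
            driver = _complexity_driver(spec0)
            days = base_days * (1.0 + 0.4 * config.rate_link * (driver - 0.5)) \
                * float(np.exp(rng.normal(0.0, config.rate_noise_sd)))
            if config.rate_link < 0:
                # invert the between-family scale as well
                days = FAMILY_RATE_DAYS["peg"] + FAMILY_RATE_DAYS["cusped"] - days
            days = max(days, 5.0)
            for tooth_i in range(config.teeth_per_taxon):
                spec = replace(spec0, seed=int(rng.integers(0, 2**31 - 1)))
                mesh = make_tooth(spec)
                mesh.name = f"{taxon}_t{tooth_i + 1}"
                teeth.append((spec, mesh))
                rows.append(dict(
                    mesh_name=mesh.name,
                    taxon=taxon,
                    family=family,
                    clade=FAMILY_CLADE[family],
                    element="combined",
                    wear_state="unworn",
                    replacement_rate_days=round(days, 2),
                    rate_source="measured",
                ))
    metadata = pd.DataFrame(rows)
    return teeth, metadata


def assemblage_tree(metadata: pd.DataFrame, tip_age_ma: float = 152.0):
    """Deterministic time-calibrated tree over an assemblage's taxa.

    Families form monophyletic clades arranged like their dinosaurian
    analogues: (cusped, (blade, (peg, spatulate))) — ornithischians sister
    to saurischians, sauropod morphotypes united.  Within each family the
    topology is a ladder with node ages evenly spaced between the family's
    crown age and just above the tip age.  All tips sit at ``tip_age_ma``;
    ages are package conventions in Ma.
    """
    crown_age = {"cusped": 200.0, "blade": 180.0, "peg": 170.0,
                 "spatulate": 165.0}
    node_age = {"root": 235.0, "saurischian": 233.0, "sauropod": 175.0}

    def family_newick(family: str) -> tuple[str, float]:
        taxa = sorted(metadata.loc[metadata["family"] == family, "taxon"]
                      .unique())
        age = crown_age[family]
        if len(taxa) == 1:
            return taxa[0], tip_age_ma
        # pectinate ladder: internal node ages from the crown age down to
        # just above the tips
        ages = np.linspace(age, tip_age_ma + 2.0, len(taxa) - 1)
        k = len(taxa)
        nw = (f"({taxa[k - 2]}:{ages[k - 2] - tip_age_ma:.6f},"
              f"{taxa[k - 1]}:{ages[k - 2] - tip_age_ma:.6f})")
        for i in range(k - 3, -1, -1):
            nw = (f"({taxa[i]}:{ages[i] - tip_age_ma:.6f},"
                  f"{nw}:{ages[i] - ages[i + 1]:.6f})")
        return nw, age

    from .phylo import _parse_newick

    parts = {}
    for family in FAMILIES:
        if (metadata["family"] == family).any():
            parts[family] = family_newick(family)

    def join(a: tuple[str, float], b: tuple[str, float], age: float
             ) -> tuple[str, float]:
        (nw_a, age_a), (nw_b, age_b) = a, b
        return (f"({nw_a}:{age - age_a:.6f},{nw_b}:{age - age_b:.6f})", age)

    sub = None
    if "peg" in parts and "spatulate" in parts:
        sub = join(parts["peg"], parts["spatulate"], node_age["sauropod"])
    else:
        sub = parts.get("peg") or parts.get("spatulate")
    if "blade" in parts:
        sub = join(parts["blade"], sub, node_age["saurischian"]) \
            if sub else parts["blade"]
    if "cusped" in parts:
        sub = join(parts["cusped"], sub, node_age["root"]) \
            if sub else parts["cusped"]
    if sub is None:
        raise ValueError("metadata contains no known families")
    return _parse_newick(sub[0] + ";", name="assemblage_tree")
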