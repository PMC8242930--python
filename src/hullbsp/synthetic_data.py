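"""Synthetic test-input generators and the Monte-Carlo mass-property oracle.

Everything here is seeded: the same seed always reproduces the same trees,
meshes and datasets (numpy's default_rng throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .calibration_fit import PairedDataset, Phylogeny, bm_covariance
from .hulling import convex_hull
from .mass_properties import (
    BSPVector,
    PARAMETER_NAMES,
    mass_properties,
)
from .mesh_io import TriangleMesh, make_box, make_icosphere, make_prism
from .segments_calibration import (
    LOG10_PARAMETERS,
    SEGMENT_NAMES,
)

__all__ = [
    "SyntheticSpecimen",
    "SimulationConfig",
    "simulate_tree",
    "simulate_bm",
    "generate_paired_dataset",
    "generate_specimen",
    "mc_mass_properties",
    "random_convex_mesh",
]


# ---------------------------------------------------------------------------
# Phylogenies and Brownian motion
# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) tree with exponential waiting times.

    Tips are labeled sp1..spN. Deterministic under the seed.
    """
    if n_tips < 2:
        raise ValueError(f"need at least 2 tips, got {n_tips}")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace([f"sp{i + 1}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    # Active lineages start as the root's two children.
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = root.new_child(edge_length=0.0)
        active.append(child)

    while len(active) < n_tips:
        wait = rng.exponential(1.0 / len(active))
        for node in active:
            node.edge.length += wait
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        for _ in range(2):
            child = parent.new_child(edge_length=0.0)
            active.append(child)
    # terminal stretch so every pendant edge is positive
    wait = rng.exponential(1.0 / len(active))
    for node in active:
        node.edge.length += wait

    rng.shuffle(active)
    for i, node in enumerate(active):
        node.taxon = taxa[i]
    return Phylogeny(tree)


def simulate_bm(tree: Phylogeny, sigma: float, seed: int) -> dict[str, float]:
    """Brownian-motion tip values: jointly Gaussian, mean 0 (root value 0),
    covariance sigma^2 * bm_covariance(tree)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    order = sorted(tree.tip_labels)
    if sigma == 0:
        return {label: 0.0 for label in order}
    rng = np.random.default_rng(seed)
    V = bm_covariance(tree, order)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(order)))
    z = rng.standard_normal(len(order))
    values = sigma * (L @ z)
    return dict(zip(order, values))


# ---------------------------------------------------------------------------
# Paired datasets with known truth
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Recipe for a paired hull/soft dataset with known coefficients."""

    n_species: int
    seed: int
    true_intercepts: dict[tuple[str, str], float] = field(default_factory=dict)
    true_slopes: dict[tuple[str, str], float] = field(default_factory=dict)
    default_intercept: float = 0.0
    default_slope: float = 1.0
    noise_sd: float = 0.0
    noise_mode: str = "iid"  # "iid" | "brownian"
    size_range: tuple[float, float] = (0.02, 400.0)
    segments: tuple[str, ...] = SEGMENT_NAMES
    parameters: tuple[str, ...] = PARAMETER_NAMES

    def truth(self, segment: str, parameter: str) -> tuple[float, float]:
        a = self.true_intercepts.get((segment, parameter), self.default_intercept)
        b = self.true_slopes.get((segment, parameter), self.default_slope)
        return a, b


def generate_paired_dataset(
    config: SimulationConfig, tree: Phylogeny | None = None
) -> PairedDataset:
    """Simulate a paired dataset where, on the transform scale,
    soft = a + b * hull + eps with eps iid Gaussian or Brownian on the tree.

    Hull values for log10 parameters are spread log-uniformly over
    ``size_range``; linear parameters take values uniform in a size-scaled
    band (signed, so cm_y/products exercise both signs).
    """
    if config.noise_mode not in ("iid", "brownian"):
        raise ValueError(f"noise_mode must be iid or brownian, got {config.noise_mode!r}")
    lo, hi = config.size_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid size_range {config.size_range}")
    if config.noise_mode == "brownian" and tree is None:
        raise ValueError("brownian noise_mode requires a tree")
    rng = np.random.default_rng(config.seed)

    if tree is not None:
        species = sorted(tree.tip_labels)
        if config.n_species > len(species):
            raise ValueError("n_species exceeds the number of tree tips")
        species = species[: config.n_species]
    else:
        species = [f"sp{i + 1}" for i in range(config.n_species)]

    n = len(species)
    rows = []
    bm_seed_counter = config.seed + 1
    for segment in config.segments:
        side = "left" if segment in ("arm", "forearm", "hand", "thigh", "shank", "foot") else "none"
        for parameter in config.parameters:
            a, b = config.truth(segment, parameter)
            if parameter in LOG10_PARAMETERS:
                x = rng.uniform(math.log10(lo), math.log10(hi), size=n)
            else:
                scale = rng.uniform(0.05, 0.5)
                x = rng.uniform(-scale, scale, size=n)

            if config.noise_sd == 0:
                eps = np.zeros(n)
            elif config.noise_mode == "iid":
                eps = rng.normal(0.0, config.noise_sd, size=n)
            else:
                assert tree is not None
                tip_values = simulate_bm(tree, config.noise_sd, bm_seed_counter)
                bm_seed_counter += 1
                eps = np.array([tip_values[s] for s in species])

            y = a + b * x + eps
            if parameter in LOG10_PARAMETERS:
                hull_vals = 10.0**x
                soft_vals = 10.0**y
            else:
                hull_vals, soft_vals = x, y
            for i, sp in enumerate(species):
                rows.append({
                    "species": sp,
                    "segment": segment,
                    "side": side,
                    "parameter": parameter,
                    "hull_value": hull_vals[i],
                    "soft_value": soft_vals[i],
                })
    return PairedDataset(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Specimens (paired skin / skeleton meshes)
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpecimen:
    species: str
    body_scale: float
    segments: dict[str, dict]  # name -> {skin_mesh, skeleton_mesh, true_bsp}


# per-segment primitive recipes at body_scale 1 (meters): kind, size knobs
_SEGMENT_SHAPES: dict[str, tuple[str, tuple]] = {
    "arm": ("box", (0.05, 0.05, 0.14)),
    "forearm": ("box", (0.04, 0.04, 0.12)),
    "hand": ("box", (0.05, 0.03, 0.06)),
    "thigh": ("box", (0.07, 0.07, 0.16)),
    "shank": ("box", (0.05, 0.05, 0.14)),
    "foot": ("box", (0.08, 0.04, 0.05)),
    "head": ("sphere", (0.06,)),
    "neck": ("prism", (0.08, 0.045)),
    "torso": ("box", (0.30, 0.12, 0.14)),
    "tail1": ("prism", (0.10, 0.030)),
    "tail2": ("prism", (0.10, 0.024)),
    "tail3": ("prism", (0.10, 0.018)),
    "tail4": ("prism", (0.10, 0.012)),
}


def _segment_skin(segment: str, scale: float) -> TriangleMesh:
    kind, dims = _SEGMENT_SHAPES[segment]
    if kind == "box":
        return make_box(tuple(d * scale for d in dims))
    if kind == "sphere":
        return make_icosphere(dims[0] * scale, subdivisions=2)
    # hexagonal prism along x
    length, radius = (d * scale for d in dims)
    angles = np.linspace(0.0, 2.0 * math.pi, 7)[:-1]
    polygon = np.column_stack([radius * np.cos(angles), radius * np.sin(angles)])
    return make_prism(length, polygon, axis="x")


def generate_specimen(species: str, body_scale: float, seed: int) -> SyntheticSpecimen:
    """Paired skin/skeleton meshes for all 13 segments.

    The skin is a primitive scaled by ``body_scale``; the skeleton is the
    skin's vertex set pulled toward the centroid by a random per-vertex
    factor in [0.3, 0.7] and re-hulled, so skeleton vertices lie strictly
    inside the skin. true_bsp is the skin's exact mass properties at
    1000 kg m^-3.
    """
    if body_scale <= 0:
        raise ValueError(f"body_scale must be positive, got {body_scale}")
    rng = np.random.default_rng(seed)
    segments: dict[str, dict] = {}
    for segment in SEGMENT_NAMES:
        skin = _segment_skin(segment, body_scale)
        centroid = skin.vertices.mean(axis=0)
        shrink = rng.uniform(0.3, 0.7, size=(skin.n_vertices, 1))
        inner_pts = centroid + shrink * (skin.vertices - centroid)
        skeleton = convex_hull(inner_pts).hull
        segments[segment] = {
            "skin_mesh": skin,
            "skeleton_mesh": skeleton,
            "true_bsp": mass_properties(skin, 1000.0),
        }
    return SyntheticSpecimen(species=species, body_scale=body_scale, segments=segments)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------


def random_convex_mesh(seed: int, n_points: int = 50, scale: float = 1.0) -> TriangleMesh:
    """Convex hull of random points in a ball: a generic watertight fixture."""
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n_points, 3))
    radii = rng.uniform(0.2, 1.0, size=n_points) ** (1.0 / 3.0)
    pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * radii[:, None] * scale
    return convex_hull(pts).hull


def _ray_crossings_inside(points: np.ndarray, mesh: TriangleMesh, rng) -> np.ndarray:
    """Vectorised inside test: parity of +x ray crossings per query point.

    A fixed ray direction is used; if any query point grazes a triangle
    edge/vertex or a coplanar face the whole batch is retried with a tiny
    random perturbation of the direction.
    """
    v = mesh.vertices
    a = v[mesh.faces[:, 0]]
    b = v[mesh.faces[:, 1]]
    c = v[mesh.faces[:, 2]]

    tri_stack = np.stack([a, b, c], axis=1)  # (m, 3, 3)
    # yz bounding boxes per face, padded so the prefilter stays valid for
    # slightly perturbed (near +x) ray directions.
    extent = float(np.max(mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)))
    pad = extent * 1e-4 + 1e-12
    ymin = tri_stack[:, :, 1].min(axis=1) - pad
    ymax = tri_stack[:, :, 1].max(axis=1) + pad
    zmin = tri_stack[:, :, 2].min(axis=1) - pad
    zmax = tri_stack[:, :, 2].max(axis=1) + pad
    xmax = tri_stack[:, :, 0].max(axis=1) + pad

    py, pz, px = points[:, 1], points[:, 2], points[:, 0]
    direction = np.array([1.0, 0.0, 0.0])
    for _ in range(16):
        edge1 = b - a
        edge2 = c - a
        h = np.cross(direction, edge2)  # (m, 3)
        det = np.einsum("ij,ij->i", edge1, h)  # (m,)
        ok = np.abs(det) > 1e-14
        inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)

        # Moller-Trumbore per face, restricted to points whose +x ray can
        # possibly cross the face (yz-bbox prefilter).
        grazed = False
        counts = np.zeros(len(points), dtype=np.int64)
        eps = 1e-12
        for fi in range(len(a)):
            if not ok[fi]:
                continue
            cand = np.nonzero(
                (py >= ymin[fi]) & (py <= ymax[fi])
                & (pz >= zmin[fi]) & (pz <= zmax[fi])
                & (px <= xmax[fi])
            )[0]
            if cand.size == 0:
                continue
            s = points[cand] - a[fi]
            u = (s @ h[fi]) * inv_det[fi]
            q = np.cross(s, edge1[fi])
            vpar = (q @ direction) * inv_det[fi]
            t = (q @ edge2[fi]) * inv_det[fi]
            hit = (u > eps) & (u < 1 - eps) & (vpar > eps) & (u + vpar < 1 - eps) & (t > eps)
            counts[cand[hit]] += 1
            graze = (
                ((np.abs(u) <= eps) | (np.abs(1 - u) <= eps)
                 | (np.abs(vpar) <= eps) | (np.abs(u + vpar - 1) <= eps)
                 | (np.abs(t) <= eps))
                & (u > -eps) & (vpar > -eps) & (u + vpar < 1 + eps) & (t > -eps)
            )
            if np.any(graze):
                grazed = True
                break
        if not grazed:
            return (counts % 2) == 1
        # perturb the ray and retry the whole batch
        direction = direction + rng.normal(0.0, 1e-6, size=3)
        direction /= np.linalg.norm(direction)
    raise RuntimeError("ray-crossing test failed to find a non-grazing direction")


def mc_mass_properties(
    mesh: TriangleMesh, n_samples: int, seed: int
) -> tuple[BSPVector, dict[str, float]]:
    """Monte-Carlo estimate of all 10 BSPs with standard errors.

    Uniform rejection sampling in the axis-aligned bounding box with a
    ray-crossing inside test; independent of the exact face-integral path.
    Density is fixed at 1000 kg m^-3.
    """
    if n_samples < 100:
        raise ValueError("n_samples too small for a meaningful estimate")
    rng = np.random.default_rng(seed)
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    box_volume = float(np.prod(hi - lo))

    points = rng.uniform(lo, hi, size=(n_samples, 3))
    inside = _ray_crossings_inside(points, mesh, rng)
    n_in = int(inside.sum())
    if n_in == 0:
        raise RuntimeError("no samples accepted; mesh volume too small for its bbox")
    acc = points[inside]
    density = 1000.0

    p_hat = n_in / n_samples
    volume = box_volume * p_hat
    volume_se = box_volume * math.sqrt(p_hat * (1 - p_hat) / n_samples)
    mass = density * volume
    com = acc.mean(axis=0)
    com_se = acc.std(axis=0, ddof=1) / math.sqrt(n_in)

    d = acc - com
    xx, yy, zz = d[:, 0] ** 2, d[:, 1] ** 2, d[:, 2] ** 2
    terms = {
        "ixx": yy + zz,
        "iyy": xx + zz,
        "izz": xx + yy,
        "ixy": d[:, 0] * d[:, 1],
        "ixz": d[:, 0] * d[:, 2],
        "iyz": d[:, 1] * d[:, 2],
    }
    inertia = {}
    inertia_se = {}
    for key, vals in terms.items():
        inertia[key] = mass * float(vals.mean())
        # relative volume error also feeds the estimate; fold both in
        mean_se = float(vals.std(ddof=1)) / math.sqrt(n_in)
        inertia_se[key] = math.hypot(mass * mean_se, density * volume_se * abs(float(vals.mean())))

    estimate = BSPVector(
        mass=mass,
        cm_x=float(com[0]),
        cm_y=float(com[1]),
        cm_z=float(com[2]),
        ixx=inertia["ixx"],
        iyy=inertia["iyy"],
        izz=inertia["izz"],
        ixy=inertia["ixy"],
        ixz=inertia["ixz"],
        iyz=inertia["iyz"],
        density=density,
    )
    stderr = {
        "mass": density * volume_se,
        "cm_x": float(com_se[0]),
        "cm_y": float(com_se[1]),
        "cm_z": float(com_se[2]),
        **{k: inertia_se[k] for k in ("ixx", "iyy", "izz", "ixy", "ixz", "iyz")},
    }
    return estimate, stderr
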