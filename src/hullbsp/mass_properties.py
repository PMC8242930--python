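"""Exact rigid-body mass properties of watertight triangle meshes.

Volume, first, second and mixed moments are evaluated exactly (up to
floating point) by face-projection integration: each surface integral is
reduced to line integrals over the projection of the face onto the
coordinate plane that maximises the face normal component, following the
classical polyhedral mass-property algorithm.

Sign convention: products of inertia are stored as positive integrals,
Ixy = rho * integral(x*y dV).  The assembled inertia tensor negates them:

    [[Ixx, -Ixy, -Ixz],
     [-Ixy, Iyy, -Iyz],
     [-Ixz, -Iyz, Izz]]
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, replace

import numpy as np

from .mesh_io import TriangleMesh, require_valid

__all__ = [
    "RawIntegrals",
    "BSPVector",
    "PARAMETER_NAMES",
    "polyhedron_integrals",
    "mass_properties",
    "rescale_density",
    "inertia_about_point",
]

#: Canonical ordering of the 10 body segment parameters.
PARAMETER_NAMES = (
    "mass",
    "cm_x",
    "cm_y",
    "cm_z",
    "ixx",
    "iyy",
    "izz",
    "ixy",
    "ixz",
    "iyz",
)


@dataclass(frozen=True)
class RawIntegrals:
    """The ten monomial volume integrals over the enclosed solid."""

    volume: float  # integral 1 dV
    x: float       # integral x dV
    y: float
    z: float
    xx: float      # integral x^2 dV
    yy: float
    zz: float
    xy: float      # integral x*y dV
    yz: float
    zx: float


@dataclass(frozen=True)
class BSPVector:
    """The 10 body segment parameters plus the density used.

    Moments and products are about axes through the centre of mass,
    parallel to the mesh frame axes. Products use the positive-integral
    convention (see module docstring).
    """

    mass: float
    cm_x: float
    cm_y: float
    cm_z: float
    ixx: float
    iyy: float
    izz: float
    ixy: float
    ixz: float
    iyz: float
    density: float = 1000.0

    @property
    def com(self) -> np.ndarray:
        return np.array([self.cm_x, self.cm_y, self.cm_z])

    def get(self, parameter: str) -> float:
        if parameter not in PARAMETER_NAMES:
            raise KeyError(f"unknown BSP parameter {parameter!r}")
        return getattr(self, parameter)

    def inertia_tensor(self) -> np.ndarray:
        """3x3 inertia tensor about the CoM (negated products off-diagonal)."""
        return np.array(
            [
                [self.ixx, -self.ixy, -self.ixz],
                [-self.ixy, self.iyy, -self.iyz],
                [-self.ixz, -self.iyz, self.izz],
            ]
        )

    def as_dict(self) -> dict:
        """Flat record in the JSON/CSV output schema (SI units)."""
        return {
            "mass_kg": self.mass,
            "cm_x_m": self.cm_x,
            "cm_y_m": self.cm_y,
            "cm_z_m": self.cm_z,
            "ixx_kgm2": self.ixx,
            "iyy_kgm2": self.iyy,
            "izz_kgm2": self.izz,
            "ixy_kgm2": self.ixy,
            "ixz_kgm2": self.ixz,
            "iyz_kgm2": self.iyz,
            "density_kgm3": self.density,
            "products_sign_convention": "positive_integral",
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.as_dict(), **kwargs)

    def to_csv(self) -> str:
        import io

        record = self.as_dict()
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=list(record))
        writer.writeheader()
        writer.writerow(record)
        return buf.getvalue()


def _face_integrals(vertices: np.ndarray) -> dict[str, float]:
    """Projection integrals over one triangular face.

    Returns the ten monomial volume-integral contributions of the face,
    computed by projecting onto the coordinate plane where the unit normal
    has its largest absolute component and integrating Green's-theorem
    line integrals over the projected edges.
    """
    a, b, c = vertices
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n)
    if norm == 0.0:
        return dict.fromkeys(
            ("volume", "x", "y", "z", "xx", "yy", "zz", "xy", "yz", "zx"), 0.0
        )
    n = n / norm

    # gamma = projection axis (largest |n| component); (alpha, beta, gamma)
    # is a cyclic permutation of (x, y, z).
    C = int(np.argmax(np.abs(n)))
    A = (C + 1) % 3
    B = (C + 2) % 3

    # Projection integrals over the face's projection onto the (A, B) plane.
    P1 = Pa = Pb = Paa = Pab = Pbb = Paaa = Paab = Pabb = Pbbb = 0.0
    pts = vertices[:, (A, B)]
    for i in range(3):
        a0, b0 = pts[i]
        a1, b1 = pts[(i + 1) % 3]
        da = a1 - a0
        db = b1 - b0
        a0_2 = a0 * a0
        a0_3 = a0_2 * a0
        b0_2 = b0 * b0
        b0_3 = b0_2 * b0
        a1_2 = a1 * a1
        b1_2 = b1 * b1

        C1 = a1 + a0
        Ca = a1 * C1 + a0_2
        Caa = a1 * Ca + a0_3
        Caaa = a1 * Caa + a0_2 * a0_2
        Cb = b1 * (b1 + b0) + b0_2
        Cbb = b1 * Cb + b0_3
        Cbbb = b1 * Cbb + b0_2 * b0_2
        Cab = 3 * a1_2 + 2 * a1 * a0 + a0_2
        Kab = a1_2 + 2 * a1 * a0 + 3 * a0_2
        Caab = a0 * Cab + 4 * a1 * a1_2
        Kaab = a1 * Kab + 4 * a0_3
        Cabb = 4 * b1 * b1_2 + 3 * b1_2 * b0 + 2 * b1 * b0_2 + b0_3
        Kabb = b1 * b1_2 + 2 * b1_2 * b0 + 3 * b1 * b0_2 + 4 * b0_3

        P1 += db * C1
        Pa += db * Ca
        Paa += db * Caa
        Paaa += db * Caaa
        Pb += da * Cb
        Pbb += da * Cbb
        Pbbb += da * Cbbb
        Pab += db * (b1 * Cab + b0 * Kab)
        Paab += db * (b1 * Caab + b0 * Kaab)
        Pabb += da * (a1 * Cabb + a0 * Kabb)

    P1 /= 2.0
    Pa /= 6.0
    Paa /= 12.0
    Paaa /= 20.0
    Pb /= -6.0
    Pbb /= -12.0
    Pbbb /= -20.0
    Pab /= 24.0
    Paab /= 60.0
    Pabb /= -60.0

    # Face plane: n . p = w offset
    w = float(-np.dot(n, a))
    na, nb, nc = float(n[A]), float(n[B]), float(n[C])
    k1 = 1.0 / nc
    k2 = k1 * k1
    k3 = k2 * k1
    k4 = k3 * k1

    Fa = k1 * Pa
    Fb = k1 * Pb
    Fc = -k2 * (na * Pa + nb * Pb + w * P1)
    Faa = k1 * Paa
    Fbb = k1 * Pbb
    Fcc = k3 * (
        na * na * Paa
        + 2 * na * nb * Pab
        + nb * nb * Pbb
        + w * (2 * (na * Pa + nb * Pb) + w * P1)
    )
    Faaa = k1 * Paaa
    Fbbb = k1 * Pbbb
    Fccc = -k4 * (
        na**3 * Paaa
        + 3 * na * na * nb * Paab
        + 3 * na * nb * nb * Pabb
        + nb**3 * Pbbb
        + 3 * w * (na * na * Paa + 2 * na * nb * Pab + nb * nb * Pbb)
        + w * w * (3 * (na * Pa + nb * Pb) + w * P1)
    )
    Faab = k1 * Paab
    Fbbc = -k2 * (na * Pabb + nb * Pbbb + w * Pbb)
    Fcca = k3 * (
        na * na * Paaa
        + 2 * na * nb * Paab
        + nb * nb * Pabb
        + w * (2 * (na * Paa + nb * Pab) + w * Pa)
    )

    out = dict.fromkeys(("volume", "x", "y", "z", "xx", "yy", "zz", "xy", "yz", "zx"), 0.0)
    axis_names = ("x", "y", "z")
    sq_names = ("xx", "yy", "zz")
    # T0 accumulates from the x-projection term only (standard trick).
    if A == 0:
        out["volume"] = float(n[0] * Fa)
    elif B == 0:
        out["volume"] = float(n[0] * Fb)
    else:
        out["volume"] = float(n[0] * Fc)

    out[axis_names[A]] = float(n[A] * Faa) / 2.0
    out[axis_names[B]] = float(n[B] * Fbb) / 2.0
    out[axis_names[C]] = float(n[C] * Fcc) / 2.0
    out[sq_names[A]] = float(n[A] * Faaa) / 3.0
    out[sq_names[B]] = float(n[B] * Fbbb) / 3.0
    out[sq_names[C]] = float(n[C] * Fccc) / 3.0

    # Mixed integrals: T_{alpha beta} pattern, mapped back to xy/yz/zx.
    mixed = {
        (0, 1): "xy",
        (1, 2): "yz",
        (2, 0): "zx",
    }
    out[mixed[(A, B)]] = float(n[A] * Faab) / 2.0
    out[mixed[(B, C)]] = float(n[B] * Fbbc) / 2.0
    out[mixed[(C, A)]] = float(n[C] * Fcca) / 2.0
    return out


def polyhedron_integrals(mesh: TriangleMesh, *, validate: bool = True) -> RawIntegrals:
    """Exact monomial volume integrals of a watertight outward-oriented mesh.

    Per-face contributions are accumulated with math.fsum to suppress
    cancellation error on large-coordinate meshes.
    """
    if validate:
        require_valid(mesh)
    keys = ("volume", "x", "y", "z", "xx", "yy", "zz", "xy", "yz", "zx")
    acc: dict[str, list[float]] = {k: [] for k in keys}
    v = mesh.vertices
    for f in mesh.faces:
        contrib = _face_integrals(v[f])
        for k in keys:
            acc[k].append(contrib[k])
    totals = {k: math.fsum(acc[k]) for k in keys}
    return RawIntegrals(**totals)


def mass_properties(
    mesh: TriangleMesh, density: float = 1000.0, *, validate: bool = True
) -> BSPVector:
    """Mass, centre of mass, and CoM-frame inertia of a uniform-density solid.

    Parameters
    ----------
    mesh : watertight, outward-oriented triangle mesh (meters).
    density : uniform density in kg m^-3 (default 1000, the density of water).
    """
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    raw = polyhedron_integrals(mesh, validate=validate)
    vol = raw.volume
    if vol <= 0:
        raise ValueError(f"mesh encloses non-positive volume {vol}")
    mass = density * vol
    cx, cy, cz = raw.x / vol, raw.y / vol, raw.z / vol

    # Origin-frame second moments -> CoM frame via the parallel axis theorem.
    ixx = density * (raw.yy + raw.zz) - mass * (cy * cy + cz * cz)
    iyy = density * (raw.xx + raw.zz) - mass * (cx * cx + cz * cz)
    izz = density * (raw.xx + raw.yy) - mass * (cx * cx + cy * cy)
    ixy = density * raw.xy - mass * cx * cy
    ixz = density * raw.zx - mass * cx * cz
    iyz = density * raw.yz - mass * cy * cz
    return BSPVector(
        mass=mass,
        cm_x=cx,
        cm_y=cy,
        cm_z=cz,
        ixx=ixx,
        iyy=iyy,
        izz=izz,
        ixy=ixy,
        ixz=ixz,
        iyz=iyz,
        density=density,
    )


def rescale_density(bsp: BSPVector, new_density: float) -> BSPVector:
    """Rescale a BSP vector to a new uniform density.

    Mass and all six inertia components scale by new_density / bsp.density;
    the centre of mass is unchanged.
    """
    if bsp.density <= 0:
        raise ValueError(f"source density must be positive, got {bsp.density}")
    if new_density <= 0:
        raise ValueError(f"new density must be positive, got {new_density}")
    k = new_density / bsp.density
    return replace(
        bsp,
        mass=bsp.mass * k,
        ixx=bsp.ixx * k,
        iyy=bsp.iyy * k,
        izz=bsp.izz * k,
        ixy=bsp.ixy * k,
        ixz=bsp.ixz * k,
        iyz=bsp.iyz * k,
        density=new_density,
    )


def inertia_about_point(bsp: BSPVector, point) -> dict[str, float]:
    """Inertia components about axes through `point` (parallel axis theorem).

    Returns a dict with keys ixx..iyz in the positive-integral product
    convention. inertia_about_point(bsp, bsp.com) reproduces bsp's own
    components.
    """
    point = np.asarray(point, dtype=float)
    d = bsp.com - point  # displacement of the CoM from the reference point
    m = bsp.mass
    dx, dy, dz = d
    return {
        "ixx": bsp.ixx + m * (dy * dy + dz * dz),
        "iyy": bsp.iyy + m * (dx * dx + dz * dz),
        "izz": bsp.izz + m * (dx * dx + dy * dy),
        "ixy": bsp.ixy + m * dx * dy,
        "ixz": bsp.ixz + m * dx * dz,
        "iyz": bsp.iyz + m * dy * dz,
    }
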