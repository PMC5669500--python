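"""Coarse-grained S-shaped protein scaffold (Atg17 dimer) model.

An Atg17 dimer is represented as a chain of 16 beads whose reference
geometry is a double crescent: two tangent-continuous quarter-circle arcs
(central angle 90 degrees each) whose planes are tilted by 15 degrees about
the shared tangent, matching the S-shaped dimer seen in crystal and
solution structures.  Harmonic bond, angle and dihedral terms preserve the
shape; membrane binding is an attractive square well on the distance of
each bead to the closest membrane triangle.

Lengths in tether units ``l``, energies in k_B T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import TriMesh

__all__ = [
    "DimerChain",
    "AdhesionParams",
    "HardCoreOverlap",
    "build_s_dimer",
    "build_straight_chain",
    "internal_energy",
    "bead_surface_distance",
    "closest_point_triangles",
    "adhesion_energy",
    "u_to_U",
    "U_to_u",
    "excluded_volume_check",
    "DEFAULT_ARC_RADIUS",
]

#: Arc radius for which 15 unit-length chords span the two quarter circles.
DEFAULT_ARC_RADIUS = 1.0 / (2.0 * np.sin(np.pi / 30.0))


class HardCoreOverlap(ValueError):
    """A bead was asked to be scored at distance <= d0 from the membrane.

    Such configurations are unreachable: proposals creating them must be
    rejected by the caller, never scored.
    """


@dataclass
class AdhesionParams:
    """Square-well membrane adhesion: hard core below ``d0`` (= l/2),
    energy ``-U * A_i`` of the closest triangle ``i`` for ``d0 < d <= d1``,
    zero beyond ``d1``.  The outer range ``d1`` defaults to one tether
    length (one membrane patch)."""

    U: float = 0.0
    d0: float = 0.5
    d1: float = 1.0

    def __post_init__(self):
        if not self.d1 > self.d0 > 0:
            raise ValueError("require d1 > d0 > 0")


@dataclass
class DimerChain:
    """16-bead protein chain with reference geometry and stiffnesses.

    ``bond_ref``, ``theta_ref`` and ``gamma_ref`` are recorded from the
    built geometry so the internal energy vanishes exactly at reference.
    Default stiffnesses (1e4 / 1e3 / 500 k_B T) give a relatively rigid
    dimer; flexible variants lower ``K_ang`` down to 200 k_B T.
    """

    positions: np.ndarray
    bond_ref: np.ndarray = field(repr=False)
    theta_ref: np.ndarray = field(repr=False)
    gamma_ref: np.ndarray = field(repr=False)
    K_bond: float = 1.0e4
    K_ang: float = 1.0e3
    K_dih: float = 500.0
    shape: str = "s"

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        n = len(self.positions)
        if len(self.bond_ref) != n - 1 or len(self.theta_ref) != n - 2 \
                or len(self.gamma_ref) != n - 3:
            raise ValueError("reference geometry sizes inconsistent with bead count")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def copy(self) -> "DimerChain":
        return DimerChain(self.positions.copy(), self.bond_ref, self.theta_ref,
                          self.gamma_ref, self.K_bond, self.K_ang, self.K_dih,
                          self.shape)


# ---------------------------------------------------------------------------
# chain geometry
# ---------------------------------------------------------------------------

def chain_internal_coordinates(pos: np.ndarray):
    """Bond lengths, bond angles (rad) and signed dihedrals (rad) of a chain.

    Dihedrals of (locally) collinear quadruples are returned as 0 with the
    convention that they carry no energy (the torsion is undefined there).
    """
    b = pos[1:] - pos[:-1]
    lengths = np.linalg.norm(b, axis=1)
    u = b / lengths[:, None]
    cosang = -np.einsum("ij,ij->i", u[:-1], u[1:])
    angles = np.arccos(np.clip(cosang, -1.0, 1.0))
    # dihedral between planes (b0,b1) and (b1,b2)
    n1 = np.cross(b[:-2], b[1:-1])
    n2 = np.cross(b[1:-1], b[2:])
    m1 = np.cross(n1, u[1:-1])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    dih = np.arctan2(y, x)
    degenerate = (np.linalg.norm(n1, axis=1) < 1e-9) | (np.linalg.norm(n2, axis=1) < 1e-9)
    dih[degenerate] = 0.0
    return lengths, angles, dih


def internal_energy(chain: DimerChain) -> float:
    """Harmonic internal energy: bonds + angles + dihedrals (k_B T).

    ``0.5 K_bond sum dL^2 + 0.5 K_ang sum dtheta^2 + 0.5 K_dih sum dgamma^2``
    over the 15 bonds, 14 angles and 13 dihedrals of a 16-bead chain;
    dihedral deviations are wrapped to (-pi, pi].
    """
    L, th, ga = chain_internal_coordinates(chain.positions)
    d_ga = np.angle(np.exp(1j * (ga - chain.gamma_ref)))
    return float(
        0.5 * chain.K_bond * np.sum((L - chain.bond_ref) ** 2)
        + 0.5 * chain.K_ang * np.sum((th - chain.theta_ref) ** 2)
        + 0.5 * chain.K_dih * np.sum(d_ga ** 2)
    )


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def s_curve_points(arc_radius: float, tilt_deg: float, n_beads: int) -> np.ndarray:
    """Bead positions equally spaced in arc length along the S double-crescent.

    Two quarter circles of radius ``R`` meet tangent-continuously; the plane
    of the second is rotated by ``tilt_deg`` about the shared tangent.  With
    zero tilt the tip-to-tip distance is ``2 sqrt(2) R``.
    """
    R = float(arc_radius)
    total = np.pi * R  # two quarter arcs
    s = np.linspace(0.0, total, n_beads)
    pts = np.empty((n_beads, 3))
    half = total / 2.0
    tau = np.deg2rad(tilt_deg)
    # arc 1: center (0, R, 0), from origin, initial tangent +x
    m1 = s <= half + 1e-12
    th = s[m1] / R
    pts[m1] = np.column_stack([R * np.sin(th), R * (1 - np.cos(th)), np.zeros(th.size)])
    # arc 2: curls the other way; its plane is spanned by the tangent y-hat
    # and x-hat rotated by tau about y-hat
    j = np.array([R, R, 0.0])          # junction
    xr = np.array([np.cos(tau), 0.0, np.sin(tau)])
    yh = np.array([0.0, 1.0, 0.0])
    c2 = j + R * xr
    ps = (s[~m1] - half) / R
    pts[~m1] = (c2[None, :]
                - R * np.cos(ps)[:, None] * xr[None, :]
                + R * np.sin(ps)[:, None] * yh[None, :])
    return pts


def _chain_from_points(pts: np.ndarray, shape: str, **stiff) -> DimerChain:
    L, th, ga = chain_internal_coordinates(pts)
    return DimerChain(pts, bond_ref=L, theta_ref=th, gamma_ref=ga,
                      shape=shape, **stiff)


def build_s_dimer(
    arc_radius: float = DEFAULT_ARC_RADIUS,
    tilt: float = 15.0,
    n_beads: int = 16,
    K_bond: float = 1.0e4,
    K_ang: float = 1.0e3,
    K_dih: float = 500.0,
) -> DimerChain:
    """S-shaped dimer: 16 beads on two tilted tangent quarter circles.

    The default radius makes the 15 chords unit length (L_0 = 1 in tether
    units); physically the crescent radius matches the radius of the
    vesicles before fusion (about 10 nm for 20-nm vesicles, giving the
    ~34-nm-long dimer).
    """
    if arc_radius <= 0:
        raise ValueError("arc_radius must be positive")
    pts = s_curve_points(arc_radius, tilt, n_beads)
    return _chain_from_points(pts, "s", K_bond=K_bond, K_ang=K_ang, K_dih=K_dih)


def build_straight_chain(
    n_beads: int = 16,
    bond_length: float = 1.0,
    K_bond: float = 1.0e4,
    K_ang: float = 1.0e3,
) -> DimerChain:
    """Straight control variant: collinear reference geometry (all interior
    angles pi), same bead count and adhesion as the S-dimer.  Dihedrals are
    undefined on a line, so the torsional stiffness is zero."""
    pts = np.zeros((n_beads, 3))
    pts[:, 0] = bond_length * np.arange(n_beads)
    chain = _chain_from_points(pts, "straight", K_bond=K_bond, K_ang=K_ang, K_dih=0.0)
    chain.theta_ref[:] = np.pi
    chain.gamma_ref[:] = 0.0
    return chain


# ---------------------------------------------------------------------------
# bead <-> membrane distances (reference implementation)
# ---------------------------------------------------------------------------

def closest_point_triangles(p: np.ndarray, verts: np.ndarray, tris: np.ndarray):
    """Closest point on each triangle to point ``p`` (vectorized Ericson).

    Returns an (n_t, 3) array of closest points; the minimum over triangles
    realizes the normal distance when the projection falls inside a
    triangle, and the distance to the nearest edge or corner otherwise.
    """
    a = verts[tris[:, 0]]
    b = verts[tris[:, 1]]
    c = verts[tris[:, 2]]
    ab, ac, ap = b - a, c - a, p[None, :] - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p[None, :] - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p[None, :] - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        out[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)                                   # vertex a
    assign((d3 >= 0) & (d4 <= d3), b)                                  # vertex b
    assign((d6 >= 0) & (d5 <= d6), c)                                  # vertex c
    vc = d1 * d4 - d3 * d2
    t = np.divide(d1, d1 - d3, out=np.zeros_like(d1), where=(d1 - d3) != 0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t[:, None] * ab)     # edge ab
    vb = d5 * d2 - d1 * d6
    w = np.divide(d2, d2 - d6, out=np.zeros_like(d2), where=(d2 - d6) != 0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w[:, None] * ac)     # edge ac
    va = d3 * d6 - d5 * d4
    den = (d4 - d3) + (d5 - d6)
    w2 = np.divide(d4 - d3, den, out=np.zeros_like(den), where=den != 0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           b + w2[:, None] * (c - b))                                  # edge bc
    denom = va + vb + vc
    v = np.divide(vb, denom, out=np.zeros_like(denom), where=denom != 0)
    w3 = np.divide(vc, denom, out=np.zeros_like(denom), where=denom != 0)
    assign(np.ones(len(a), dtype=bool), a + v[:, None] * ab + w3[:, None] * ac)
    return out


def bead_surface_distance(bead: np.ndarray, mesh: TriMesh):
    """Distance of a bead to the membrane surface.

    Returns ``(d, triangle index, side)`` where ``d`` is the minimum
    point-to-triangle distance over all triangles and ``side`` is +1 outside
    / -1 inside by the sign of ``(bead - foot) . n`` of the closest triangle.
    """
    bead = np.asarray(bead, dtype=np.float64)
    cps = closest_point_triangles(bead, mesh.vertices, mesh.triangles)
    d2 = np.einsum("ij,ij->i", bead[None, :] - cps, bead[None, :] - cps)
    i = int(np.argmin(d2))
    from .energetics import triangle_geometry

    normals, _, _ = triangle_geometry(mesh)
    side = 1 if np.dot(bead - cps[i], normals[i]) >= 0 else -1
    return float(np.sqrt(d2[i])), i, side


def adhesion_energy(chains, mesh: TriMesh, params: AdhesionParams):
    """Square-well binding energy ``E_bd = -U * A_bd`` and the bound-bead map.

    Every bead within ``(d0, d1]`` of the surface contributes minus ``U``
    times the area of its closest triangle; ``A_bd`` sums those areas.
    Raises :class:`HardCoreOverlap` for any bead at ``d <= d0``.
    """
    areas = mesh.triangle_areas()
    e = 0.0
    bound = []
    for ci, chain in enumerate(chains):
        for bi, bead in enumerate(chain.positions):
            d, tri, _ = bead_surface_distance(bead, mesh)
            if d <= params.d0:
                raise HardCoreOverlap(
                    f"bead {bi} of chain {ci} at d={d:.4f} <= d0={params.d0}"
                )
            if d <= params.d1:
                e -= params.U * areas[tri]
                bound.append((ci, bi, tri))
    return float(e), bound


# ---------------------------------------------------------------------------
# binding-strength conversion and excluded volume
# ---------------------------------------------------------------------------

def u_to_U(u: float, kappa: float, mean_triangle_area: float, n_beads: int = 16) -> float:
    """Convert the reduced binding strength ``u = U A_Atg / (8 pi kappa)``
    (dimer footprint ``A_Atg = 16 Abar`` in units of the sphere bending
    energy) to the adhesion energy density ``U`` (k_B T per unit area)."""
    if kappa <= 0 or mean_triangle_area <= 0:
        raise ValueError("kappa and mean triangle area must be positive")
    return u * 8.0 * np.pi * kappa / (n_beads * mean_triangle_area)


def U_to_u(U: float, kappa: float, mean_triangle_area: float, n_beads: int = 16) -> float:
    return U * n_beads * mean_triangle_area / (8.0 * np.pi * kappa)


def excluded_volume_check(
    chains,
    mesh: TriMesh,
    params: AdhesionParams,
    previous_sides: list[np.ndarray] | None = None,
    min_separation: float = 1.0,
) -> bool:
    """Hard-constraint check of a proposed configuration.

    Returns ``False`` (reject) if any bead pair from *different* dimers is
    closer than one tether length, any bead is within the hard core ``d0``
    of the membrane, or a bead's side flag changed relative to the last
    accepted state (membrane crossing); ``True`` otherwise.
    """
    pos = [c.positions for c in chains]
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            d2 = np.sum((pos[i][:, None, :] - pos[j][None, :, :]) ** 2, axis=2)
            if (d2 < min_separation ** 2).any():
                return False
    for ci, chain in enumerate(chains):
        for bi, bead in enumerate(chain.positions):
            d, _, side = bead_surface_distance(bead, mesh)
            if d <= params.d0:
                return False
            if previous_sides is not None and side != previous_sides[ci][bi]:
                return False
    return True
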