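"""Scalar observables and energy terms of a membrane configuration.

Discretization of the Helfrich bending energy on a triangulated vesicle:
the bending energy is accumulated per vertex as

    E_b = 2 kappa * sum_alpha M_alpha**2 / A_alpha

where ``M_alpha = (1/4) sum_(ij at alpha) l_ij * phi_ij`` is the vertex
mean-curvature contribution (``phi_ij`` the signed dihedral angle between
the outward normals of the two triangles sharing edge ``ij``, positive when
the surface is locally convex outward) and ``A_alpha`` is one third of the
area of the triangles at the vertex.  With these conventions a sphere has
``E_b -> 8 pi kappa``, reduced volume ``v -> 1`` and area difference
``da -> 1`` in the resolution limit.

Constraint potentials on area, volume and area difference are stiff
harmonic terms ``K (1 - X/X_ref)**2``.  All energies are in units of
``k_B T = 1``; lengths are in tether units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import TriMesh

__all__ = [
    "ShapeState",
    "EnergyModel",
    "triangle_geometry",
    "edge_dihedrals",
    "vertex_curvature_and_area",
    "bending_energy",
    "surface_area",
    "signed_volume",
    "reduced_volume",
    "fused_reduced_volume",
    "area_difference",
    "shape_state",
    "total_energy",
]


# ---------------------------------------------------------------------------
# per-triangle / per-edge geometry
# ---------------------------------------------------------------------------

def triangle_geometry(mesh: TriMesh):
    """Unit normals, areas, and signed volume contributions of all triangles.

    The signed volume contribution of triangle ``i`` is the tetrahedron
    volume to the origin, ``V_i = det(r_a, r_b, r_c) / 6``; the sum over a
    closed outward-oriented surface is the enclosed volume, independent of
    the reference point.
    """
    p = mesh.vertices[mesh.triangles]
    raw = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    areas = 0.5 * np.linalg.norm(raw, axis=1)
    normals = raw / (2.0 * areas)[:, None]
    vols = np.einsum("ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2])) / 6.0
    return normals, areas, vols


def edge_dihedrals(mesh: TriMesh, normals: np.ndarray | None = None):
    """Edge lengths and signed dihedral angles ``phi_ij``.

    ``phi = atan2((n1 x n2) . e_hat, n1 . n2)`` with ``e_hat`` the edge
    direction as traversed by the first adjacent triangle; positive for
    locally convex (outward-bulging) edges, so that a sphere has all
    ``phi > 0`` and stomatocyte invaginations contribute negatively.
    """
    if normals is None:
        normals, _, _ = triangle_geometry(mesh)
    ev = mesh.edges
    vec = mesh.vertices[ev[:, 1]] - mesh.vertices[ev[:, 0]]
    lengths = np.linalg.norm(vec, axis=1)
    ehat = vec / lengths[:, None]
    # orient ehat as the edge appears in the first adjacent triangle
    t1 = mesh.edge_tri[:, 0]
    tri1 = mesh.triangles[t1]
    flip = np.ones(len(ev))
    for k in range(3):
        mask = (tri1[:, k] == ev[:, 1]) & (tri1[:, (k + 1) % 3] == ev[:, 0])
        flip[mask] = -1.0
    ehat = ehat * flip[:, None]
    n1 = normals[mesh.edge_tri[:, 0]]
    n2 = normals[mesh.edge_tri[:, 1]]
    sin_phi = np.einsum("ij,ij->i", np.cross(n1, n2), ehat)
    cos_phi = np.einsum("ij,ij->i", n1, n2)
    return lengths, np.arctan2(sin_phi, cos_phi)


def vertex_curvature_and_area(mesh: TriMesh):
    """Per-vertex curvature contributions ``M_alpha`` and areas ``A_alpha``.

    ``sum_alpha M_alpha`` approximates the total mean-curvature integral
    (``4 pi R`` for a sphere of radius ``R``) and ``sum_alpha A_alpha``
    equals the total triangle area exactly.
    """
    normals, areas, _ = triangle_geometry(mesh)
    lengths, phis = edge_dihedrals(mesh, normals)
    nv = mesh.n_vertices
    M = np.zeros(nv)
    contrib = 0.25 * lengths * phis
    np.add.at(M, mesh.edges[:, 0], contrib)
    np.add.at(M, mesh.edges[:, 1], contrib)
    Av = np.zeros(nv)
    np.add.at(Av, mesh.triangles.ravel(), np.repeat(areas / 3.0, 3))
    return M, Av


# ---------------------------------------------------------------------------
# scalar observables
# ---------------------------------------------------------------------------

def surface_area(mesh: TriMesh) -> float:
    return mesh.area()


def signed_volume(mesh: TriMesh) -> float:
    """Enclosed volume; positive for outward orientation."""
    _, _, vols = triangle_geometry(mesh)
    return float(vols.sum())


def bending_energy(mesh: TriMesh, kappa: float) -> float:
    """Discrete Helfrich bending energy ``2 kappa sum M^2 / A`` (k_B T)."""
    M, Av = vertex_curvature_and_area(mesh)
    return float(2.0 * kappa * np.sum(M * M / Av))


def reduced_volume(area: float, volume: float) -> float:
    """``v = 6 sqrt(pi) V / A^(3/2)``; 1 for a sphere."""
    return float(6.0 * np.sqrt(np.pi) * volume / area ** 1.5)


def fused_reduced_volume(n: int) -> float:
    """Reduced volume ``1/sqrt(n)`` after area- and volume-conserving fusion
    of ``n`` equal spheres (0.707, 0.577, 0.5 for n = 2, 3, 4)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1.0 / np.sqrt(float(n))


def area_difference(mesh: TriMesh) -> float:
    """Normalized mean-curvature integral ``da = sum M_alpha / (2 sqrt(pi A))``.

    Scale invariant and equal to 1 for a sphere; the shape index / reaction
    coordinate of the vesicle shape branch.
    """
    M, _ = vertex_curvature_and_area(mesh)
    return float(M.sum() / (2.0 * np.sqrt(np.pi * mesh.area())))


@dataclass
class ShapeState:
    """Derived scalars of a membrane configuration."""

    area: float
    volume: float
    reduced_volume: float
    area_difference: float
    bending_energy: float
    vertex_curvature: np.ndarray = field(repr=False)
    vertex_area: np.ndarray = field(repr=False)


def shape_state(mesh: TriMesh, kappa: float = 20.0) -> ShapeState:
    M, Av = vertex_curvature_and_area(mesh)
    _, areas, vols = triangle_geometry(mesh)
    A = float(areas.sum())
    V = float(vols.sum())
    return ShapeState(
        area=A,
        volume=V,
        reduced_volume=reduced_volume(A, V),
        area_difference=float(M.sum() / (2.0 * np.sqrt(np.pi * A))),
        bending_energy=float(2.0 * kappa * np.sum(M * M / Av)),
        vertex_curvature=M,
        vertex_area=Av,
    )


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------

@dataclass
class EnergyModel:
    """Coupling constants and reference values of the total energy.

    ``E = E_b + K_A (1-A/A_ref)^2 + K_V (1-V/V_ref)^2
        [+ K_da (1-da/da_0)^2] [+ 0.5 k_umb (da-da_umb)^2] [+ E_bd + E_d]``

    All stiffnesses in k_B T.  Defaults correspond to free-vesicle runs
    (kappa = 20 k_B T, area/volume stiffness of order 1e6 restraining
    fluctuations to ~0.1%); protein production runs use kappa = 10,
    K_A = 2e5, K_V = 5e5.  A constraint term is active iff its stiffness is
    nonzero; its reference value must then be set.
    """

    kappa: float = 20.0
    K_A: float = 1.0e6
    K_V: float = 1.0e6
    K_da: float = 0.0
    A_ref: float | None = None
    V_ref: float | None = None
    da_0: float = 1.0
    # umbrella bias 0.5 * k_umb * (da - da_umb)^2 (used instead of K_da)
    k_umb: float = 0.0
    da_umb: float = 1.0
    # protein adhesion (square well); U in k_B T per unit membrane area
    U: float = 0.0
    d0: float = 0.5
    d1: float = 1.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for name in ("K_A", "K_V", "K_da", "k_umb", "U"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.d1 > self.d0 > 0:
            raise ValueError("require d1 > d0 > 0")

    def with_refs(self, A_ref: float, V_ref: float) -> "EnergyModel":
        return replace(self, A_ref=A_ref, V_ref=V_ref)

    def constraint_energy(self, A: float, V: float, da: float) -> dict[str, float]:
        terms = {}
        if self.K_A > 0:
            if self.A_ref is None:
                raise ValueError("area constraint active but A_ref unset")
            terms["E_area"] = self.K_A * (1.0 - A / self.A_ref) ** 2
        if self.K_V > 0:
            if self.V_ref is None:
                raise ValueError("volume constraint active but V_ref unset")
            terms["E_vol"] = self.K_V * (1.0 - V / self.V_ref) ** 2
        if self.K_da > 0:
            terms["E_da"] = self.K_da * (1.0 - da / self.da_0) ** 2
        if self.k_umb > 0:
            terms["E_umb"] = 0.5 * self.k_umb * (da - self.da_umb) ** 2
        return terms


def total_energy(mesh: TriMesh, chains, model: EnergyModel) -> dict[str, float]:
    """Full energy breakdown of a configuration (k_B T).

    ``chains`` is an iterable of :class:`~phagosim.proteins.DimerChain`
    (may be empty, in which case the result is the free-vesicle energy).
    Returns each term separately plus the sum under ``"E_total"``.
    """
    st = shape_state(mesh, model.kappa)
    terms = {"E_b": st.bending_energy}
    terms.update(model.constraint_energy(st.area, st.volume, st.area_difference))
    chains = list(chains or [])
    if chains:
        from .proteins import AdhesionParams, adhesion_energy, internal_energy

        params = AdhesionParams(U=model.U, d0=model.d0, d1=model.d1)
        e_bd, _ = adhesion_energy(chains, mesh, params)
        terms["E_bd"] = e_bd
        terms["E_d"] = float(sum(internal_energy(c) for c in chains))
    terms["E_total"] = float(sum(terms.values()))
    return terms
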