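"""Starting configurations: fused multi-sphere vesicles and dimer placement.

The state immediately after fusion of ``n`` equal vesicles is modeled as
``n`` spheres in a linear arrangement, punctured at their contact points
and joined by narrow necks.  The mesh is built as a surface of revolution
(rings of vertices along the fusion axis, stitched with a zig-zag band
triangulation) so that edge lengths stay near the tether length scale even
through the necks.  Protein dimers are placed in two groups of three, each
group straddling one neck on the same side of the fusion axis.
"""

from __future__ import annotations

import numpy as np

from .energetics import shape_state
from .mesh import TriMesh, build_edges, MeshTopologyError
from .proteins import DimerChain, build_s_dimer, build_straight_chain

__all__ = [
    "fused_spheres_mesh",
    "fused_sphere_geometry",
    "place_dimers",
    "fuse_vesicle_to_shape",
    "reference_values",
    "revolution_mesh",
    "oblate_mesh",
    "prolate_mesh",
    "stomatocyte_mesh",
    "SCENARIOS",
    "build_scenario",
]


# ---------------------------------------------------------------------------
# analytic geometry of the fused-sphere union
# ---------------------------------------------------------------------------

def fused_sphere_geometry(n: int, neck_radius_fraction: float = 0.1,
                          target_area: float | None = None):
    """Sphere radius, centers (on the z axis) and neck planes of the union.

    ``target_area`` fixes the union surface area (defaults to the area of a
    20*4**3-triangle tessellation with unit tether length, A = 1280*sqrt(3)/4,
    so that the mesh resolution matches the 642-vertex vesicles).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < neck_radius_fraction < 0.5:
        raise ValueError("neck_radius_fraction must be in (0, 0.5)")
    if target_area is None:
        target_area = 1280 * np.sqrt(3.0) / 4.0
    f = neck_radius_fraction
    h_over_R = np.sqrt(1.0 - f * f)
    # union area = n*4 pi R^2 - 2(n-1) * 2 pi R (R - h)   (spherical caps)
    area_unit = n * 4 * np.pi - 2 * (n - 1) * 2 * np.pi * (1 - h_over_R)
    R = np.sqrt(target_area / area_unit)
    h = R * h_over_R
    centers = np.array([(2 * k - (n - 1)) * h for k in range(n)])
    necks = np.array([(centers[k] + centers[k + 1]) / 2 for k in range(n - 1)])
    return R, centers, necks


def _union_profile(n, R, centers):
    """Meridian of the union as a list of (sphere index, theta range) arcs,
    with theta the polar angle from the north (+z) pole of each sphere."""
    h = (centers[1] - centers[0]) / 2 if n > 1 else R
    cut = np.arccos(h / R) if n > 1 else 0.0
    arcs = []
    for k in range(n):  # from south (k=0) to north (k=n-1)
        th_hi = np.pi if k == 0 else np.pi - cut
        th_lo = 0.0 if k == n - 1 else cut
        arcs.append((k, th_hi, th_lo))  # traversed from high theta to low
    return arcs


def _meridian_points(n, R, centers, ds):
    """Sample the meridian at arc-length spacing ~ds.

    Returns arrays z, rho (excluding the two poles).
    """
    arcs = _union_profile(n, R, centers)
    zs, rhos = [], []
    for k, th_hi, th_lo in arcs:
        length = R * (th_hi - th_lo)
        m = max(1, int(round(length / ds)))
        # interior sample points of this arc (avoid duplicating junctions)
        ths = th_hi - (np.arange(m) + 0.5) * (th_hi - th_lo) / m
        for th in ths:
            zs.append(centers[k] + R * np.cos(th))
            rhos.append(R * np.sin(th))
    order = np.argsort(zs)
    return np.asarray(zs)[order], np.asarray(rhos)[order]


def surface_distance_point(p, n, R, centers):
    """Signed distance from a point to the analytic fused-sphere union
    (positive outside)."""
    d = min(np.sqrt(p[0] ** 2 + p[1] ** 2 + (p[2] - c) ** 2) - R
            for c in centers)
    return d


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def _stitch_band(tris, ring_lo, ang_lo, ring_hi, ang_hi):
    """Zig-zag triangulation between two vertex rings (any sizes), with
    consistent orientation (outward for CCW azimuth along +z)."""
    m, q = len(ring_lo), len(ring_hi)
    i = j = 0
    while i < m or j < q:
        np_ang = ang_lo[0] + 2 * np.pi if i + 1 > m - 1 and i < m else \
            (ang_lo[i + 1] if i < m - 1 else ang_lo[0] + 2 * np.pi)
        nq_ang = ang_hi[0] + 2 * np.pi if j + 1 > q - 1 and j < q else \
            (ang_hi[j + 1] if j < q - 1 else ang_hi[0] + 2 * np.pi)
        if i < m and (j >= q or np_ang <= nq_ang):
            tris.append((ring_lo[i], ring_lo[(i + 1) % m], ring_hi[j % q]))
            i += 1
        else:
            tris.append((ring_lo[i % m], ring_hi[(j + 1) % q], ring_hi[j % q]))
            j += 1


def fused_spheres_mesh(n: int, neck_radius_fraction: float = 0.1,
                       target_area: float | None = None,
                       edge_length: float = 1.0) -> TriMesh:
    """Closed genus-0 mesh of ``n`` equal spheres fused along the z axis.

    Overlapping spheres are punctured at their contact circles (radius
    ``neck_radius_fraction * R``), giving narrow necks; the reduced volume
    approaches ``1/sqrt(n)`` as the necks narrow.  ``n = 1`` gives a plain
    revolution sphere.  The ring construction keeps edge lengths near
    ``edge_length``; residual tether violations (a few edges at the necks)
    heal in the first MC sweeps.
    """
    R, centers, _ = fused_sphere_geometry(n, neck_radius_fraction, target_area)
    ds = edge_length * np.sqrt(3.0) / 2.0
    z, rho = _meridian_points(n, R, centers, ds)
    verts = [np.array([0.0, 0.0, centers[0] - R])]  # south pole
    rings = []
    angles = []
    for irow in range(len(z)):
        mrow = max(3, int(round(2 * np.pi * rho[irow] / edge_length)))
        off = (irow % 2) * np.pi / mrow
        ang = off + 2 * np.pi * np.arange(mrow) / mrow
        idx = []
        for a in ang:
            idx.append(len(verts))
            verts.append(np.array([rho[irow] * np.cos(a),
                                   rho[irow] * np.sin(a), z[irow]]))
        rings.append(idx)
        angles.append(ang)
    north = len(verts)
    verts.append(np.array([0.0, 0.0, centers[-1] + R]))

    tris: list[tuple[int, int, int]] = []
    r0 = rings[0]
    for i in range(len(r0)):  # south cap
        tris.append((0, r0[(i + 1) % len(r0)], r0[i]))
    for k in range(len(rings) - 1):
        _stitch_band(tris, rings[k], angles[k], rings[k + 1], angles[k + 1])
    rl = rings[-1]
    for i in range(len(rl)):  # north cap
        tris.append((north, rl[i], rl[(i + 1) % len(rl)]))

    verts = np.asarray(verts)
    tris = np.asarray(tris, dtype=np.int64)
    mesh = TriMesh(verts, tris)
    if shape_state(mesh).volume < 0:  # enforce outward orientation
        tris = tris[:, [0, 2, 1]]
        mesh = TriMesh(verts, tris)
    return mesh


def reference_values(mesh: TriMesh, n: int) -> tuple[float, float]:
    """(A_ref, V_ref) that drive the constrained vesicle to v = 1/sqrt(n)."""
    A_ref = mesh.area()
    V_ref = A_ref ** 1.5 / (6.0 * np.sqrt(np.pi) * np.sqrt(float(n)))
    return A_ref, V_ref


# ---------------------------------------------------------------------------
# generic revolution meshes (anchors for the disk / cup shape families)
# ---------------------------------------------------------------------------

def revolution_mesh(z: np.ndarray, rho: np.ndarray,
                    edge_length: float = 1.0) -> TriMesh:
    """Closed mesh of the surface of revolution of the profile (z, rho).

    The profile runs from the south pole (``rho[0] = 0``) to the north pole
    (``rho[-1] = 0``); interior samples become vertex rings stitched with the
    same zig-zag bands as :func:`fused_spheres_mesh`.  Sample the profile at
    arc-length spacing ``~ edge_length * sqrt(3)/2`` for near-equilateral
    triangles.
    """
    z = np.asarray(z, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if len(z) < 4:
        raise ValueError("profile needs at least 4 samples")
    verts = [np.array([0.0, 0.0, z[0]])]
    rings, angles = [], []
    for irow in range(1, len(z) - 1):
        r = rho[irow]
        mrow = max(3, int(round(2 * np.pi * r / edge_length)))
        off = (irow % 2) * np.pi / mrow
        ang = off + 2 * np.pi * np.arange(mrow) / mrow
        idx = []
        for a in ang:
            idx.append(len(verts))
            verts.append(np.array([r * np.cos(a), r * np.sin(a), z[irow]]))
        rings.append(idx)
        angles.append(ang)
    north = len(verts)
    verts.append(np.array([0.0, 0.0, z[-1]]))
    tris: list[tuple[int, int, int]] = []
    r0 = rings[0]
    for i in range(len(r0)):
        tris.append((0, r0[(i + 1) % len(r0)], r0[i]))
    for k in range(len(rings) - 1):
        _stitch_band(tris, rings[k], angles[k], rings[k + 1], angles[k + 1])
    rl = rings[-1]
    for i in range(len(rl)):
        tris.append((north, rl[i], rl[(i + 1) % len(rl)]))
    verts = np.asarray(verts)
    tris = np.asarray(tris, dtype=np.int64)
    mesh = TriMesh(verts, tris)
    if shape_state(mesh).volume < 0:
        mesh = TriMesh(verts, tris[:, [0, 2, 1]])
    return mesh


def _scale_to_area(mesh: TriMesh, area: float) -> TriMesh:
    s = np.sqrt(area / mesh.area())
    return TriMesh(mesh.vertices * s, mesh.triangles)


def _profile_scale(z, rho, target_area):
    """Scale factor mapping a unit profile to revolution area target_area."""
    ds = np.hypot(np.diff(z), np.diff(rho))
    rmid = 0.5 * (np.asarray(rho)[1:] + np.asarray(rho)[:-1])
    A_unit = 2.0 * np.pi * float(np.sum(rmid * ds))
    return np.sqrt(target_area / A_unit)


def _resample_arclength(z, rho, spacing):
    """Resample a pole-to-pole profile at uniform arc-length spacing (keeps
    both endpoints); near-equilateral triangles need rings at ~ sqrt(3)/2
    times the edge length."""
    z = np.asarray(z, dtype=float)
    rho = np.asarray(rho, dtype=float)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(z),
                                                  np.diff(rho)))])
    n = max(4, int(round(s[-1] / spacing)))
    si = np.linspace(0.0, s[-1], n + 1)
    return np.interp(si, s, z), np.interp(si, s, rho)


def oblate_mesh(aspect: float = 0.35, target_area: float | None = None,
                n_profile: int = 40) -> TriMesh:
    """Oblate spheroid (polar/equatorial aspect < 1) scaled to the target
    area; the starting point of the disk shape family."""
    if target_area is None:
        target_area = 1280 * np.sqrt(3.0) / 4.0
    th = np.linspace(np.pi, 0.0, 8 * n_profile)
    zs, rs = aspect * np.cos(th), np.sin(th)
    scale = _profile_scale(zs, rs, target_area)
    zs, rs = _resample_arclength(zs * scale, rs * scale,
                                 np.sqrt(3.0) / 2.0)
    return _scale_to_area(revolution_mesh(zs, rs), target_area)


def prolate_mesh(aspect: float = 3.0, target_area: float | None = None,
                 n_profile: int = 40) -> TriMesh:
    """Prolate spheroid (polar/equatorial aspect > 1); the starting point
    of the tube shape family at reduced volumes without a fused-sphere
    construction."""
    return oblate_mesh(aspect=aspect, target_area=target_area,
                       n_profile=n_profile)


def stomatocyte_mesh(mouth_angle: float = 0.55, dimple_radius: float = 0.9,
                     target_area: float | None = None) -> TriMesh:
    """Sphere with a spherical inward dimple (axisymmetric cup/stomatocyte).

    The outer sphere (unit radius before scaling) is cut at polar angle
    ``mouth_angle`` from +z; an inner spherical arc of radius
    ``dimple_radius`` caps the mouth, curving down into the interior.
    """
    if target_area is None:
        target_area = 1280 * np.sqrt(3.0) / 4.0
    th = np.linspace(np.pi, mouth_angle, 30)
    zs = list(np.cos(th))
    rs = list(np.sin(th))
    zc = np.cos(mouth_angle) - np.sqrt(
        max(dimple_radius ** 2 - np.sin(mouth_angle) ** 2, 1e-9))
    a_ring = np.arctan2(np.cos(mouth_angle) - zc, np.sin(mouth_angle))
    for a in np.linspace(a_ring, -np.pi / 2, 20)[1:]:
        rs.append(dimple_radius * np.cos(a))
        zs.append(zc + dimple_radius * np.sin(a))
    zs, rs = np.asarray(zs), np.asarray(rs)
    scale = _profile_scale(zs, rs, target_area)
    zs, rs = _resample_arclength(zs * scale, rs * scale,
                                 np.sqrt(3.0) / 2.0)
    return _scale_to_area(revolution_mesh(zs, rs), target_area)


# ---------------------------------------------------------------------------
# dimer placement
# ---------------------------------------------------------------------------

def _axis_rotation(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _rigid_place(template: np.ndarray, jt, Tt, Nt, w_j, t_w, n_w,
                 omega: float = 0.0, psi: float = 0.0):
    """Map the template chain rigidly so its anchor point ``jt`` (with local
    tangent ``Tt`` and inward normal ``Nt``) lands on ``w_j`` with tangent
    ``t_w`` and inward normal (toward the sphere center) ``n_w``; ``omega``
    pre-rotates about the tangent, ``psi`` about the surface normal."""
    Bt = np.cross(Tt, Nt)
    b_w = np.cross(t_w, n_w)
    Rm = np.column_stack([t_w, n_w, b_w]) @ np.column_stack([Tt, Nt, Bt]).T
    Rm = _axis_rotation(-n_w, psi) @ _axis_rotation(t_w, omega) @ Rm
    return w_j[None, :] + (template - jt[None, :]) @ Rm.T


def place_dimers(mesh: TriMesh, n_spheres: int = 3, n_dimers: int = 6,
                 neck_radius_fraction: float = 0.1,
                 offset: float = 0.75, d0: float = 0.5, d1: float = 1.0,
                 shape: str = "s", azimuth_spread: float = 0.45,
                 K_ang: float = 1.0e3, seed: int = 0) -> list[DimerChain]:
    """Two groups of three dimers straddling the necks of a fused vesicle.

    Each dimer is a rigid copy of the reference chain placed with its
    junction over a neck at distance ``offset`` from the surface, its first
    crescent hugging the lower sphere; group members are separated in
    azimuth.  A small scan over the tilt about the local surface normal
    picks the orientation with the most beads inside the adhesion range
    while avoiding the hard core.  Raises RuntimeError if no hard-core-free
    placement exists.
    """
    if n_dimers % 2 != 0:
        raise ValueError("n_dimers must be even (two symmetric groups)")
    R, centers, necks = fused_sphere_geometry(n_spheres, neck_radius_fraction)
    if len(necks) == 0:
        raise ValueError("need at least two fused spheres to place dimers")
    neck_pair = (necks[0], necks[-1])
    per_group = n_dimers // 2
    arc_radius = R + offset
    if shape == "s":
        template = build_s_dimer(arc_radius=arc_radius, K_ang=K_ang)
        # analytic junction of the two arcs: (R, R, 0), tangent +y, inward
        # normal (toward the first-arc center) -x
        anchor = np.array([arc_radius, arc_radius, 0.0])
        Tt = np.array([0.0, 1.0, 0.0])
        Nt = np.array([-1.0, 0.0, 0.0])
    elif shape == "straight":
        template = build_straight_chain(K_ang=K_ang)
        anchor = template.positions.mean(axis=0)
        Tt = np.array([1.0, 0.0, 0.0])
        Nt = np.array([0.0, -1.0, 0.0])
    else:
        raise ValueError(f"unknown chain shape {shape!r}")
    chains: list[DimerChain] = []
    group_phis = azimuth_spread * (np.arange(per_group) - (per_group - 1) / 2)
    for g, z_neck in enumerate(neck_pair):
        # the two spheres joined by this neck
        k_lo = int(np.argmin([abs(c - (z_neck - 0.5)) for c in centers]))
        c_lo = centers[k_lo]
        c_hi = 2 * z_neck - c_lo
        h = z_neck - c_lo
        rho_j = np.sqrt(max(arc_radius ** 2 - h ** 2, 1e-9))
        for im, phi in enumerate(group_phis):
            e_rho = np.array([np.cos(phi), np.sin(phi), 0.0])
            if shape == "straight":
                # strand parallel to the fusion axis, touching both spheres
                # at their equators (common external tangent line)
                w_j = (R + offset) * e_rho + np.array([0.0, 0.0, z_neck])
                t_w = np.array([0.0, 0.0, 1.0])
                n_w = -e_rho
            else:
                # alternate the hugged sphere so group members separate axially
                c_hug = c_lo if im % 2 == 0 else c_hi
                w_j = rho_j * e_rho + np.array([0.0, 0.0, z_neck])
                c_vec = np.array([0.0, 0.0, c_hug])
                n_w = (c_vec - w_j)
                n_w /= np.linalg.norm(n_w)
                # the only direction tangent to both offset spheres at the
                # neck circle is azimuthal: the S wraps across the neck
                # sideways, its crescents peeling onto the two spheres
                t_w = np.array([-np.sin(phi), np.cos(phi), 0.0])
                n_w = n_w - t_w * (n_w @ t_w)
                n_w /= np.linalg.norm(n_w)
            # scan rigid orientations; if the surface is too crowded (the
            # dimers are longer than the neck circumference), lift the
            # junction outward and let the chain drape over its neighbours —
            # it binds during the first sweeps of the run
            # outward bisector of the two sphere normals at the neck circle
            u1 = w_j - np.array([0.0, 0.0, c_lo])
            u2 = w_j - np.array([0.0, 0.0, c_hi])
            e_out = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
            e_out /= np.linalg.norm(e_out)
            best = None
            for lift in (0.0, 0.8, 1.6, 2.4):
                wj2 = w_j + e_out * lift
                for omega in np.deg2rad(np.arange(0, 360, 20)):
                    for psi in np.deg2rad(np.arange(-40, 41, 10)):
                        pts = _rigid_place(template.positions, anchor, Tt, Nt,
                                           wj2, t_w, n_w, omega, psi)
                        dists = np.array(
                            [surface_distance_point(p, n_spheres, R, centers)
                             for p in pts])
                        if dists.min() <= d0 + 0.05:
                            continue
                        clash = False
                        for other in chains:
                            d2 = np.sum((pts[:, None, :]
                                         - other.positions[None, :, :]) ** 2,
                                        axis=2)
                            if (d2 < 1.05).any():
                                clash = True
                                break
                        if clash:
                            continue
                        score = int(((dists > d0) & (dists <= d1)).sum())
                        if best is None or score > best[0]:
                            best = (score, pts)
                if best is not None and best[0] > 0:
                    break
            if best is None:
                raise RuntimeError("dimer placement failed: no admissible "
                                   "orientation")
            chain = template.copy()
            chain.positions = best[1]
            chains.append(chain)
    return chains


# ---------------------------------------------------------------------------
# fusing one more vesicle to an existing shape
# ---------------------------------------------------------------------------

def _boundary_loop(triangles, removed_vertex, nv):
    """Ordered vertex loop around a removed vertex's one-ring."""
    ring_edges = {}
    for t in triangles:
        if removed_vertex in t:
            rest = [v for v in t if v != removed_vertex]
            # directed edge of the triangle opposite the removed vertex,
            # keeping the triangle's own orientation
            idx = list(t).index(removed_vertex)
            a, b = t[(idx + 1) % 3], t[(idx + 2) % 3]
            ring_edges[a] = b
    loop = [next(iter(ring_edges))]
    while len(loop) < len(ring_edges):
        loop.append(ring_edges[loop[-1]])
    return loop


def fuse_vesicle_to_shape(mesh: TriMesh, sphere: TriMesh,
                          attachment_point, gap: float = 1.0) -> TriMesh:
    """Join a spherical vesicle to an existing shape by a narrow neck.

    The vertex of each mesh closest to the attachment axis is removed and
    the two one-ring boundary loops are stitched with a zig-zag band,
    producing a closed genus-0 composite.  ``gap`` is the neck length in
    tether units.  Raises ValueError for self-intersecting attachments
    (sphere overlapping the host surface).
    """
    attachment_point = np.asarray(attachment_point, dtype=float)
    # host vertex nearest the attachment point
    iv = int(np.argmin(np.linalg.norm(mesh.vertices - attachment_point, axis=1)))
    p = mesh.vertices[iv]
    # outward direction: area-weighted normal of incident triangles
    normal = np.zeros(3)
    for t, tt in enumerate(mesh.triangles):
        if iv in tt:
            a, b, c = mesh.vertices[tt]
            normal += np.cross(b - a, c - a)
    normal /= np.linalg.norm(normal)

    sc = sphere.vertices.mean(axis=0)
    r_s = np.linalg.norm(sphere.vertices - sc, axis=1).mean()
    center = p + normal * (r_s + gap)
    sv = sphere.vertices - sc + center
    # sphere vertex facing the host
    jv = int(np.argmin(sv @ normal))
    # self-intersection guard: every host vertex outside the sphere
    if (np.linalg.norm(mesh.vertices - center, axis=1) < 0.95 * r_s).sum() > 0:
        raise ValueError("attachment would self-intersect")

    host_tris = [tuple(t) for t in mesh.triangles if iv not in t]
    loop_h = _boundary_loop(mesh.triangles, iv, mesh.n_vertices)
    sph_tris = [tuple(int(v) + mesh.n_vertices for v in t)
                for t in sphere.triangles if jv not in t]
    loop_s = [v + mesh.n_vertices
              for v in _boundary_loop(sphere.triangles, jv, sphere.n_vertices)]

    verts = np.vstack([mesh.vertices, sv])
    axis = normal
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    def angs(loop, about):
        rel = verts[loop] - about
        return np.arctan2(rel @ e2, rel @ e1)

    mid = 0.5 * (p + center - axis * r_s)
    for flip in (False, True):
        ls = list(reversed(loop_s)) if flip else list(loop_s)
        a_h = angs(loop_h, mid)
        a_s = angs(ls, mid)
        # rotate loops to start near angle 0 and unwrap increasing
        def order(loop, a):
            k = int(np.argmin(np.mod(a, 2 * np.pi)))
            loop2 = loop[k:] + loop[:k]
            a2 = np.mod(a, 2 * np.pi)
            a2 = np.concatenate([a2[k:], a2[:k] + 2 * np.pi])
            a2 = np.maximum.accumulate(a2)
            return loop2, a2 - a2[0]
        lh, ah = order(list(loop_h), a_h)
        ls2, as_ = order(ls, a_s)
        tris = list(host_tris) + list(sph_tris)
        _stitch_band(tris, lh, ah, ls2, as_)
        tri_arr = np.asarray(tris, dtype=np.int64)
        # drop the two removed vertices (now isolated) and reindex
        keep = np.ones(len(verts), dtype=bool)
        keep[iv] = False
        keep[jv + mesh.n_vertices] = False
        remap = np.cumsum(keep) - 1
        try:
            out = TriMesh(verts[keep].copy(), remap[tri_arr])
        except MeshTopologyError:
            continue
        if shape_state(out).volume < 0:
            out = TriMesh(out.vertices, out.triangles[:, [0, 2, 1]])
        return out
    raise MeshTopologyError("could not stitch the two boundary loops")


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

SCENARIOS = {
    "free_vesicle": dict(n_spheres=1, n_dimers=0, shape="s"),
    "fused3_s6": dict(n_spheres=3, n_dimers=6, shape="s"),
    "fused4_s6": dict(n_spheres=4, n_dimers=6, shape="s"),
    "fused3_straight6": dict(n_spheres=3, n_dimers=6, shape="straight"),
}


def build_scenario(name: str, neck_radius_fraction: float = 0.1,
                   K_ang: float = 1.0e3, seed: int = 0):
    """Mesh + chains + (A_ref, V_ref) for a named scenario preset."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; options: {sorted(SCENARIOS)}")
    cfg = SCENARIOS[name]
    mesh = fused_spheres_mesh(cfg["n_spheres"], neck_radius_fraction)
    chains = []
    if cfg["n_dimers"]:
        chains = place_dimers(mesh, cfg["n_spheres"], cfg["n_dimers"],
                              neck_radius_fraction, shape=cfg["shape"],
                              K_ang=K_ang, seed=seed)
    A_ref, V_ref = reference_values(mesh, cfg["n_spheres"])
    return mesh, chains, (A_ref, V_ref)
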