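"""Closed genus-0 triangulated surfaces with tether bounds and edge-flip fluidity.

The membrane is a dynamically triangulated mesh: a closed, orientable,
2-manifold triangulation whose fluidity is realized by edge flips and whose
triangles are kept non-degenerate by a hard tether interval on every edge
length.  Coordinates are dimensionless, in units of the tether length ``l``
derived from the mean triangle area.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field

import numpy as np

#: Hard cap on vertex degree (number of incident edges/triangles).
MAX_DEGREE = 24

#: Default ratio between upper and lower tether bound.  sqrt(3) keeps
#: triangles non-degenerate; the literal factor 3 is also supported.
TETHER_RATIO = np.sqrt(3.0)


class MeshTopologyError(ValueError):
    """Raised when a triangle soup cannot be assembled into a closed
    orientable manifold."""


def build_edges(triangles: np.ndarray, n_vertices: int):
    """Assemble the edge tables of an oriented closed triangulation.

    Returns ``(edges, edge_tri, tri_edge)`` where ``edges[e] = (i, j)`` is
    ordered as the edge appears in its first adjacent triangle,
    ``edge_tri[e]`` are the two adjacent triangle indices and
    ``tri_edge[t, k]`` is the edge between local vertices ``k`` and
    ``(k+1) % 3`` of triangle ``t``.

    Raises :class:`MeshTopologyError` if any edge does not have exactly one
    traversal in each direction (open boundary, non-manifold edge, or
    inconsistent orientation).
    """
    triangles = np.asarray(triangles, dtype=np.int64)
    nt = len(triangles)
    directed: dict[tuple[int, int], tuple[int, int]] = {}
    for t in range(nt):
        a, b, c = triangles[t]
        if a == b or b == c or a == c:
            raise MeshTopologyError(f"triangle {t} has repeated vertices")
        for k, (i, j) in enumerate(((a, b), (b, c), (c, a))):
            key = (int(i), int(j))
            if key in directed:
                raise MeshTopologyError(
                    f"directed edge {key} traversed twice: orientation inconsistent"
                )
            directed[key] = (t, k)

    edges = []
    edge_tri = []
    tri_edge = np.full((nt, 3), -1, dtype=np.int64)
    for (i, j), (t, k) in directed.items():
        if i > j:
            continue
        if (j, i) not in directed:
            raise MeshTopologyError(f"edge ({i},{j}) has no opposite traversal (boundary)")
        t2, k2 = directed[(j, i)]
        e = len(edges)
        edges.append((i, j))
        edge_tri.append((t, t2))
        tri_edge[t, k] = e
        tri_edge[t2, k2] = e
    if (tri_edge < 0).any():
        raise MeshTopologyError("triangle with unmatched edge")
    return (
        np.asarray(edges, dtype=np.int64),
        np.asarray(edge_tri, dtype=np.int64),
        tri_edge,
    )


@dataclass
class TriMesh:
    """Closed orientable genus-0 triangulated surface.

    Attributes
    ----------
    vertices : (n_v, 3) float array
        Vertex positions in units of the tether length.
    triangles : (n_t, 3) int array
        Ordered vertex triples with consistent outward orientation.
    edges, edge_tri, tri_edge
        Derived connectivity tables (see :func:`build_edges`).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    edges: np.ndarray = field(default=None, repr=False)
    edge_tri: np.ndarray = field(default=None, repr=False)
    tri_edge: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.edges is None:
            self.edges, self.edge_tri, self.tri_edge = build_edges(
                self.triangles, len(self.vertices)
            )

    # -- counts ------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_triangles

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            self.edges.copy(),
            self.edge_tri.copy(),
            self.tri_edge.copy(),
        )

    # -- simple geometry ---------------------------------------------------
    def edge_lengths(self) -> np.ndarray:
        d = self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def mean_triangle_area(self) -> float:
        return self.area() / self.n_triangles

    def vertex_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=np.int64)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def vertex_edge_table(self):
        """(n_v, MAX_DEGREE) table of incident edge indices plus degrees."""
        deg = np.zeros(self.n_vertices, dtype=np.int64)
        tab = np.full((self.n_vertices, MAX_DEGREE), -1, dtype=np.int64)
        for e, (i, j) in enumerate(self.edges):
            for v in (i, j):
                if deg[v] >= MAX_DEGREE:
                    raise MeshTopologyError(f"vertex {v} exceeds MAX_DEGREE")
                tab[v, deg[v]] = e
                deg[v] += 1
        return tab, deg


def tether_length(mean_triangle_area: float) -> float:
    """Tether length scale ``l = sqrt(4 * Abar / sqrt(3))`` — the edge of an
    equilateral triangle whose area equals the mean triangle area."""
    return float(np.sqrt(4.0 * mean_triangle_area / np.sqrt(3.0)))


def tether_bounds(mesh_or_l, ratio: float = TETHER_RATIO) -> tuple[float, float]:
    """Edge-length interval ``[l_min, l_max]`` with ``l_max = ratio * l_min``.

    The lower bound is placed so that the tether length scale sits at the
    geometric midpoint of the interval, which centres the edges of a fresh
    near-uniform triangulation.  Pass ``ratio=3`` for the literal wide
    interval ``[l, 3 l]`` variant (with ``l_min = l``).
    """
    if isinstance(mesh_or_l, TriMesh):
        l = tether_length(mesh_or_l.mean_triangle_area())
    else:
        l = float(mesh_or_l)
    if ratio >= 2.5:  # literal [l, ratio*l] reading
        return l, ratio * l
    lo = l / np.sqrt(ratio)
    return lo, lo * ratio


# ---------------------------------------------------------------------------
# icosphere construction
# ---------------------------------------------------------------------------

def _icosahedron():
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    tris = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=np.int64,
    )
    return verts, tris


def build_icosphere(subdivision_level: int, radius: float = 1.0) -> TriMesh:
    """Geodesic sphere by midpoint subdivision of an icosahedron.

    Level ``L`` gives ``n_v = 10 * 4**L + 2`` vertices; every vertex lies at
    distance ``radius`` from the origin with outward triangle orientation.
    """
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    verts, tris = _icosahedron()
    verts = list(map(np.asarray, verts))
    for _ in range(subdivision_level):
        midpoint: dict[tuple[int, int], int] = {}
        new_tris = []

        def mid(i, j):
            key = (i, j) if i < j else (j, i)
            if key not in midpoint:
                m = verts[i] + verts[j]
                m /= np.linalg.norm(m)
                midpoint[key] = len(verts)
                verts.append(m)
            return midpoint[key]

        for a, b, c in tris:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_tris += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        tris = np.asarray(new_tris, dtype=np.int64)
    v = np.asarray(verts) * radius
    return TriMesh(v, tris)


def subdivide(mesh: TriMesh) -> TriMesh:
    """Midpoint (1-to-4) subdivision without reprojection.

    The refined mesh represents the same polyhedral surface at four times
    the triangle count; used to re-measure a coarsely annealed shape at
    higher resolution (where sharp features are priced correctly) after a
    short relaxation.
    """
    verts = list(mesh.vertices)
    midpoint: dict[tuple[int, int], int] = {}

    def mid(i, j):
        key = (i, j) if i < j else (j, i)
        if key not in midpoint:
            midpoint[key] = len(verts)
            verts.append(0.5 * (mesh.vertices[i] + mesh.vertices[j]))
        return midpoint[key]

    new_tris = []
    for a, b, c in mesh.triangles:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_tris += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
    return TriMesh(np.asarray(verts), np.asarray(new_tris, dtype=np.int64))


# ---------------------------------------------------------------------------
# edge flip (reference implementation; the MC engine has a fast in-place one)
# ---------------------------------------------------------------------------

def flip_edge(
    mesh: TriMesh,
    edge: int,
    l_min: float | None = None,
    l_max: float | None = None,
) -> TriMesh | None:
    """Flip an interior edge to the opposite diagonal of its quadrilateral.

    Returns the flipped mesh, or ``None`` (a *rejection*, not an error) if
    the flip is not admissible: the opposite diagonal already exists, an
    endpoint of the old edge would drop below degree 3, the new edge length
    falls outside the tether interval, or the quadrilateral is non-convex in
    the flip sense (either new triangle would invert its orientation).
    """
    a, b = mesh.edges[edge]
    t1, t2 = mesh.edge_tri[edge]
    tri1, tri2 = mesh.triangles[t1], mesh.triangles[t2]
    c = int(tri1[~np.isin(tri1, (a, b))][0])
    d = int(tri2[~np.isin(tri2, (a, b))][0])
    if c == d:
        return None
    # opposite diagonal must not already exist
    ev = mesh.edges
    if np.any(((ev[:, 0] == min(c, d)) & (ev[:, 1] == max(c, d)))
              | ((ev[:, 0] == max(c, d)) & (ev[:, 1] == min(c, d)))):
        return None
    deg = mesh.vertex_degrees()
    if deg[a] <= 3 or deg[b] <= 3:
        return None
    pos = mesh.vertices
    new_len = np.linalg.norm(pos[c] - pos[d])
    if l_min is not None and not (l_min <= new_len <= l_max):
        return None
    # orient a->b as in t1 so that new triangles keep outward orientation
    ia = list(tri1).index(a)
    if tri1[(ia + 1) % 3] != b:
        a, b = b, a
    n_old = np.cross(pos[b] - pos[a], pos[c] - pos[a]) + np.cross(
        pos[a] - pos[b], pos[d] - pos[b]
    )
    n1 = np.cross(pos[a] - pos[c], pos[d] - pos[c])  # triangle (c, a, d)
    n2 = np.cross(pos[b] - pos[d], pos[c] - pos[d])  # triangle (d, b, c)
    eps = 1e-12
    if (np.linalg.norm(n1) < eps or np.linalg.norm(n2) < eps
            or np.dot(n1, n_old) <= 0 or np.dot(n2, n_old) <= 0):
        return None  # non-convex quadrilateral: flip would invert orientation
    tris = mesh.triangles.copy()
    tris[t1] = (c, a, d)
    tris[t2] = (d, b, c)
    return TriMesh(mesh.vertices.copy(), tris)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_mesh(
    mesh: TriMesh,
    l_min: float | None = None,
    l_max: float | None = None,
    area_tol: float = 1e-12,
) -> list[str]:
    """Report violated invariants of a closed genus-0 tethered triangulation.

    Returns an empty list iff the mesh is a closed orientable 2-manifold of
    genus 0 with no degenerate triangles and (when bounds are given) all edge
    lengths inside the tether interval.
    """
    report: list[str] = []
    try:
        edges, edge_tri, tri_edge = build_edges(mesh.triangles, mesh.n_vertices)
    except MeshTopologyError as exc:
        return [f"manifold/orientation violation: {exc}"]
    chi = mesh.n_vertices - len(edges) + mesh.n_triangles
    if chi != 2:
        report.append(f"Euler characteristic {chi} != 2 (genus != 0)")
    areas = mesh.triangle_areas()
    n_bad = int((areas <= area_tol).sum())
    if n_bad:
        report.append(f"{n_bad} degenerate triangle(s) with area <= {area_tol}")
    if l_min is not None:
        ln = mesh.edge_lengths()
        n_out = int(((ln < l_min) | (ln > l_max)).sum())
        if n_out:
            report.append(
                f"{n_out} edge(s) outside tether interval [{l_min:.4g}, {l_max:.4g}]"
            )
    if (mesh.vertex_degrees() < 3).any():
        report.append("vertex with degree < 3")
    return report


# ---------------------------------------------------------------------------
# I/O: PLY / OFF via trimesh, legacy ASCII VTK polydata by hand
# ---------------------------------------------------------------------------

def save_mesh(mesh: TriMesh, path: str) -> None:
    """Write PLY/OFF (via the ``trimesh`` package) or legacy ASCII VTK
    polydata, chosen by file extension.  Vertex order is preserved."""
    path = str(path)
    if path.endswith(".vtk"):
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nphagosim membrane mesh\nASCII\n")
            fh.write("DATASET POLYDATA\n")
            fh.write(f"POINTS {mesh.n_vertices} double\n")
            for p in mesh.vertices:
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            fh.write(f"POLYGONS {mesh.n_triangles} {4 * mesh.n_triangles}\n")
            for t in mesh.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        return
    import trimesh as _tm

    tm = _tm.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    tm.export(path)


def load_mesh(path: str) -> TriMesh:
    """Read a mesh written by :func:`save_mesh` (PLY, OFF or legacy VTK)."""
    path = str(path)
    if path.endswith(".vtk"):
        with open(path) as fh:
            lines = fh.read().split("\n")
        ip = next(i for i, l in enumerate(lines) if l.startswith("POINTS"))
        nv = int(lines[ip].split()[1])
        verts = np.array(
            [list(map(float, lines[ip + 1 + k].split())) for k in range(nv)]
        )
        ig = next(i for i, l in enumerate(lines) if l.startswith("POLYGONS"))
        nt = int(lines[ig].split()[1])
        tris = np.array(
            [list(map(int, lines[ig + 1 + k].split()))[1:] for k in range(nt)]
        )
        return TriMesh(verts, tris)
    import trimesh as _tm

    tm = _tm.load(path, process=False)
    return TriMesh(np.asarray(tm.vertices, dtype=np.float64),
                   np.asarray(tm.faces, dtype=np.int64))
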