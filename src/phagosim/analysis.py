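"""Shape classification, branch-barrier extraction and run success rates.

The classifier is a deterministic rule on rigid-motion- and scale-invariant
descriptors computed from the mesh alone: reduced volume, area difference,
gyration-tensor eigenvalues, the depth of the deepest inward pocket
(fraction of the largest extent) and the number of radial arms.  Pocket
depth is measured by casting a ray along each principal axis from far
outside toward the center of mass: the distance by which the first surface
hit recedes behind the convex support plane of that direction is the depth
of the invagination (zero for convex bodies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energetics import shape_state
from .mesh import TriMesh

__all__ = [
    "ShapeLabel",
    "classify_shape",
    "extract_barriers",
    "BranchExtrema",
    "success_rate",
]

LABELS = ("sphere", "tube", "disk", "paddle", "bowl", "cup", "starfish",
          "other")

# pocket-depth thresholds (fraction of the largest extent); calibrated on
# the axisymmetric reference shapes of the branch families
POCKET_BOWL = 0.2
POCKET_CUP = 0.5


@dataclass
class ShapeLabel:
    label: str
    reduced_volume: float
    area_difference: float
    gyration_eigenvalues: tuple[float, float, float]
    asphericity: float
    pocket_depth: float
    n_arms: int
    descriptors: dict = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def _gyration(vertices: np.ndarray):
    p = vertices - vertices.mean(axis=0)
    cov = p.T @ p / len(p)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


def _ray_hits(mesh: TriMesh, origin: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Parameters t of all intersections of the line origin + t*d with the
    mesh (Moller-Trumbore, vectorized over triangles)."""
    tri = mesh.triangles
    a = mesh.vertices[tri[:, 0]]
    e1 = mesh.vertices[tri[:, 1]] - a
    e2 = mesh.vertices[tri[:, 2]] - a
    p = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > 1e-12
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    s = origin - a
    u = np.einsum("ij,ij->i", s, p) * inv
    q = np.cross(s, e1)
    v = q @ d * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
    return t[hit]


def _pocket_depth(mesh: TriMesh, axes: np.ndarray, extent: float) -> float:
    """Deepest first-hit recession behind the support plane, over the six
    principal directions, as a fraction of the largest extent."""
    com = mesh.vertices.mean(axis=0)
    depth = 0.0
    for k in range(3):
        for sgn in (1.0, -1.0):
            d = sgn * axes[:, k]
            h = float(np.max(mesh.vertices @ d))  # support plane offset
            t = _ray_hits(mesh, com, d)
            if len(t) == 0:
                continue
            first = float(np.max(t))  # first hit coming inward from +d side
            depth = max(depth, h - (com @ d + first))
    return depth / extent


def _arm_count(vertices: np.ndarray, axes: np.ndarray, w: np.ndarray) -> int:
    """Count radial arms in the plane of the two largest gyration axes."""
    com = vertices.mean(axis=0)
    p = (vertices - com) @ axes[:, :2]
    r = np.hypot(p[:, 0], p[:, 1])
    theta = np.arctan2(p[:, 1], p[:, 0])
    nbin = 72
    idx = ((theta + np.pi) / (2 * np.pi) * nbin).astype(int) % nbin
    prof = np.zeros(nbin)
    np.maximum.at(prof, idx, r)
    if prof.max() <= 0:
        return 0
    # smooth and count peaks rising above 60% of max with 40% prominence
    kern = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    kern /= kern.sum()
    sm = np.convolve(np.r_[prof[-2:], prof, prof[:2]], kern, "same")[2:-2]
    hi, lo = sm.max(), sm.min()
    if hi - lo < 0.25 * hi:
        return 0
    level = lo + 0.6 * (hi - lo)
    above = sm > level
    # count circular runs of "above"
    runs = int(np.sum(above & ~np.roll(above, 1)))
    return runs


def classify_shape(mesh: TriMesh, kappa: float = 20.0) -> ShapeLabel:
    """Deterministic shape label from mesh descriptors alone.

    Rules, in order: sphere (v ~ 1); cup (pocket depth > 0.5 of the largest
    extent); bowl (pocket 0.2-0.5); starfish (>= 3 radial arms); tube /
    paddle (one dominant gyration eigenvalue; paddle when the cross-section
    flattens somewhere along the long axis); disk (two dominant
    eigenvalues); otherwise "other".
    """
    st = shape_state(mesh, kappa)
    w, axes = _gyration(mesh.vertices)
    tr = float(np.sum(w))
    asph = float((w[0] - 0.5 * (w[1] + w[2])) / tr)
    com = mesh.vertices.mean(axis=0)
    extent = 0.0
    for k in range(3):
        proj = mesh.vertices @ axes[:, k]
        extent = max(extent, float(proj.max() - proj.min()))
    pocket = _pocket_depth(mesh, axes, extent)
    arms = _arm_count(mesh.vertices, axes, w)
    desc = {"eig_ratio_2": float(w[1] / w[0]),
            "eig_ratio_3": float(w[2] / w[0]),
            "extent": extent}

    label = "other"
    r2, r3 = w[1] / w[0], w[2] / w[0]
    if st.reduced_volume > 0.98 and pocket < POCKET_BOWL:
        label = "sphere"
    elif pocket > POCKET_CUP:
        label = "cup"
    elif pocket > POCKET_BOWL:
        label = "bowl"
    elif arms >= 3:
        label = "starfish"
    elif r2 < 0.45:
        # elongated: tube if the cross-section stays round, paddle if it
        # flattens somewhere along the long axis
        p = (mesh.vertices - com) @ axes
        order = np.argsort(p[:, 0])
        ps = p[order]
        n_slab = 6
        bounds = np.linspace(ps[0, 0], ps[-1, 0], n_slab + 1)
        aspects = []
        for s in range(n_slab):
            sel = (ps[:, 0] >= bounds[s]) & (ps[:, 0] <= bounds[s + 1])
            if np.sum(sel) < 12:
                continue
            q = ps[sel][:, 1:]
            ww = np.linalg.eigvalsh(np.cov(q.T))
            aspects.append(np.sqrt(max(ww[0], 1e-30) / max(ww[1], 1e-30)))
        desc["section_aspects"] = aspects
        if aspects and min(aspects) < 0.35 and max(aspects) > 0.6:
            label = "paddle"
        else:
            label = "tube"
    elif r2 > 0.55 and r3 < 0.3:
        label = "disk"
    return ShapeLabel(label=label, reduced_volume=st.reduced_volume,
                      area_difference=st.area_difference,
                      gyration_eigenvalues=(float(w[0]), float(w[1]),
                                            float(w[2])),
                      asphericity=asph, pocket_depth=float(pocket),
                      n_arms=arms, descriptors=desc)


# ---------------------------------------------------------------------------
# branch extrema / barriers
# ---------------------------------------------------------------------------

@dataclass
class BranchExtrema:
    """Stationary points of a (da, E) branch, scanned from large da down."""
    minima: list        # [(da, E), ...] ordered by decreasing da
    maxima: list
    H1: float | None    # E(first max) - E(first min); None if absent
    H2: float | None    # E(second max) - E(second min); None if absent

    @property
    def barrier_absent(self) -> bool:
        return self.H1 is None


def extract_barriers(da, energy) -> BranchExtrema:
    """Locate local extrema of a branch table and the barriers H1, H2.

    The table is sorted by decreasing ``da`` (the branch is traversed from
    the fused/tube side toward the cup side); interior local minima and
    maxima alternate.  H1 is the climb from the first minimum (tube) over
    the first maximum; H2 the climb from the second minimum (disk) over the
    second maximum (bowl top).  Monotone profiles report no barrier.
    """
    da = np.asarray(da, dtype=float)
    energy = np.asarray(energy, dtype=float)
    if len(da) != len(energy) or len(da) < 3:
        raise ValueError("need matching (da, E) arrays with >= 3 points")
    order = np.argsort(da)[::-1]
    x, e = da[order], energy[order]
    minima, maxima = [], []
    for i in range(1, len(x) - 1):
        if e[i] < e[i - 1] and e[i] <= e[i + 1]:
            minima.append((float(x[i]), float(e[i])))
        elif e[i] > e[i - 1] and e[i] >= e[i + 1]:
            maxima.append((float(x[i]), float(e[i])))
    # endpoints count as minima when the profile rises away from them
    if e[1] > e[0]:
        minima.insert(0, (float(x[0]), float(e[0])))
    if e[-2] > e[-1]:
        minima.append((float(x[-1]), float(e[-1])))
    minima.sort(key=lambda t: -t[0])
    maxima.sort(key=lambda t: -t[0])
    H1 = H2 = None
    if len(minima) >= 1 and len(maxima) >= 1 and maxima[0][0] < minima[0][0]:
        H1 = maxima[0][1] - minima[0][1]
    if len(minima) >= 2 and len(maxima) >= 2 and maxima[1][0] < minima[1][0]:
        H2 = maxima[1][1] - minima[1][1]
    return BranchExtrema(minima=minima, maxima=maxima, H1=H1, H2=H2)


def success_rate(labels) -> tuple[float, str]:
    """Fraction of runs whose final shape is a cup; success iff >= 0.75."""
    labels = list(labels)
    if not labels:
        raise ValueError("need at least one run")
    names = [lab.label if isinstance(lab, ShapeLabel) else str(lab)
             for lab in labels]
    frac = sum(1 for s in names if s == "cup") / len(names)
    return frac, ("successful" if frac >= 0.75 else "not successful")
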