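import numpy as np
import pytest

from phagosim.mesh import (MAX_DEGREE, MeshTopologyError, TriMesh,
                           build_icosphere, flip_edge, load_mesh, save_mesh,
                           subdivide, tether_bounds, tether_length,
                           validate_mesh)


def euler_characteristic(mesh):
    return mesh.n_vertices - mesh.n_edges + mesh.n_triangles


@pytest.mark.parametrize("level,nv", [(0, 12), (1, 42), (2, 162), (3, 642),
                                      (4, 2562)])
def test_icosphere_counts(level, nv):
    m = build_icosphere(level)
    assert m.n_vertices == nv
    assert m.n_triangles == 20 * 4 ** level
    assert m.n_edges == 30 * 4 ** level
    assert euler_characteristic(m) == 2


def test_icosphere_radius():
    m = build_icosphere(3, radius=2.5)
    r = np.linalg.norm(m.vertices, axis=1)
    assert np.allclose(r, 2.5, atol=1e-12)


def test_validate_detects_duplicate_face():
    m = build_icosphere(1)
    bad = np.vstack([m.triangles, m.triangles[:1]])
    with pytest.raises(MeshTopologyError):
        TriMesh(m.vertices, bad)


def test_validate_detects_orientation_flip():
    m = build_icosphere(1)
    bad = m.triangles.copy()
    bad[0] = bad[0][[0, 2, 1]]
    with pytest.raises(MeshTopologyError):
        TriMesh(m.vertices, bad)


def test_subdivide_counts():
    m = build_icosphere(2)
    s = subdivide(m)
    assert s.n_triangles == 4 * m.n_triangles
    assert s.n_vertices == m.n_vertices + m.n_edges
    assert euler_characteristic(s) == 2
    validate_mesh(s)


def test_tether_bounds():
    l = tether_length(np.sqrt(3.0) / 4.0)
    assert l == pytest.approx(1.0)
    lo, hi = tether_bounds(l)
    assert lo == pytest.approx(3.0 ** -0.25)
    assert hi == pytest.approx(3.0 ** 0.25)
    assert hi / lo >= np.sqrt(2.0)  # flip-safe interval


def test_flip_edge_preserves_topology():
    from phagosim.engine import reference_icosphere

    m = reference_icosphere(2)
    lo, hi = tether_bounds(m, ratio=3.0)  # wide interval admits diagonals
    flipped = 0
    e = 0
    while flipped < 25 and e < m.n_edges:
        out = flip_edge(m, e, lo, hi)
        if out is not None:
            m = out
            flipped += 1
            validate_mesh(m)
            assert euler_characteristic(m) == 2
            assert m.vertex_degrees().max() <= MAX_DEGREE
        e += 1
    assert flipped >= 10


@pytest.mark.parametrize("ext", ["ply", "off", "vtk"])
def test_save_load_roundtrip(tmp_path, ext):
    m = build_icosphere(1, radius=1.7)
    path = tmp_path / f"mesh.{ext}"
    save_mesh(m, str(path))
    back = load_mesh(str(path))
    assert np.allclose(back.vertices, m.vertices, atol=1e-6)
    assert np.array_equal(np.sort(back.triangles, axis=None),
                          np.sort(m.triangles, axis=None))
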