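import numpy as np
import pytest

from phagosim.proteins import (DEFAULT_ARC_RADIUS, AdhesionParams,
                               DimerChain, U_to_u, adhesion_energy,
                               bead_surface_distance, build_s_dimer,
                               build_straight_chain,
                               chain_internal_coordinates, internal_energy,
                               s_curve_points, u_to_U)


def test_s_dimer_reference_energy_zero():
    c = build_s_dimer()
    assert c.n_beads == 16
    assert internal_energy(c) == pytest.approx(0.0, abs=1e-18)


def test_s_dimer_geometry():
    pts = s_curve_points(DEFAULT_ARC_RADIUS, 15.0, 16)
    bonds, _, _ = chain_internal_coordinates(pts)
    # unit chords by construction of the default arc radius (the chord
    # across the tilted junction is marginally longer)
    assert np.allclose(bonds, 1.0, atol=2e-3)
    # S shape: two oppositely-curving halves -> end-to-end shorter than
    # a straight 15-bond chain but much longer than a single crescent
    ee = np.linalg.norm(pts[-1] - pts[0])
    assert 8.0 < ee < 15.0


def test_internal_energy_quadratic_in_bond_stretch():
    c = build_s_dimer()
    p = c.positions.copy()
    d = p[1] - p[0]
    eps = 1e-3
    c.positions[0] = p[0] - eps * d / np.linalg.norm(d)
    e = internal_energy(c)
    assert e == pytest.approx(0.5 * c.K_bond * eps ** 2, rel=1e-3)


def test_straight_chain_reference():
    c = build_straight_chain()
    assert internal_energy(c) == pytest.approx(0.0, abs=1e-18)
    assert c.K_dih == 0.0
    bonds, thetas, _ = chain_internal_coordinates(c.positions)
    assert np.allclose(thetas, np.pi)


def test_adhesion_square_well(icosphere3):
    from phagosim.proteins import HardCoreOverlap

    mesh = icosphere3
    params = AdhesionParams(U=2.0, d0=0.5, d1=1.0)
    r = np.linalg.norm(mesh.vertices[0])
    n = mesh.vertices[0] / r
    c = build_s_dimer()
    # all beads stacked at controlled height above one vertex
    c.positions = np.tile(mesh.vertices[0] + 0.75 * n, (16, 1))
    e, bound = adhesion_energy([c], mesh, params)
    assert e < 0 and len(bound) == 16
    # well contributes -U * (closest triangle area) per bound bead
    areas = mesh.triangle_areas()
    expect = -params.U * sum(areas[t] for _, _, t in bound)
    assert e == pytest.approx(expect, rel=1e-12)
    c.positions = np.tile(mesh.vertices[0] + 1.5 * n, (16, 1))
    e, bound = adhesion_energy([c], mesh, params)
    assert e == 0.0 and not bound
    c.positions = np.tile(mesh.vertices[0] + 0.3 * n, (16, 1))
    with pytest.raises(HardCoreOverlap):
        adhesion_energy([c], mesh, params)


def test_bead_surface_distance_sign(icosphere3):
    mesh = icosphere3
    r = np.linalg.norm(mesh.vertices, axis=1).mean()
    outside = np.array([0.0, 0.0, r + 2.0])
    inside = np.array([0.0, 0.0, r - 2.0])
    d_out, _, side_out = bead_surface_distance(outside, mesh)
    d_in, _, side_in = bead_surface_distance(inside, mesh)
    assert d_out > 0 and d_in > 0
    assert side_out != side_in


def test_u_conversion_roundtrip():
    mean_area = np.sqrt(3.0) / 4.0
    U = u_to_U(0.12, 10.0, mean_area)
    assert U_to_u(U, 10.0, mean_area) == pytest.approx(0.12, rel=1e-12)
    # u = U * 16 Abar / (8 pi kappa)
    assert U * 16 * mean_area / (8 * np.pi * 10.0) == pytest.approx(0.12)


def test_excluded_volume_check():
    from phagosim.engine import reference_icosphere
    from phagosim.proteins import excluded_volume_check

    mesh = reference_icosphere(2)
    params = AdhesionParams(U=1.0, d0=0.5, d1=1.0)
    r = np.linalg.norm(mesh.vertices[0])
    n = mesh.vertices[0] / r
    # bead inside the hard core -> reject
    c = build_s_dimer()
    c.positions = np.tile(mesh.vertices[0] + 0.1 * n, (16, 1))
    assert not excluded_volume_check([c], mesh, params)
    # two overlapping dimers -> reject; far apart -> accept
    a = build_s_dimer()
    b = build_s_dimer()
    a.positions = a.positions + (r + 2.0) * n
    b.positions = a.positions + 0.2
    assert not excluded_volume_check([a, b], mesh, params)
    b.positions = a.positions + np.array([20.0, 0.0, 0.0])
    assert excluded_volume_check([a, b], mesh, params)
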