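import numpy as np
import pytest

from phagosim.energetics import (EnergyModel, area_difference,
                                 bending_energy, fused_reduced_volume,
                                 reduced_volume, shape_state, signed_volume,
                                 total_energy)
from phagosim.mesh import build_icosphere


def sphere_errors(level):
    m = build_icosphere(level, radius=3.0)
    st = shape_state(m, kappa=1.0)
    return (abs(st.bending_energy / (8 * np.pi) - 1.0),
            abs(st.area_difference - 1.0),
            abs(st.reduced_volume - 1.0))


def test_sphere_limits_converge():
    """E_b/(8 pi kappa), da and v all -> 1 on icospheres, with error
    decreasing under subdivision."""
    e3 = sphere_errors(3)
    e4 = sphere_errors(4)
    for a, b in zip(e3, e4):
        assert a < 0.02
        assert b < a
    # scale invariance of the reduced quantities
    small = shape_state(build_icosphere(3, radius=0.1))
    big = shape_state(build_icosphere(3, radius=30.0))
    assert small.reduced_volume == pytest.approx(big.reduced_volume, rel=1e-12)
    assert small.area_difference == pytest.approx(big.area_difference,
                                                  rel=1e-10)


def test_signed_volume_orientation():
    m = build_icosphere(2, radius=2.0)
    v = signed_volume(m)
    assert v == pytest.approx(4.0 / 3.0 * np.pi * 8.0, rel=5e-2)
    assert v > 0


def test_reduced_volume_sphere_exact():
    A = 4 * np.pi
    V = 4 * np.pi / 3
    assert reduced_volume(A, V) == pytest.approx(1.0, rel=1e-14)


def test_fused_reduced_volume():
    assert fused_reduced_volume(2) == pytest.approx(1 / np.sqrt(2))
    assert fused_reduced_volume(3) == pytest.approx(0.577, abs=5e-4)
    assert fused_reduced_volume(4) == pytest.approx(0.5)


def test_bending_energy_scale_invariant():
    m1 = build_icosphere(2, radius=1.0)
    m2 = build_icosphere(2, radius=17.0)
    assert bending_energy(m1, 20.0) == pytest.approx(
        bending_energy(m2, 20.0), rel=1e-10)


def test_capped_cylinder_reference():
    """A structured capped-cylinder mesh approaches the analytic Helfrich
    energy of a cylinder of length L plus a spherical cap pair."""
    from phagosim.initial_conditions import (_resample_arclength,
                                             revolution_mesh)

    R, L = 4.0, 20.0
    # profile: south cap, straight wall, north cap
    th = np.linspace(np.pi, np.pi / 2, 60)
    z1, r1 = R * np.cos(th) - L / 2, R * np.sin(th)
    zw = np.linspace(-L / 2, L / 2, 120)[1:-1]
    th2 = np.linspace(np.pi / 2, 0, 60)
    z2, r2 = R * np.cos(th2) + L / 2, R * np.sin(th2)
    z = np.concatenate([z1, zw, z2])
    r = np.concatenate([r1, np.full(len(zw), R), r2])
    z, r = _resample_arclength(z, r, np.sqrt(3.0) / 2.0)
    m = revolution_mesh(z, r, edge_length=1.0)
    # analytic: caps 8 pi kappa/(8 pi kappa)=1... cylinder part
    # E_cyl = kappa/2 * (1/R)^2 * 2 pi R L = pi kappa L / R
    expect = 1.0 + (np.pi * L / R) / (8 * np.pi)
    got = bending_energy(m, 1.0) / (8 * np.pi)
    assert got == pytest.approx(expect, rel=0.03)


def test_constraint_energy_quadratic():
    m = build_icosphere(2)
    model = EnergyModel(kappa=20.0, K_A=1e4, K_V=0.0, K_da=0.0,
                        A_ref=2.0 * m.area())
    terms = total_energy(m, [], model)
    # A/A_ref = 0.5 -> K_A * 0.25
    assert terms["E_area"] == pytest.approx(1e4 * 0.25, rel=1e-10)
    assert terms["E_total"] == pytest.approx(
        terms["E_b"] + terms["E_area"], rel=1e-12)


def test_umbrella_bias_term():
    m = build_icosphere(2)
    st = shape_state(m)
    model = EnergyModel(kappa=20.0, K_A=0, K_V=0, K_da=0.0, k_umb=2e5,
                        da_umb=st.area_difference + 0.01)
    terms = total_energy(m, [], model)
    assert terms["E_umb"] == pytest.approx(0.5 * 2e5 * 1e-4, rel=1e-6)
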