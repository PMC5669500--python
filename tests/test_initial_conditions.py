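import numpy as np
import pytest

from phagosim.energetics import (fused_reduced_volume, reduced_volume,
                                 shape_state)
from phagosim.initial_conditions import (SCENARIOS, build_scenario,
                                         fuse_vesicle_to_shape,
                                         fused_sphere_geometry,
                                         fused_spheres_mesh, oblate_mesh,
                                         place_dimers, prolate_mesh,
                                         reference_values, revolution_mesh,
                                         stomatocyte_mesh,
                                         surface_distance_point)
from phagosim.mesh import validate_mesh


@pytest.mark.parametrize("n", [1, 2, 3, 4])
def test_fused_spheres_valid_and_reduced_volume(n):
    mesh = fused_spheres_mesh(n)
    assert validate_mesh(mesh) == []
    st = shape_state(mesh)
    # narrow necks: v approaches 1/sqrt(n) (discrete necks bias it slightly)
    assert st.reduced_volume == pytest.approx(fused_reduced_volume(n),
                                              abs=0.02)
    assert fused_reduced_volume(n) == pytest.approx(1.0 / np.sqrt(n))


def test_fused_spheres_area_scaling():
    # target_area sets the analytic union area; the faceted mesh sits a
    # couple of percent under it
    mesh = fused_spheres_mesh(3, target_area=600.0)
    assert mesh.area() == pytest.approx(600.0, rel=0.03)
    mesh2 = fused_spheres_mesh(3, target_area=2400.0)
    assert mesh2.area() / mesh.area() == pytest.approx(4.0, rel=0.02)


def test_reference_values_drive_target():
    mesh = fused_spheres_mesh(3)
    A_ref, V_ref = reference_values(mesh, 3)
    assert A_ref == pytest.approx(mesh.area())
    assert reduced_volume(A_ref, V_ref) == pytest.approx(1.0 / np.sqrt(3.0))


def test_surface_distance_point():
    R, centers, necks = fused_sphere_geometry(2)
    p = np.array([0.0, 0.0, centers[0] - R - 0.7])
    assert surface_distance_point(p, 2, R, centers) == pytest.approx(0.7,
                                                                     abs=1e-9)
    inside = np.array([0.0, 0.0, centers[0]])
    assert surface_distance_point(inside, 2, R, centers) < 0


def test_revolution_mesh_sphere():
    th = np.linspace(np.pi, 0.0, 60)
    r = 5.0
    mesh = revolution_mesh(r * np.cos(th), r * np.sin(th))
    assert validate_mesh(mesh) == []
    st = shape_state(mesh)
    assert st.reduced_volume > 0.98
    assert mesh.area() == pytest.approx(4 * np.pi * r * r, rel=0.02)


@pytest.mark.parametrize("build", [lambda: oblate_mesh(0.35),
                                   lambda: prolate_mesh(3.0),
                                   lambda: stomatocyte_mesh()])
def test_revolution_anchors_are_valid(build):
    mesh = build()
    assert validate_mesh(mesh) == []
    assert mesh.euler_characteristic == 2
    assert shape_state(mesh).volume > 0


def test_place_dimers_counts_and_admissibility():
    from phagosim.proteins import AdhesionParams, excluded_volume_check

    mesh = fused_spheres_mesh(3)
    chains = place_dimers(mesh, n_spheres=3, n_dimers=6)
    assert len(chains) == 6
    assert all(c.n_beads == 16 for c in chains)
    params = AdhesionParams(U=1.0, d0=0.5, d1=1.0)
    assert excluded_volume_check(chains, mesh, params)
    # junction groups straddle the two necks: mean bead z separates
    R, centers, necks = fused_sphere_geometry(3)
    z_mean = np.array([c.positions[:, 2].mean() for c in chains])
    assert (z_mean[:3] < centers[1]).all()
    assert (z_mean[3:] > centers[1]).all()


def test_place_dimers_straight_chains():
    mesh = fused_spheres_mesh(3)
    chains = place_dimers(mesh, n_spheres=3, n_dimers=6, shape="straight")
    assert len(chains) == 6
    # straight strands run parallel to the fusion (z) axis
    for c in chains:
        d = c.positions[-1] - c.positions[0]
        assert abs(d[2]) / np.linalg.norm(d) > 0.95


def test_place_dimers_rejects_odd_count():
    mesh = fused_spheres_mesh(3)
    with pytest.raises(ValueError):
        place_dimers(mesh, n_spheres=3, n_dimers=5)
    with pytest.raises(ValueError):
        place_dimers(fused_spheres_mesh(1), n_spheres=1)


def test_fuse_vesicle_to_shape():
    host = fused_spheres_mesh(2)
    sphere = fused_spheres_mesh(1, target_area=host.area() / 2)
    top = host.vertices[np.argmax(host.vertices[:, 2])]
    out = fuse_vesicle_to_shape(host, sphere, top)
    assert validate_mesh(out) == []
    assert out.euler_characteristic == 2
    assert shape_state(out).volume > shape_state(host).volume
    # overlapping attachment rejected
    inside = host.vertices.mean(axis=0)
    with pytest.raises(ValueError):
        fuse_vesicle_to_shape(host, fused_spheres_mesh(1), inside)


def test_build_scenario_presets():
    mesh, chains, (A_ref, V_ref) = build_scenario("fused3_s6")
    assert len(chains) == 6
    assert A_ref == pytest.approx(mesh.area())
    assert reduced_volume(A_ref, V_ref) == pytest.approx(1 / np.sqrt(3))
    mesh1, chains1, _ = build_scenario("free_vesicle")
    assert chains1 == []
    with pytest.raises(ValueError):
        build_scenario("nope")
    assert set(SCENARIOS) == {"free_vesicle", "fused3_s6", "fused4_s6",
                              "fused3_straight6"}
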