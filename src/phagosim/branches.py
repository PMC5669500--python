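"""Shape-branch construction and barrier measurements.

The branch of minimum-energy shapes vs. area difference ``da`` at fixed
reduced volume ``v`` has (for deflated/fused vesicles) three families —
tube, disk and cup — whose local minima and the maxima between them define
the barriers H1 (tube -> disk) and H2 (disk -> cup), in units of the sphere
bending energy 8*pi*kappa.

At desk scale the barriers (a few percent of 8*pi*kappa, i.e. tens of k_B T
on shapes with bending energies of ~1000 k_B T) cannot be resolved by plain
simulated annealing: frozen thermal roughness contributes more energy than
the barrier height.  The protocol used here therefore separates *basin
finding* from *energy measurement*:

1.  Anchors.  Each family is entered from a structured starting mesh: the
    tube family from the fused-spheres initial condition (warm MC opens the
    necks), the disk family from an oblate spheroid.
2.  Warm exploration.  Short Metropolis runs at T = 1 k_B T with the
    area-difference constraint ramped to the target let the shape cross
    into the correct basin (several independent seeds near barrier tops).
3.  Deterministic quench.  Each candidate is relaxed by L-BFGS on the
    analytic gradient alternated with downhill edge flips
    (:func:`phagosim.minimize.quench_shape`), removing SA noise.
4.  Refined re-measurement.  The quenched mesh is midpoint-subdivided
    (4x triangles) and re-quenched.  This step re-prices sharp rims that the
    coarse mesh under-resolves; without it the coarse quench admits spurious
    flattened "ribbon" states that undercut the physical branch.
5.  The family energy at each ``da`` is the minimum over seeds of the
    refined quench energy; barrier heights are differences of these minima
    (metastable minimum vs. the maximum of the refined continuation between
    the families).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .energetics import EnergyModel, shape_state
from .engine import MembraneState, _child_seeds
from .initial_conditions import (fused_spheres_mesh, oblate_mesh,
                                 reference_values)
from .mesh import TriMesh, subdivide
from .minimize import quench_shape

__all__ = [
    "BarrierResult",
    "branch_model",
    "tube_state",
    "disk_state",
    "refined_energy",
    "family_energy",
    "branch_candidate",
    "continuation_profile",
    "tube_disk_barrier",
    "disk_cup_barrier",
]


def branch_model(A_ref: float, n_spheres: int, kappa: float = 20.0,
                 da_0: float = 1.0) -> EnergyModel:
    """Stiffly constrained free-vesicle model at v = 1/sqrt(n_spheres)."""
    V_ref = A_ref ** 1.5 / (6.0 * np.sqrt(np.pi) * np.sqrt(float(n_spheres)))
    return EnergyModel(kappa=kappa, K_A=1e6, K_V=1e6, K_da=5e6,
                       da_0=da_0).with_refs(A_ref, V_ref)


@dataclass
class BarrierResult:
    """Outcome of a barrier measurement (energies in 8*pi*kappa units)."""
    height: float                    # barrier height H
    E_min: float                     # metastable minimum energy
    E_top: float                     # barrier-top energy
    da_min: float                    # constraint target at the minimum
    da_top: float                    # constraint target at the top
    profile: dict = field(default_factory=dict)   # da -> refined energy
    n_samples: int = 0               # number of quenched candidates used


def refined_energy(mesh: TriMesh, model: EnergyModel,
                   rounds: int = 3, maxiter: int = 800):
    """Subdivide a quenched mesh and re-quench; return (mesh, E/8*pi*kappa).

    The refined energy is the measurement used for all branch points: it is
    deterministic and re-prices coarse-mesh rim artifacts.
    """
    mq, info = quench_shape(subdivide(mesh), model, rounds=rounds,
                            maxiter=maxiter)
    return mq, info["E_b"] / (8.0 * np.pi * model.kappa)


def tube_state(n_spheres: int, da_tube: float, seed: int,
               kappa: float = 20.0, warm_sweeps: int = 600):
    """Tube-family anchor at v = 1/sqrt(n) and the given area difference.

    Builds the fused-spheres mesh, opens the necks with warm MC while
    ramping the area-difference target to ``da_tube``, then quenches.
    Returns ``(mesh_coarse, model, F_refined)`` where ``F_refined`` is the
    refined metastable tube energy in 8*pi*kappa units.
    """
    mesh = fused_spheres_mesh(n_spheres)
    A_ref, _ = reference_values(mesh, n_spheres)
    model = branch_model(A_ref, n_spheres, kappa=kappa, da_0=da_tube)
    st = MembraneState(mesh, model=model)
    s1, s2 = _child_seeds(seed, 2)
    wv = 0.08
    stats, _ = st.run(warm_sweeps, model, T=1.0,
                      da_0=(st.area_difference, da_tube), tune=True,
                      seed=s1, vertex_width=wv)
    st.run(warm_sweeps, model, T=1.0, da_0=da_tube, tune=True, seed=s2,
           vertex_width=stats["vertex_width"])
    mq, _ = quench_shape(st.mesh(), model, rounds=6, maxiter=2000)
    _, F = refined_energy(mq, model, rounds=4, maxiter=1500)
    return mq, model, F


def disk_state(n_spheres: int = 3, da_disk: float = 1.04,
               kappa: float = 20.0, aspect: float = 0.35):
    """Disk-family anchor at v = 1/sqrt(n) and the given area difference.

    Quenches an oblate spheroid under the constrained model (the volume
    constraint deflates it onto the disk branch).  Deterministic (no MC).
    Returns ``(mesh_coarse, model, B_refined)``.
    """
    mesh = oblate_mesh(aspect)
    model = branch_model(mesh.area(), n_spheres, kappa=kappa, da_0=da_disk)
    mq, _ = quench_shape(mesh, model, rounds=8, maxiter=1200)
    _, B = refined_energy(mq, model)
    return mq, model, B


def branch_candidate(anchor: TriMesh, model: EnergyModel, da_from: float,
                     da_to: float, seed: int, warm_sweeps: int = 800):
    """One warm-MC candidate at ``da_to``, refined-measured.

    Starts from a quenched anchor mesh, ramps the area-difference target at
    T = 1 over ``warm_sweeps`` sweeps, quenches at coarse resolution, then
    refines.  Returns the refined energy in 8*pi*kappa units.
    """
    mdl = replace(model, da_0=float(da_to))
    st = MembraneState(anchor.copy(), model=mdl)
    st.run(warm_sweeps, mdl, T=1.0, da_0=(da_from, da_to), tune=True,
           seed=seed, vertex_width=0.06)
    mq, _ = quench_shape(st.mesh(), mdl, rounds=4, maxiter=600)
    _, e = refined_energy(mq, mdl)
    return e


def continuation_profile(anchor: TriMesh, model: EnergyModel, da_grid,
                         rounds: int = 3, maxiter: int = 600):
    """Deterministic quench continuation along a grid of ``da`` targets.

    The coarse mesh is carried from point to point (each quench starts from
    the previous solution); the reported energy at every point comes from
    the refined re-measurement.  Returns ``{da: refined energy}``.
    """
    cur = anchor
    profile: dict[float, float] = {}
    for da in da_grid:
        mdl = replace(model, da_0=float(da))
        cur, _ = quench_shape(cur, mdl, rounds=rounds, maxiter=maxiter)
        _, profile[float(da)] = refined_energy(cur, mdl)
    return profile


def family_energy(family: str, v: float, kappa: float = 20.0,
                  rounds: int = 6, maxiter: int = 1200):
    """Refined quenched bending energy of a shape family at reduced volume v.

    Builds the family anchor (prolate spheroid for the tube family, oblate
    for the disk family, stomatocyte for the cup family), quenches it under
    stiff area/volume constraints targeting ``v`` with *no* area-difference
    constraint, and returns ``(mesh, E_b / 8 pi kappa)`` from the refined
    re-measurement.  Comparing families at the same ``v`` locates the
    ground-state transitions of the shape diagram.
    """
    from .initial_conditions import prolate_mesh, stomatocyte_mesh

    if family == "tube":
        mesh = prolate_mesh(3.0)
    elif family == "disk":
        mesh = oblate_mesh(0.35)
    elif family == "cup":
        # pick the invagination depth whose starting reduced volume is
        # closest to the target, so the quench stays inside the family
        cands = [stomatocyte_mesh(mouth_angle=0.35, dimple_radius=r)
                 for r in (0.5, 0.55, 0.6, 0.65)]
        mesh = min(cands,
                   key=lambda m: abs(shape_state(m).reduced_volume - v))
    else:
        raise ValueError(f"unknown family {family!r}")
    A_ref = mesh.area()
    V_ref = v * A_ref ** 1.5 / (6.0 * np.sqrt(np.pi))
    model = EnergyModel(kappa=kappa, K_A=1e6, K_V=1e6,
                        K_da=0.0).with_refs(A_ref, V_ref)
    mq, _ = quench_shape(mesh, model, rounds=rounds, maxiter=maxiter)
    return refined_energy(mq, model)


def tube_disk_barrier(n_spheres: int = 3, da_tube: float | None = None,
                      da_top: float | None = None, seed: int = 0,
                      n_seeds: int = 3, n_anchor_seeds: int = 2,
                      kappa: float = 20.0) -> BarrierResult:
    """Barrier H1 between the metastable tube and the disk family.

    ``F`` is the refined tube energy at ``da_tube``, minimized over
    ``n_anchor_seeds`` warm-MC anchors (warm exploration occasionally
    freezes a slightly rough tube; the branch energy is the best local
    minimum found).  The barrier top is the minimum over ``n_seeds``
    warm-MC candidates at ``da_top`` (the last area difference at which
    the shape still has to pass over the rim of the tube-to-disk
    transition).  Defaults target v = 0.577 (n = 3, with da 1.44 / 1.33)
    and v = 0.5 (n = 4, with da 1.61 / 1.45).
    """
    if da_tube is None:
        da_tube = {2: 1.28, 3: 1.44, 4: 1.61}.get(n_spheres, 1.44)
    if da_top is None:
        da_top = {2: 1.18, 3: 1.33, 4: 1.45}.get(n_spheres, 1.33)
    seeds = _child_seeds(seed, n_seeds + n_anchor_seeds)
    anchors = [tube_state(n_spheres, da_tube, s, kappa=kappa)
               for s in seeds[:n_anchor_seeds]]
    tube, model, F = min(anchors, key=lambda a: a[2])
    cand = [branch_candidate(tube, model, da_tube, da_top, s)
            for s in seeds[n_anchor_seeds:]]
    top = min(cand)
    return BarrierResult(height=top - F, E_min=F, E_top=top,
                         da_min=da_tube, da_top=da_top,
                         profile={da_tube: F, da_top: top},
                         n_samples=len(cand) + len(anchors))


def disk_cup_barrier(da_disk: float = 1.04, da_grid=None,
                     kappa: float = 20.0) -> BarrierResult:
    """Barrier H2 between the disk minimum and the cup family at v = 0.577.

    ``B`` is the refined disk energy at ``da_disk``; the barrier top is the
    maximum of the refined continuation from the disk down in area
    difference (the disk rim closes into a bowl before collapsing to the
    cup).  Deterministic: both the anchor and the continuation are pure
    quenches.
    """
    if da_grid is None:
        da_grid = (1.00, 0.96, 0.92, 0.88, 0.84)
    disk, model, B = disk_state(da_disk=da_disk, kappa=kappa)
    profile = continuation_profile(disk, model, da_grid)
    da_top = max(profile, key=profile.get)
    top = profile[da_top]
    profile[float(da_disk)] = B
    return BarrierResult(height=top - B, E_min=B, E_top=top,
                         da_min=da_disk, da_top=da_top, profile=profile,
                         n_samples=len(da_grid) + 1)
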