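"""Metropolis Monte Carlo engine: sweeps, annealing, branch scans, production.

One MC step is one *sweep*: ``n_v`` vertex-move attempts, ``n_e`` edge-flip
attempts, and one move attempt per protein bead.  Moves are accepted with
the Metropolis probability ``min(1, exp(-dE/T))``; tether and excluded-volume
violations are rejections, not errors.  Simulated annealing follows a
four-phase protocol (volume ramp, area-difference ramp, equilibration,
linear cooling); the phase lengths are the published step counts times a
global scale factor so the same protocol runs at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from .energetics import EnergyModel, shape_state
from .mesh import MAX_DEGREE, TriMesh, build_icosphere, tether_bounds
from .proteins import DimerChain

__all__ = [
    "MCSchedule",
    "MembraneState",
    "SAResult",
    "metropolis_sweep",
    "tune_move_widths",
    "simulated_annealing",
    "shape_branch_scan",
    "production_run",
    "sample_harmonic_toy",
    "reference_icosphere",
]


@dataclass
class MCSchedule:
    """Step counts (in sweeps) per annealing phase, temperatures and widths.

    The phase lengths are stored at full scale (1e6 / 1e6 / 5e5 / 5e5) and
    multiplied by ``scale`` when run, so scaled-down desk runs keep the
    published proportions.  Move widths adapt during warm-up toward ~40%
    acceptance and are frozen for production/umbrella sampling; during SA
    cooling they shrink with sqrt(T/T0).
    """

    volume_ramp: int = 1_000_000
    da_ramp: int = 1_000_000
    equilibrate: int = 500_000
    cool: int = 500_000
    scale: float = 1.0
    T_start: float = 1.0
    T_end: float = 1.0e-3
    vertex_width: float = 0.08
    bead_width: float = 0.08
    refresh_stride: int = 20
    seed: int = 0

    def __post_init__(self):
        if min(self.volume_ramp, self.da_ramp, self.equilibrate, self.cool) < 0:
            raise ValueError("phase step counts must be >= 0")
        if self.T_start < 0 or self.T_end < 0:
            raise ValueError("temperatures must be >= 0")

    def phase_sweeps(self) -> tuple[int, int, int, int]:
        s = self.scale
        return tuple(max(1, int(round(n * s))) for n in
                     (self.volume_ramp, self.da_ramp, self.equilibrate, self.cool))


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31 - 1)) + 1 for c in ss.spawn(n)]


class MembraneState:
    """Mutable MC state: mesh connectivity + caches + protein chains.

    All arrays are laid out for the numba kernels; :meth:`mesh` and
    :meth:`chains_out` convert back to the library containers.
    """

    OBS_COLUMNS = ("sweep", "E_b", "A", "V", "v", "da", "E_bd", "E_d", "T")

    def __init__(self, mesh: TriMesh, chains: list[DimerChain] | None = None,
                 model: EnergyModel | None = None,
                 l_bounds: tuple[float, float] | None = None):
        self.model = model if model is not None else EnergyModel()
        self.pos = np.ascontiguousarray(mesh.vertices, dtype=np.float64)
        self.tri = np.ascontiguousarray(mesh.triangles, dtype=np.int64)
        self.edge_v = np.ascontiguousarray(mesh.edges, dtype=np.int64)
        self.edge_t = np.ascontiguousarray(mesh.edge_tri, dtype=np.int64)
        self.tri_edge = np.ascontiguousarray(mesh.tri_edge, dtype=np.int64)
        self.v_edges, self.v_deg = mesh.vertex_edge_table()
        self.v_edges = np.ascontiguousarray(self.v_edges)
        self.v_deg = np.ascontiguousarray(self.v_deg)
        nt, ne, nv = mesh.n_triangles, mesh.n_edges, mesh.n_vertices
        self.tri_n = np.zeros((nt, 3))
        self.tri_a = np.zeros(nt)
        self.tri_vc = np.zeros(nt)
        self.e_len = np.zeros(ne)
        self.e_phi = np.zeros(ne)
        self.Mv = np.zeros(nv)
        self.Av = np.zeros(nv)
        self.scal = np.zeros(6)
        if l_bounds is None:
            l_bounds = tether_bounds(mesh)
        self.l_bounds = l_bounds

        chains = list(chains or [])
        self.chain_templates = [c.copy() for c in chains]
        nb_per = [c.n_beads for c in chains]
        if chains and len(set(nb_per)) != 1:
            raise ValueError("all chains must have the same bead count")
        nb = sum(nb_per)
        self.bpos = (np.concatenate([c.positions for c in chains])
                     if chains else np.zeros((0, 3)))
        self.chain_ptr = np.cumsum([0] + nb_per).astype(np.int64)
        nc = len(chains)
        m = nb_per[0] if chains else 16
        self.bond_ref = np.zeros((max(nc, 1), m - 1))
        self.th_ref = np.zeros((max(nc, 1), m - 2))
        self.ga_ref = np.zeros((max(nc, 1), m - 3))
        self.kb_c = np.zeros(max(nc, 1))
        self.ka_c = np.zeros(max(nc, 1))
        self.kd_c = np.zeros(max(nc, 1))
        for i, c in enumerate(chains):
            self.bond_ref[i] = c.bond_ref
            self.th_ref[i] = c.theta_ref
            self.ga_ref[i] = c.gamma_ref
            self.kb_c[i] = c.K_bond
            self.ka_c[i] = c.K_ang
            self.kd_c[i] = c.K_dih
        self.bead_tri = np.zeros(nb, dtype=np.int64)
        self.bead_dist = np.zeros(nb)
        self.bead_side = np.zeros(nb, dtype=np.int64)
        self.bead_eps = np.zeros(nb)
        self.ed_c = np.zeros(max(nc, 1))
        self.recompute()

    # -- bookkeeping ---------------------------------------------------------
    def _pm(self, model: EnergyModel | None = None, T: float = 1.0) -> np.ndarray:
        m = model or self.model
        pm = np.zeros(16)
        pm[K.P_KAP] = m.kappa
        pm[K.P_KA] = m.K_A
        pm[K.P_KV] = m.K_V
        pm[K.P_KDA] = m.K_da
        pm[K.P_AREF] = m.A_ref if m.A_ref is not None else 1.0
        pm[K.P_VREF] = m.V_ref if m.V_ref is not None else 1.0
        pm[K.P_DA0] = m.da_0
        pm[K.P_KUMB] = m.k_umb
        pm[K.P_DAUMB] = m.da_umb
        pm[K.P_LMIN], pm[K.P_LMAX] = self.l_bounds
        pm[K.P_U] = m.U
        pm[K.P_D0] = m.d0
        pm[K.P_D1] = m.d1
        pm[K.P_T] = T
        pm[K.P_SEP] = 1.0
        return pm

    def recompute(self, model: EnergyModel | None = None) -> None:
        """Full (non-incremental) recomputation of all caches and scalars."""
        m = model or self.model
        K.full_recompute(self.pos, self.tri, self.edge_v, self.edge_t,
                         self.v_edges, self.v_deg, self.tri_n, self.tri_a,
                         self.tri_vc, self.e_len, self.e_phi, self.Mv,
                         self.Av, self.scal, m.kappa)
        if len(self.bpos):
            K.refresh_beads(self.bpos, self.tri, self.pos, self.tri_a,
                            self.bead_tri, self.bead_dist, self.bead_side,
                            self.bead_eps, self.scal, self._pm(m))
            for c in range(len(self.chain_templates)):
                self.ed_c[c] = K.chain_energy(
                    self.bpos, self.chain_ptr[c], self.chain_ptr[c + 1],
                    self.bond_ref[c], self.th_ref[c], self.ga_ref[c],
                    self.kb_c[c], self.ka_c[c], self.kd_c[c])
            self.scal[K.I_ED] = self.ed_c[: len(self.chain_templates)].sum()

    @property
    def area(self) -> float:
        return float(self.scal[K.I_A])

    @property
    def volume(self) -> float:
        return float(self.scal[K.I_V])

    @property
    def reduced_volume(self) -> float:
        return float(6 * np.sqrt(np.pi) * self.volume / self.area ** 1.5)

    @property
    def area_difference(self) -> float:
        return float(self.scal[K.I_SM] / (2 * np.sqrt(np.pi * self.area)))

    @property
    def bending_energy(self) -> float:
        return float(self.scal[K.I_EB])

    def mesh(self) -> TriMesh:
        return TriMesh(self.pos.copy(), self.tri.copy())

    def chains_out(self) -> list[DimerChain]:
        out = []
        for i, c in enumerate(self.chain_templates):
            cc = c.copy()
            cc.positions = self.bpos[self.chain_ptr[i]:self.chain_ptr[i + 1]].copy()
            out.append(cc)
        return out

    # -- running -------------------------------------------------------------
    def run(self, n_sweeps: int, model: EnergyModel | None = None, *,
            T: float | tuple[float, float] = 1.0,
            V_ref: float | tuple[float, float] | None = None,
            da_0: float | tuple[float, float] | None = None,
            vertex_width: float = 0.08, bead_width: float = 0.08,
            tune: bool = False, width_follows_T: bool = False,
            seed: int = 1, refresh_stride: int = 20,
            sample_stride: int = 0, flips_per_sweep: int | None = None):
        """Run one MC phase; ramped quantities take (start, end) tuples.

        Returns ``(stats, observables)`` where ``stats`` holds acceptance
        fractions and the (possibly tuned) move widths, and ``observables``
        is a float array with columns :data:`OBS_COLUMNS` sampled every
        ``sample_stride`` sweeps (empty when stride is 0).
        """
        m = model or self.model
        T0, T1 = (T if isinstance(T, tuple) else (T, T))
        pm = self._pm(m, T0)
        if V_ref is None:
            v0 = v1 = pm[K.P_VREF]
        else:
            v0, v1 = (V_ref if isinstance(V_ref, tuple) else (V_ref, V_ref))
        if da_0 is None:
            d0_ = d1_ = pm[K.P_DA0]
        else:
            d0_, d1_ = (da_0 if isinstance(da_0, tuple) else (da_0, da_0))
        n_samp = n_sweeps // sample_stride if sample_stride > 0 else 0
        obs = np.zeros((n_samp, 9))
        acc, wv, wb, nrow = K.run_phase(
            self.pos, self.tri, self.edge_v, self.edge_t, self.tri_edge,
            self.v_edges, self.v_deg, self.tri_n, self.tri_a, self.tri_vc,
            self.e_len, self.e_phi, self.Mv, self.Av, self.scal,
            self.bpos, self.chain_ptr, self.bond_ref, self.th_ref,
            self.ga_ref, self.kb_c, self.ka_c, self.kd_c,
            self.bead_tri, self.bead_dist, self.bead_side, self.bead_eps,
            self.ed_c, pm, int(n_sweeps),
            float(v0), float(v1), float(d0_), float(d1_),
            float(T0), float(T1),
            float(vertex_width), float(bead_width),
            1 if tune else 0, 1 if width_follows_T else 0,
            int(seed),
            int(refresh_stride), int(sample_stride), obs,
            int(flips_per_sweep if flips_per_sweep is not None
                else len(self.edge_v)))
        stats = {
            "acc_vertex": acc[0] / max(acc[1], 1.0),
            "acc_flip": acc[2] / max(acc[3], 1.0),
            "acc_bead": acc[4] / max(acc[5], 1.0),
            "vertex_width": wv,
            "bead_width": wb,
        }
        return stats, obs[:nrow]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def reference_icosphere(subdivision_level: int = 3) -> TriMesh:
    """Icosphere whose mean triangle area is that of a unit-edge equilateral
    triangle, so that the tether length scale is l = 1."""
    nt = 20 * 4 ** subdivision_level
    area = nt * np.sqrt(3.0) / 4.0
    radius = np.sqrt(area / (4.0 * np.pi))
    m = build_icosphere(subdivision_level, radius)
    # rescale so the actual mean triangle area matches exactly
    m.vertices *= np.sqrt(area / m.area())
    return m


def metropolis_sweep(state: MembraneState, model: EnergyModel | None = None,
                     n_sweeps: int = 1, **kwargs):
    """Run plain Metropolis sweeps at fixed conditions (thin wrapper)."""
    return state.run(n_sweeps, model, **kwargs)


def tune_move_widths(state: MembraneState, model: EnergyModel | None = None,
                     n_sweeps: int = 300, T: float = 1.0,
                     vertex_width: float = 0.08, bead_width: float = 0.08,
                     seed: int = 1):
    """Adapt move widths toward ~40% acceptance on an equilibrating state.

    Returns ``(vertex_width, bead_width, stats)``; raises RuntimeError when
    tuning cannot reach the window (e.g. T = 0 freezes all uphill moves).
    """
    if T <= 0:
        raise RuntimeError("cannot tune acceptance at T = 0")
    st, _ = state.run(n_sweeps, model, T=T, tune=True, seed=seed,
                      vertex_width=vertex_width, bead_width=bead_width)
    st2, _ = state.run(max(50, n_sweeps // 4), model, T=T, seed=seed + 1,
                       vertex_width=st["vertex_width"],
                       bead_width=st["bead_width"])
    if not (0.2 < st2["acc_vertex"] < 0.65):
        raise RuntimeError(
            f"width tuning failed: acceptance {st2['acc_vertex']:.2f}")
    return st["vertex_width"], st["bead_width"], st2


@dataclass
class SAResult:
    mesh: TriMesh
    bending_energy: float          # k_B T
    energy_8pik: float             # E_b / (8 pi kappa)
    reduced_volume: float
    area_difference: float
    repeat_energies: list = field(default_factory=list)


def _sa_single(v_target: float, da_target: float, model: EnergyModel,
               schedule: MCSchedule, seed: int,
               subdivision_level: int) -> tuple[TriMesh, float]:
    mesh = reference_icosphere(subdivision_level)
    A_ref = mesh.area()
    V_target = v_target * A_ref ** 1.5 / (6.0 * np.sqrt(np.pi))
    m = replace(model, A_ref=A_ref, V_ref=V_target, da_0=da_target)
    state = MembraneState(mesh, model=m)
    V0 = state.volume
    n1, n2, n3, n4 = schedule.phase_sweeps()
    seeds = _child_seeds(seed, 4)
    wv = schedule.vertex_width
    # phase 1: deflate at constant T, no da constraint, tuning on
    m1 = replace(m, K_da=0.0)
    st, _ = state.run(n1, m1, T=schedule.T_start, V_ref=(V0, V_target),
                      vertex_width=wv, tune=True, seed=seeds[0],
                      refresh_stride=schedule.refresh_stride)
    wv = st["vertex_width"]
    # phase 2: ramp the area-difference target from the current value
    da_now = state.area_difference
    st, _ = state.run(n2, m, T=schedule.T_start, da_0=(da_now, da_target),
                      vertex_width=wv, tune=True, seed=seeds[1],
                      refresh_stride=schedule.refresh_stride)
    wv = st["vertex_width"]
    # phase 3: equilibrate
    st, _ = state.run(n3, m, T=schedule.T_start, vertex_width=wv, tune=True,
                      seed=seeds[2], refresh_stride=schedule.refresh_stride)
    wv = st["vertex_width"]
    # phase 4: cool linearly, widths shrink with sqrt(T)
    state.run(n4, m, T=(schedule.T_start, schedule.T_end), vertex_width=wv,
              width_follows_T=True, seed=seeds[3],
              refresh_stride=schedule.refresh_stride)
    state.recompute()
    return state.mesh(), state.bending_energy


def simulated_annealing(v_target: float, da_target: float,
                        model: EnergyModel | None = None,
                        schedule: MCSchedule | None = None,
                        n_repeats: int = 10,
                        subdivision_level: int = 3) -> SAResult:
    """Minimum-bending-energy shape at (v, da) by simulated annealing.

    Runs ``n_repeats`` independent SA simulations from a spherical vesicle
    (four-phase protocol) and returns the one with minimum elastic energy.
    Free-vesicle constraint stiffnesses default to K_da = 5e6 and
    K_A = K_V = 1e6 k_B T.
    """
    if not 0.0 < v_target <= 1.0:
        raise ValueError("v_target must be in (0, 1]")
    model = model or EnergyModel(kappa=20.0, K_A=1e6, K_V=1e6, K_da=5e6)
    if model.K_da <= 0:
        model = replace(model, K_da=5e6)
    schedule = schedule or MCSchedule()
    seeds = _child_seeds(schedule.seed, n_repeats)
    best = None
    energies = []
    for r in range(n_repeats):
        mesh, eb = _sa_single(v_target, da_target, model, schedule,
                              seeds[r], subdivision_level)
        energies.append(eb)
        if best is None or eb < best[1]:
            best = (mesh, eb)
    mesh, eb = best
    st = shape_state(mesh, model.kappa)
    return SAResult(mesh=mesh, bending_energy=eb,
                    energy_8pik=eb / (8 * np.pi * model.kappa),
                    reduced_volume=st.reduced_volume,
                    area_difference=st.area_difference,
                    repeat_energies=energies)


def shape_branch_scan(v_target: float, da_grid, model: EnergyModel | None = None,
                      schedule: MCSchedule | None = None, n_repeats: int = 10,
                      subdivision_level: int = 3, classify: bool = True):
    """SA minima along a grid of area differences at fixed reduced volume.

    Returns a pandas DataFrame with columns ``da``, ``E_8pik`` (rescaled
    bending energy of the best repeat), ``E_kBT`` and ``shape``; the branch
    extrema define the tube-to-disk (H1) and disk-to-cup (H2) barriers.
    """
    import pandas as pd

    model = model or EnergyModel(kappa=20.0, K_A=1e6, K_V=1e6, K_da=5e6)
    schedule = schedule or MCSchedule()
    rows = []
    for i, da in enumerate(np.atleast_1d(np.asarray(da_grid, dtype=float))):
        sub = replace(schedule, seed=schedule.seed + 7919 * (i + 1))
        res = simulated_annealing(v_target, float(da), model, sub,
                                  n_repeats=n_repeats,
                                  subdivision_level=subdivision_level)
        label = ""
        if classify:
            from .analysis import classify_shape

            label = classify_shape(res.mesh).label
        rows.append({"da": float(da), "E_8pik": res.energy_8pik,
                     "E_kBT": res.bending_energy, "shape": label,
                     "v": res.reduced_volume,
                     "da_measured": res.area_difference})
    return pd.DataFrame(rows)


def production_run(state: MembraneState, model: EnergyModel | None = None,
                   n_sweeps: int = 10_000, seed: int = 0,
                   sample_stride: int = 50, frame_stride: int = 0,
                   T: float = 1.0, vertex_width: float | None = None,
                   bead_width: float | None = None, tune_sweeps: int = 200):
    """Fixed-temperature production run of a vesicle with adhered dimers.

    Widths are tuned during a short warm-up, then frozen.  Returns a dict
    with the observable table, acceptance stats, captured frames (meshes +
    chains every ``frame_stride`` sweeps if nonzero) and the final shape
    label from :func:`phagosim.analysis.classify_shape`.
    """
    from .analysis import classify_shape

    model = model or state.model
    seeds = _child_seeds(seed, 3)
    wv = vertex_width if vertex_width is not None else 0.08
    wb = bead_width if bead_width is not None else 0.08
    if tune_sweeps > 0:
        st, _ = state.run(tune_sweeps, model, T=T, tune=True, seed=seeds[0],
                          vertex_width=wv, bead_width=wb)
        wv, wb = st["vertex_width"], st["bead_width"]
    frames = []
    obs_parts = []
    chunk = n_sweeps if frame_stride <= 0 else frame_stride
    done = 0
    stats = {}
    k = 0
    while done < n_sweeps:
        n = min(chunk, n_sweeps - done)
        stats, obs = state.run(n, model, T=T, vertex_width=wv, bead_width=wb,
                               seed=(seeds[1] + 17 * k) % (2 ** 31 - 1),
                               sample_stride=sample_stride)
        if len(obs):
            obs = obs.copy()
            obs[:, 0] += done
            obs_parts.append(obs)
        done += n
        k += 1
        if frame_stride > 0:
            frames.append((state.mesh(), state.chains_out()))
    state.recompute()
    final_mesh = state.mesh()
    label = classify_shape(final_mesh)
    obs = (np.concatenate(obs_parts) if obs_parts else np.zeros((0, 9)))
    return {
        "observables": obs,
        "obs_columns": MembraneState.OBS_COLUMNS,
        "stats": stats,
        "frames": frames,
        "final_mesh": final_mesh,
        "final_chains": state.chains_out(),
        "final_label": label,
        "widths": (wv, wb),
    }


# ---------------------------------------------------------------------------
# engine sanity oracle: Metropolis sampling of a 1-D harmonic well
# ---------------------------------------------------------------------------

def sample_harmonic_toy(k: float, n_steps: int, width: float = 1.0,
                        seed: int = 0, T: float = 1.0) -> np.ndarray:
    """Metropolis samples of a particle in the well ``0.5 k x^2``.

    Uses the same acceptance rule as the membrane engine; the long-run
    position variance must equal ``T/k`` (equipartition), which anchors the
    engine's Boltzmann statistics independently of the membrane code.
    """
    rng = np.random.default_rng(seed)
    x = 0.0
    out = np.empty(n_steps)
    for i in range(n_steps):
        xn = x + width * (rng.random() - 0.5) * 2.0
        dE = 0.5 * k * (xn * xn - x * x)
        if dE <= 0 or rng.random() < np.exp(-dE / T):
            x = xn
        out[i] = x
    return out
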