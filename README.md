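# phagosim

Monte Carlo simulation of fluid lipid vesicles on dynamically triangulated
meshes, built to study how curved protein scaffolds drive the early shapes
of the phagophore (the cup-shaped double membrane of autophagy).

The package covers:

* **Membrane model** — Helfrich bending energy on closed genus-0
  triangulations, with stiff quadratic constraints on area, volume and the
  integrated mean curvature ("area difference" `da`), plus an optional
  harmonic umbrella bias on `da`.
* **Monte Carlo engine** — Metropolis vertex moves, tethered bond flips
  and rigid/internal protein-bead moves, compiled with numba
  (~2 ms per sweep on a 642-vertex mesh). Simulated annealing schedules,
  fixed-temperature production runs and a 1-D harmonic-well oracle for the
  sampling statistics.
* **Protein model** — S-shaped 16-bead dimers (two oppositely curving
  crescents) and straight control chains, bound to the membrane by a
  square-well adhesion per bead with a hard core.
* **Shape branches and barriers** — deterministic quench (L-BFGS on the
  analytic gradient + downhill edge flips), midpoint-subdivision
  re-measurement, and branch continuation along `da` to measure the
  tube → disk and disk → cup energy barriers of deflated vesicles.
* **Free energies** — umbrella sampling along `da`, in-house WHAM with
  autocorrelation thinning and bootstrap errors, bi-exponential
  autocorrelation fits, and Kramers escape-time estimates.
* **Shape analysis** — rigid-motion/scale-invariant classification
  (sphere, tube, disk, paddle, bowl, cup, starfish) from gyration
  eigenvalues, pocket depth and angular arm counts.
* **I/O + CLI** — YAML run configs with validation and hashing, ASCII PLY
  meshes, directory-based trajectories, and a `phagosim` command-line
  front end.

## Units

Energies are in units of k_B T; the bending rigidity `kappa` is given in
k_B T (typical values 10–20). Lengths are in tether units: the mesh is
scaled so the mean triangle area is that of a unit-edge equilateral
triangle. Shape energies are usually reported in units of `8 pi kappa`
(the bending energy of a sphere); `phagosim.free_energy.barrier_to_kT`
converts. Reduced volume `v = 6 sqrt(pi) V / A^(3/2)` and area difference
`da = M / (2 sqrt(pi A))` are dimensionless (both are 1 for a sphere).

## Quick start

```python
from phagosim.branches import tube_disk_barrier, disk_cup_barrier

r = tube_disk_barrier(n_spheres=3, seed=1)   # H1 at v = 1/sqrt(3)
print(r.height)                              # in 8*pi*kappa units
print(disk_cup_barrier().height)             # H2, deterministic
```

```sh
# relaxed shape at a target (v, da) by simulated annealing (scaled down)
phagosim anneal --v 0.65 --da 1.2 --scale 0.001 --out shape.ply
phagosim classify --mesh shape.ply

# production run with adhered S-dimers
cat > run.yaml <<EOF
preset: fused3_s6
n_sweeps: 20000
seed: 3
EOF
phagosim run --config run.yaml --out run1
phagosim report --runs .

# umbrella sampling + WHAM along the area difference
phagosim umbrella --mesh shape.ply --centers 1.20,1.19,1.18 --out windows
phagosim wham --windows windows --out pmf.tsv
```

## Tests

```sh
python -m pytest            # full suite, ~15-20 min (barrier fixtures)
python -m pytest tests/test_mesh.py tests/test_energetics.py  # seconds
```

`tests/test_acceptance.py` holds one test per headline physics criterion
with explicit tolerances; the expensive branch barriers are computed once
per session in `tests/conftest.py` fixtures.
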