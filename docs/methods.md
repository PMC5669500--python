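# Methods

## Membrane discretization

A vesicle is a closed, orientable, genus-0 triangulation. Bending energy
uses the discrete squared-mean-curvature form

```
E_b = 2 kappa sum_v (M_v)^2 / A_v
```

with `M_v` the vertex-integrated mean curvature from edge dihedrals
(`M_v = sum_e l_e phi_e / 4` over edges at `v`) and `A_v` a third of the
incident triangle area. On icospheres this converges to the sphere limit
`8 pi kappa` from above with errors shrinking with refinement (verified in
the test suite at subdivision levels 2–4). Area, volume and integrated
mean curvature enter stiff quadratic penalties:

```
E_c = K_A/2 (A/A_ref - 1)^2 + K_V/2 (V/V_ref - 1)^2 + K_da/2 (da - da_0)^2
```

Reduced volume `v = 6 sqrt(pi) V / A^(3/2)` and area difference
`da = M / (2 sqrt(pi A))` are the two dimensionless shape coordinates;
`n` equal fused spheres give `v = 1/sqrt(n)` exactly.

Fluidity comes from tethered bond flips: edges must stay inside
`[l 3^(-1/4), l 3^(1/4)]` where `l` is the tether length set by the mean
triangle area; flips that violate the interval, orientation or
manifoldness are rejected. Invariants (Euler characteristic 2, closed
2-manifold, no degenerate triangles) are re-validated in tests after >1e4
accepted updates.

## Monte Carlo engine

One sweep = one attempted random displacement per vertex, one attempted
flip per edge and (when proteins are present) one attempted move per
bead, with Metropolis acceptance at temperature T. Move widths adapt
toward ~40% acceptance during warm-up and are frozen for sampling. All
randomness derives from a single user seed through
`numpy.random.SeedSequence.spawn`. A 1-D harmonic-well sampler that
shares the acceptance rule anchors the Boltzmann statistics
(variance = T/k within 3 standard errors).

## Protein scaffolds

An S-dimer is a chain of 16 beads on two oppositely curving circular arcs
with unit chords, stiff bond/angle terms and a reference (zero-energy)
geometry at the construction; straight chains are the control. Adhesion
is a square well per bead: a bead at signed surface distance
`d in (d0, d1]` contributes `-U * A_t` with `A_t` its closest triangle's
area; `d <= d0` is a rejected hard-core overlap. The dimensionless
binding strength is `u = U * 16 * Abar / (8 pi kappa)` (`Abar` = mean
triangle area), so `u` measures the full-dimer binding energy against
the sphere bending energy.

## Shape branches and barriers: quench + refinement

The energy branches of deflated vesicles vs `da` at fixed `v` carry
barriers of a few 0.01 in `8 pi kappa` units — tens of k_B T on shapes
whose total bending energy is ~1000 k_B T. Simulated-annealing repeats
resolve this only with very long schedules: after any affordable cool,
frozen thermal roughness contributes more residual energy than the
barrier height. The protocol here therefore separates *basin finding*
from *energy measurement*:

1. **Anchors.** Each family is entered from a structured start: fused
   spheres (tube family, necks opened by warm MC at T = 1 while the `da`
   constraint ramps to its target), an oblate spheroid (disk family), a
   stomatocyte with matched starting volume (cup family).
2. **Warm exploration.** Short T = 1 runs with several independent seeds
   cross into the basin, especially near barrier tops.
3. **Deterministic quench.** L-BFGS on the analytic gradient of
   `E_b + E_c`, alternated with downhill edge flips, removes thermal
   noise.
4. **Refined re-measurement.** The quenched mesh is midpoint-subdivided
   (4x triangles, ~2562 vertices) and re-quenched. This step re-prices
   sharp rims that the coarse mesh under-resolves; without it the coarse
   quench admits spurious flattened "ribbon" states that undercut the
   physical branch.
5. Branch energies are minima over seeds of the refined quench energy;
   barriers are differences of these minima.

Measured this way (kappa = 20, stiff constraints):

* **H1** (tube → disk at v = 0.577): metastable tube at `da = 1.44`,
  barrier top = minimum over warm candidates at `da = 1.33` (the last
  `da` before candidates fall onto the disk branch). Typical value
  ~0.061 in `8 pi kappa` units.
* **H2** (disk → cup at v = 0.577): disk minimum at `da = 1.04`,
  deterministic continuation down to `da = 0.84`; the profile maximum
  (bowl-like rim closure, near `da` 0.84–0.88) tops the barrier.
  Typical value ~0.041.
* **H1 at v = 0.5** (four fused vesicles, tube at `da = 1.61`, top at
  `da = 1.45`): the desk-scale measurement straddles the lower edge of
  the reference band (~0.07 ± 20%). At this system size the two branch
  minima converge slowly with seed count: the refined tube-anchor energy
  scatters ~0.015 across warm seeds (2.714–2.743 in `8 pi kappa` units,
  with an occasional stuck state near 3.8), and a deeper tube basin
  (2.714) appears in roughly one seed in five. Seed families that find
  it read H1 ~ 0.061; those that do not read ~0.052 against a rim top
  near 2.776. The test fixture keeps its pre-declared seed (which reads
  ~0.052 and fails the band) rather than switching to a seed that
  happens to pass; the acceptance script, which has more time budget,
  samples four anchor and four candidate seeds.

**Shape diagram.** Ground-state transitions are located by bracketing:
the refined quenched family energy with `K_da = 0` changes order
tube → disk between v = 0.66 and 0.64 (reference crossover 0.652) and
disk → cup between v = 0.61 and 0.58 (reference 0.592). The cup anchor's
invagination depth is chosen by closest starting reduced volume so the
quench stays inside the family.

## Free energies

Umbrella windows bias `da` harmonically with the stiff `da` constraint
switched off. `umbrella_scan` seeds each window from the previous
window's final configuration so the membrane deforms gradually along the
reaction coordinate; isolated seeding from one anchor produces
disconnected histograms and a hysteretic, inflated PMF. WHAM solves the
standard self-consistent equations on a common grid, thins samples by the
integrated autocorrelation time, reports bootstrap errors and flags
disconnected segments instead of silently joining them. Verified against
an analytic quartic double well to < 0.1 k_B T RMS.

At short per-window sampling (~1000 sweeps) the membrane's shape
relaxation along `da` is slower than the scan: window means lag their
bias centers several times more than the branch slope predicts, and the
dragged PMF for the tube → disk passage comes out ~53 k_B T, roughly 70%
above the quench barrier (~31 k_B T at kappa = 20); at 1200-sweep
windows it was ~46 k_B T, i.e. the overshoot shrinks with sampling, as
hysteresis should. The corresponding
consistency test documents this and is expected to fail until the
windows are run long enough to equilibrate (orders of magnitude more
sweeps).

Escape times follow Kramers, `t = 2 pi tau exp(H/k_B T)` with `tau` the
measured relaxation time of the reaction coordinate (bi-exponential
autocorrelation fits supply the timescales); e.g. `tau = 0.05 us` and a
21 k_B T barrier give ~7 minutes.

## Protein-driven cup formation

With six S-dimers straddling the necks of a triple fused vesicle
(kappa = 10, softer constraints), the dimers bind within the first
thousand sweeps (adhesion energy ~ -110 k_B T at u = 0.12 vs ~ -35 k_B T
at u = 0.05) but cup formation is a slow, activated remodeling: probe
runs show no pocket growth through 40k sweeps (pocket depth stays
~0.03), consistent with the ~1e6-sweep scale needed for the full
transition. The phenomenology test asserts the target behavior
(>= 75% cups at u = 0.12, none at u = 0.05 or for straight chains) at a
4000-sweep scale and is expected to fail on the cup fraction until run
at full length.

## Shape classification

Shapes are classified invariant under rigid motions and uniform scaling,
using gyration-tensor eigenvalue ratios, an angular arm count, and a
pocket depth: the deepest first-hit recession of the surface behind its
support plane along the principal axes (ray casting), normalized by the
largest extent. Pocket depth > 0.5 is a cup, 0.2–0.5 a bowl; elongated
shapes split into tubes and paddles by cross-section anisotropy, flat
ones are disks.
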