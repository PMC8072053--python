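# Methods

## Scope and model

The package implements a bottom-up coarse-graining chain for
nucleosome–nucleosome interactions along the inter-nucleosome center
distance d (Å):

1. **Umbrella windows.** Each window biases d with ½k(d−d0)²; ladders are
   unions of inclusive arithmetic ranges of d0, merged and sorted.  The
   linked-nucleosome (LN) preset is 175–250 Å step 1 Å plus 187.5–237.5 Å
   step 1 Å (76 + 51 = 127 windows, k = 5 kJ/mol/Å²); the stacked,
   unlinked (ULN) preset is 60–91 Å step 0.5 Å plus 55–59 Å step 1 Å
   (63 + 5 = 68 windows).  Inclusive endpoints are the only convention
   that reproduces both counts from the stated ranges.  The documented
   "10 kJ/mol/Å² in alternative windows" for the ULN ladder is ambiguous
   between *alternating* windows and a replacement value; we read it as
   alternating (even sorted indices get 10, odd get 5 kJ/mol/Å²) and
   expose a per-window callable override so either reading is one line of
   configuration.
2. **Observables.** The nucleosome center is the weighted centroid of a
   selected point set (DNA phosphorus atoms or histone-core Cα; PDB
   parsing and the selection language come from MDAnalysis, first model,
   coordinates in Å).  The superhelical axis is the smallest-variance
   principal axis of the centered, weighted cloud — the normal of the
   best-fit disc plane, appropriate because the nucleosomal DNA superhelix
   is disc-like.  Plane normals carry no sign, so the inter-axis angle is
   folded to [0°, 90°] by default (a flag disables folding).
3. **Synthetic biased sampling.** Overdamped Langevin (Euler–Maruyama)
   on a known 1D reference landscape plus the window bias,
   x' = x − (D/kBT)V′(x)dt + √(2Ddt)·ξ, with reflecting boundaries (the
   only boundary handling that preserves Boltzmann stationarity on a
   finite domain).  Defaults: T = 303.15 K, D = 1 Å²/ps, dt = 0.05 ps,
   save every 10 steps, 1000 equilibration steps, chain start at the
   combined-potential minimum.  Multiple independent chains per window
   are propagated vectorized and concatenated; per-window seeds derive
   from the base seed and window index via `SeedSequence`, so campaigns
   are bit-reproducible.  Reference presets: "LN-like" = harmonic well
   ½·0.01·(d−225)² on [160, 290] Å; "ULN-like" = exponential wall
   exp(9.2086 − 0.1213·d) on [50, 110] Å; "flat" for calibration tests.
4. **WHAM.** Standard self-consistent equations on a shared 0.5 Å bin
   grid (the finest window spacing), solved by direct iteration with the
   bias Boltzmann factors precomputed (each sweep is two matrix–vector
   products; the residual is max |Δf_i|, tolerance 1e-8 kcal/mol, cap
   1e5 sweeps).  Unoccupied bins are masked, never interpolated.  The
   profile is anchored at the occupied-bin minimum (any anchor is gauge
   equivalent).  Bins are best restricted to the restrained span of the
   ladder (the pipeline does this automatically): bins reachable only by
   the sparse sample tails beyond the outermost windows carry large
   −kBT ln(P) noise and can corrupt the anchor by ~1 kcal/mol.
   Uncertainties come from Monte-Carlo bootstrap: each replicate redraws
   every window histogram with N_i/g_i multinomial draws (g_i = 1 + 2τ_int
   from the integrated autocorrelation of that window's series, averaged
   over chains), re-solves WHAM warm-started from the full-data window
   free energies, re-anchors, and the per-bin spread across replicates is
   the error.  Window-overlap diagnostics report Σ_b min(p_ib, p_jb) and
   flag adjacent pairs below 0.05.  An optional radial-Jacobian mode adds
   2kBT·ln d; the default is "none", matching standard 1D distance WHAM
   usage.
5. **Potential fits.**  Harmonic: weighted quadratic regression of
   F ≈ a·d² + b·d + c (k = 2a, d0 = −b/2a); the constant c absorbs the
   anchor, so the fit is shift invariant; the default window is the bins
   within 2 kcal/mol of the minimum and must bracket an interior minimum.
   Exponential: nonlinear least squares of exp(β − α·d), initialized from
   the log-linear regression.  The typeset ambiguity between
   exp(−α·d − β) and exp(−(α·d − β)) is resolved to the latter
   (≡ exp(β − α·d)): with the published parameters it yields a
   kcal/mol-scale wall over 55–90 Å, whereas the former is ~1e-7 kcal/mol
   everywhere; the convention is stored on the model.  Shifted Coulomb:
   A/(d − B) with B read as a distance shift in Å (the only dimensionally
   consistent reading), B bounded below the smallest window distance.
   Both repulsive fitters accept `with_offset=True`, adding a free
   additive constant that absorbs the profile's anchoring gauge.  For the
   exponential this matters little (its tail genuinely decays within the
   window); for the shifted Coulomb it is essential — the 1/(d−B) tail is
   ~1 kcal/mol at 90 Å, so ignoring the gauge biases A by tens of
   percent.  Weights 1/σ² are used whenever bootstrap uncertainties are
   present and finite.  The harmonic vibrational frequency is
   ν = (1/2π)√(k/μ); note that ν = 2.41e9 s⁻¹ together with
   k = 0.01 kcal/mol/Å² implies μ ≈ 1.8e4 Da by closed-form inversion,
   an order of magnitude below a nucleosome's ~2e5 Da mass — the mass
   convention behind that frequency is not recoverable, so ν is reported
   as a function of assumed μ and not used as a validation quantity.
6. **Coarse-grained fiber.**  N beads, explicit ring topology
   (bond i–(i+1 mod N)); "covalently bonded to itself" is realized as the
   explicit ring in open space, which is dynamically equivalent to closure
   through periodic images for the bonded topology and avoids spatial
   PBC machinery.  Energy terms: harmonic bonds; repulsion (exponential
   or shifted Coulomb) over all non-bonded pairs, energy-shifted to zero
   at a 400 Å cutoff (the exponential is negligible there; Coulomb tail
   truncation is visible in the shift constant); optional Gaussian
   attraction −ε·exp(−(d−r0)²/2w²), defaults ε = 1 kcal/mol, r0 = 60 Å,
   w = 5 Å — a smooth, short-ranged, zero-at-infinity stand-in for the
   stacking contacts histone tails would provide.  The shifted-Coulomb
   singularity at d = B is continued linearly (constant force) below
   B + 0.5 Å and every clamped evaluation is counted, so a collapsing
   configuration fails observably instead of overflowing.  Integrator:
   BAOAB splitting; friction 1 ps⁻¹ and T = 303.15 K by default; with
   friction = T = 0 it reduces exactly to velocity Verlet (used by the
   energy-conservation test).  A stability pre-check refuses
   dt > 0.05/ν_bond for the fastest bond; with k = 0.01 kcal/mol/Å² and
   2e5 Da beads the default dt = 10 ps leaves >100 steps per bond period.
   Crash detection: any non-finite force/position or any bond beyond
   5× its rest length terminates the run with a crash record (step and
   reason), returning the trajectory up to failure.  Initial geometries:
   a regular N-gon with side = bond length, or a stacked two-start ring
   (two interleaved 50-bead stacks; in-stack neighbors i, i±2 at the
   60 Å stacking distance, bonded neighbors zigzag across at the bond
   length — 60 Å is the stacked-nucleosome crystal vicinity).  Velocities
   are Maxwell–Boltzmann with the net momentum removed.

## What the synthetic generator does and does not emulate

It reproduces exactly the statistical structure WHAM assumes: stationary,
Boltzmann-distributed, autocorrelated samples of a scalar coordinate
under reference + bias, with tunable correlation time.  It does not
emulate orientational coupling, slow conformational substates,
force-field error, or the solvent/box artifacts of real simulations
(e.g. periodic-image interactions at large d).  Passing recovery tests
therefore validates the *estimator and fitting chain*, not any claim
about real nucleosome thermodynamics.  Correlation times of the real
biased coordinate are unknown; the defaults give correlation times of
order 1 ps so that desk-scale runs hold thousands of effective samples.

## Numerical choices and degenerate inputs

- kB = 0.0019872041 kcal/mol/K; internal units kcal/mol, Å, ps, Da
  (1 kcal/mol = 418.4 Da·Å²/ps²); force constants in kJ/mol/Å² are
  divided by 4.184 on input.
- Euler–Maruyama has an O(dt) stationary-distribution bias: for an
  effective curvature κ the sampled variance is inflated by
  ≈ 1/(1 − θdt/2) with θ = Dκ/kBT.  At the defaults (θdt ≈ 0.1 for a
  5 kJ/mol/Å² bias) this is a ~5% variance effect, which WHAM largely
  forgives when window *positions* carry the information; calibration
  tests that assert variances directly use dt an order of magnitude
  smaller.
- BAOAB's kinetic temperature carries an O((ωdt)²) deficit; the
  configurational distribution is far more accurate.  Thermal-statistics
  runs use ωdt ≤ 0.1.
- Duplicate window centers are merged at 1e-6 Å; empty schedules, zero
  total weights, collinear clouds, non-finite references, biases outside
  the reference domain, and singular fit windows all raise typed errors.
- Histogram totals are conserved: out-of-range samples are counted and
  reported, never dropped silently; disconnected occupied support
  triggers a warning (the inter-island offset is not determined by data).
- The WHAM iteration's residual is monotone over its tail; non-convergence
  raises an error carrying the best iterate and residual.

## Problem sizes used by the shipped analyses

Recovery campaigns use 20 windows × 2e4 samples (harmonic well; ladder
204–246 Å chosen to extend one window beyond the ±20 Å basin that the
2 kcal/mol comparison region spans) and the full 68-window ladder ×
5e3 samples (repulsive wall).  The fiber contrast runs 100 beads for
1000 × 10 ps = 10 ns; thermal dimer statistics use 150k × 0.5 ps steps
with 100 Da beads (equilibrium statistics are mass independent; light
beads shorten the correlation time).

## Known limitations

- With the default ε = 1 kcal/mol the attraction well does not create a
  bound stacked state: the fitted repulsion is ~6.9 kcal/mol at the 60 Å
  stacking distance, so the net pair force remains outward and the
  stable-versus-unstable contrast is kinetic — the attraction run retains
  a strictly larger fraction of its initial stacked contacts over the
  10 ns observation window, but both runs lose contacts asymptotically.
  This is the physically expected behaviour of tail-less nucleosomes;
  a genuinely bound stack needs ε comparable to the contact repulsion.
- The anchoring gauge of an estimated profile is arbitrary; fits of
  forms without an additive constant inherit a systematic offset unless
  `with_offset` is used (essential for the slowly decaying shifted
  Coulomb, minor for the exponential).
- 2D (distance × angle) estimation, orientation-restrained protocols,
  and the stiffness/loop/permeability terms of full chromatin polymer
  Hamiltonians are out of scope; the CG model is isotropic, one bead per
  nucleosome.
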