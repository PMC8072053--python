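# chromocg

Bottom-up coarse-graining of nucleosome–nucleosome interactions: from
biased sampling of the inter-nucleosome distance, through WHAM estimation
of the potential of mean force (PMF), to fitted bead–bead potentials and
Langevin dynamics of a covalently closed nucleosome-bead chromatin fiber.

## The problem

Chromatin polymer models represent each nucleosome as one bead and need
effective pair potentials for (i) beads joined by linker DNA and (ii)
spatially stacked beads.  A bottom-up route derives both from free-energy
profiles F(d) along the inter-nucleosome center distance d, computed by
umbrella sampling: the Hamiltonian is biased per window with

    H_umb = H_0 + ½ k (d − d0)²,

a ladder of restraint centers d0 covers the range of interest, and the
weighted histogram analysis method (WHAM) combines the biased window
histograms into one unbiased profile by solving

    P(x_b) = Σ_i n_ib / Σ_i N_i exp[(f_i − w_i(x_b)) / kBT],
    f_i    = −kBT ln Σ_b P(x_b) exp[−w_i(x_b) / kBT],

with F(x_b) = −kBT ln P(x_b) anchored at its minimum.  Three potential
forms are then fitted: a harmonic bond ½k(d−d0)² for linked nucleosomes
(published parameters k = 0.01 kcal/mol/Å², d0 = 225 Å), and for the
repulsion between stacked, tail-less nucleosomes either an exponential
wall V(d) = exp(β − α·d) (α = 0.1213 Å⁻¹, β = 9.2086) or a shifted
Coulomb V(d) = A/(d − B) (A = 39.53 kcal·Å/mol, B = 52.82 Å).

Atomistic sampling at that scale is far beyond a desk machine, so this
package ships a synthetic-data module: overdamped Langevin sampling of a
1D coordinate on *known* reference landscapes shaped like the two
systems' profiles.  Because the generating function is known exactly, the
whole pipeline — window schedules, biased sampling, WHAM with bootstrap
errors, potential fits — is validated quantitatively, and the fitted
potentials then drive a 100-bead covalently closed ring fiber.

## Worked example

```python
import chromocg as c

# 20 umbrella windows across the harmonic well, 20k samples each
ref    = c.reference_pmf("LN-like")              # ½·0.01·(d−225)² kcal/mol
sched  = c.make_window_schedule((204, 246, 42/19), k_spec=5.0)   # k in kJ/mol/Å²
params = c.LangevinParams(seed=1101, n_steps=8000, save_stride=20,
                          n_chains=50, n_equil=2000)
trajs  = c.generate_campaign(ref, sched, params)

pmf = c.wham_solve(c.build_histograms(trajs, bin_width=0.5))
model, report = c.fit_harmonic(pmf)
print(report.summary())
```

prints

```
HarmonicModel: k=0.0096865, d0=224.678  [window 204.75-244.75 Å, n=81, RMS 0.02907 kcal/mol]
```

i.e. the generating curvature 0.01 kcal/mol/Å² and minimum 225 Å are
recovered within ~3% and ~0.3 Å, and the profile deviates < 0.05 kcal/mol
RMS from the truth — the whole estimation chain undoes the bias it added.

The numbered drivers under `analysis/` walk through the full study:
`01` builds the 127-window linked-nucleosome and 68-window stacked-
nucleosome ladders (5.85 µs of designed sampling at 30 ns/window);
`02`–`04` run both campaigns, estimate the PMFs and fit all three
potential forms; `05` contrasts paired 100-bead ring-fiber runs with and
without a weak stacking attraction (the bare repulsive model sheds its
stacked contacts — 13% retained after 10 ns versus 20% when a 1 kcal/mol
attraction well retards the loss).  Each writes its tables under
`results/`.

There is also a CLI:

```bash
chromocg windows --preset LN --out windows.manifest
chromocg simulate-synthetic --preset ULN --out campaign/ --seed 5
chromocg wham --manifest campaign/windows.manifest --boot 24 --seed 5 --out pmf.tsv
chromocg fit --pmf pmf.tsv --form exponential --window 55:90
chromocg pipeline --preset LN --out run/ --seed 3
```

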