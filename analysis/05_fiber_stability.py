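#!/usr/bin/env python
"""Stability of a 100-nucleosome covalently closed fiber under the fitted
potentials, with and without a tail-mimicking attraction.

The fiber starts as a stacked two-start ring (in-stack neighbors 60 Å
apart, bonded neighbors at the 225 Å bond rest length) and is propagated
with BAOAB Langevin dynamics at 303.15 K for 10 ns (1000 x 10 ps).  Under
the bare fitted potentials — harmonic bonds plus the purely repulsive
exponential wall — the stacked contacts disperse: without histone tails
nothing holds stacked nucleosomes together.  Adding a weak Gaussian
attraction well (1 kcal/mol at 60 Å) retards the loss; because the well
is shallower than the ~7 kcal/mol repulsion at contact it cannot arrest
it, so the contrast is kinetic, not thermodynamic.

Writes: results/fiber_observables_{bare,attraction}.tsv,
results/fiber_stability.tsv
"""

from pathlib import Path

import pandas as pd

import chromocg as c
from chromocg.io import write_observables

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SEED = 31
rows = []
for tag, attraction in (("bare", None), ("attraction", (1.0, 60.0, 5.0))):
    ff = c.ForceField(
        bond=c.HarmonicModel(k=0.01, d0=225.0),
        nonbonded=c.ExponentialModel(alpha=0.1213, beta=9.2086),
        attraction=attraction,
    )
    topo, state = c.build_ring_fiber(
        100, 225.0, "stacked-zigzag", seed=SEED, stack_distance=60.0
    )
    cfg = c.SimConfig(dt=10.0, n_steps=1000, save_stride=50, seed=SEED)
    traj = c.run_langevin(state, topo, ff, cfg)
    write_observables(OUT / f"fiber_observables_{tag}.tsv", traj)
    rep = c.stability_report(traj, topo, cfg)
    rows.append(
        {
            "model": tag,
            "crashed": rep.crashed,
            "contact_retention_pct": 100.0 * rep.initial_contact_retention,
            "contacts_start": rep.contact_counts[0],
            "contacts_end": rep.contact_counts[-1],
            "Rg_start_A": rep.rg_series[0],
            "Rg_end_A": rep.rg_series[-1],
            "mean_Tkin_K": rep.mean_kinetic_temperature,
        }
    )
    print(f"{tag:>10s}: {rep.summary()}")

df = pd.DataFrame(rows)
df.to_csv(OUT / "fiber_stability.tsv", sep="\t", index=False, float_format="%.6g")
bare, attr = df.iloc[0], df.iloc[1]
print(
    f"\ncontrast: attraction retains {attr.contact_retention_pct:.0f}% of initial "
    f"stacked contacts vs {bare.contact_retention_pct:.0f}% without, over the same "
    "10 ns from identical seeds"
)
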