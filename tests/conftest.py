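import numpy as np
import pytest

import chromocg as c

# ---------------------------------------------------------------------------
# Shared synthetic campaigns (session-scoped: they are the expensive inputs)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def ln_recovery_campaign():
    """Umbrella campaign on the harmonic (LN-like) reference landscape.

    20 windows spanning the well past the 2 kcal/mol region (centers
    204-246 Å), 2e4 samples per window at roughly one correlation time
    spacing — the conditions for quantitative landscape recovery.
    """
    ref = c.reference_pmf("LN-like")
    sched = c.make_window_schedule((204.0, 246.0, 42.0 / 19.0), k_spec=5.0, label="rec")
    params = c.LangevinParams(
        seed=1101, n_steps=8000, save_stride=20, n_chains=50, n_equil=2000
    )
    trajs = c.generate_campaign(ref, sched, params)
    return ref, sched, trajs


@pytest.fixture(scope="session")
def toy_campaign():
    """Small 5-window campaign on the same harmonic reference (oracle-sized)."""
    ref = c.reference_pmf("LN-like")
    # gentle 2 kJ/mol/A^2 bias: window width ~1.1 Å against 2.5 Å spacing
    # keeps adjacent overlap healthy, so the solvers converge briskly
    sched = c.make_window_schedule((220.0, 230.0, 2.5), k_spec=2.0, label="toy")
    params = c.LangevinParams(
        seed=77, n_steps=4000, save_stride=20, n_chains=10, n_equil=1000
    )
    return ref, sched, c.generate_campaign(ref, sched, params)


# ---------------------------------------------------------------------------
# Geometry fixtures
# ---------------------------------------------------------------------------


def ring_points(n=24, radius=42.0, plane="xy", center=(0.0, 0.0, 0.0), rng=None):
    """Points on a circle: a disc-like stand-in for the DNA superhelix."""
    t = 2 * np.pi * np.arange(n) / n
    x, y = radius * np.cos(t), radius * np.sin(t)
    z = np.zeros(n)
    if rng is not None:
        z = z + 0.5 * rng.standard_normal(n)  # slight pucker
    axes = {"xy": (x, y, z), "xz": (x, z, y), "yz": (z, x, y)}
    pts = np.stack(axes[plane], axis=1) + np.asarray(center)
    return c.PointSet(coords=pts)


@pytest.fixture
def disc_pair():
    return ring_points(plane="xy"), ring_points(plane="xy", center=(10.0, 5.0, 80.0))


# ---------------------------------------------------------------------------
# A minimal text PDB: 3 DNA phosphates + 3 Cα (chain A) + 2 Cα (chain B)
# ---------------------------------------------------------------------------

_PDB_ATOMS = [
    ("P", "DA", "A", 1, (10.0, 10.0, 10.0), "P"),
    ("P", "DA", "A", 2, (13.0, 14.0, 10.0), "P"),
    ("P", "DA", "A", 3, (16.0, 10.0, 10.0), "P"),
    ("CA", "ALA", "A", 4, (0.0, 0.0, 0.0), "C"),
    ("CA", "GLY", "A", 5, (3.0, 4.0, 0.0), "C"),
    ("CA", "SER", "A", 6, (6.0, 0.0, 0.0), "C"),
    ("CA", "LYS", "B", 1, (20.0, 20.0, 20.0), "C"),
    ("CA", "ARG", "B", 2, (24.0, 20.0, 20.0), "C"),
]


@pytest.fixture(scope="session")
def pdb_file(tmp_path_factory):
    lines = []
    for i, (name, res, chain, seq, (x, y, z), elem) in enumerate(_PDB_ATOMS, start=1):
        lines.append(
            f"ATOM  {i:5d} {name:^4s}{'':1s}{res:>3s} {chain:1s}{seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {elem:>2s}"
        )
    lines.append("END")
    path = tmp_path_factory.mktemp("pdb") / "dinucleosome_fragment.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
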