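"""Langevin dynamics of a covalently closed nucleosome-bead fiber.

One bead per nucleosome; beads i and (i+1) mod N are joined by the fitted
harmonic bond (an explicit ring in open space — dynamically equivalent to
a chain closed through periodic images for the bonded topology, and
simpler).  All non-bonded pairs interact through the fitted repulsion
(exponential wall or shifted Coulomb), optionally supplemented by a weak
Gaussian attraction well mimicking the stacking contacts that histone
tails would provide.  Integration uses the BAOAB splitting of Langevin
dynamics; with zero friction and temperature it reduces to velocity
Verlet.

The shifted-Coulomb form is singular at d = B; below B + 0.5 Å it is
continued linearly (constant force) and every such evaluation is counted,
so a collapsing fiber fails observably (crash record) instead of
overflowing silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB_KCAL, KCAL_TO_DA_A2_PS2
from .errors import ConfigurationError
from .potentials import ExponentialModel, HarmonicModel, ShiftedCoulombModel

__all__ = [
    "FiberTopology",
    "ForceField",
    "FiberState",
    "SimConfig",
    "FiberTrajectory",
    "StabilityReport",
    "build_ring_fiber",
    "total_energy",
    "forces",
    "run_langevin",
    "stability_report",
]

_COULOMB_CLAMP = 0.5  # Å above the singularity where linear continuation starts


@dataclass
class FiberTopology:
    """Ring of N beads: bonds (i, i+1 mod N), bonded pairs excluded from
    the non-bonded sum.  N = 2 is the degenerate dimer (one bond, no
    non-bonded pairs), useful for single-bond statistics."""

    n_beads: int

    def __post_init__(self):
        if self.n_beads < 2:
            raise ConfigurationError("a fiber needs at least 2 beads")
        n = self.n_beads
        if n == 2:
            self.bonds = np.array([[0, 1]])
            self.pairs_i = np.array([], dtype=int)
            self.pairs_j = np.array([], dtype=int)
            return
        self.bonds = np.stack([np.arange(n), (np.arange(n) + 1) % n], axis=1)
        iu, ju = np.triu_indices(n, k=1)
        sep = (ju - iu) % n
        nonbonded = (sep != 1) & (sep != n - 1)
        self.pairs_i = iu[nonbonded]
        self.pairs_j = ju[nonbonded]


@dataclass
class ForceField:
    """Bonded + non-bonded energy terms of the bead fiber.

    ``attraction`` is ``(epsilon, r0, w)``: a Gaussian well
    −ε·exp(−(d−r0)²/(2w²)) in kcal/mol, Å, Å, or None.  Non-bonded terms
    are energy-shifted to zero at ``cutoff``.
    """

    bond: HarmonicModel
    nonbonded: Union[ExponentialModel, ShiftedCoulombModel]
    attraction: Optional[tuple] = None
    cutoff: float = 400.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ConfigurationError("cutoff must be > 0")
        if self.attraction is not None:
            eps, r0, w = self.attraction
            if eps < 0 or w <= 0:
                raise ConfigurationError("attraction needs epsilon >= 0 and width > 0")
            if self.cutoff <= r0 + 3.0 * w:
                raise ConfigurationError("cutoff must exceed attraction center + 3 widths")

    # -- raw (unshifted) non-bonded repulsion with clamped singularity ------
    def _rep_raw(self, d):
        nb = self.nonbonded
        if isinstance(nb, ExponentialModel):
            v = nb(d)
            return v, -nb.alpha * v, np.zeros(d.shape, dtype=bool)
        c = nb.B + _COULOMB_CLAMP
        clamped = d <= c
        dd = np.where(clamped, c, d)
        v = nb.A / (dd - nb.B)
        dv = -nb.A / (dd - nb.B) ** 2
        # linear continuation below c: constant force, energy extrapolated
        v = np.where(clamped, v + (-dv) * (c - d), v)
        return v, dv, clamped

    def _attr_raw(self, d):
        if self.attraction is None:
            z = np.zeros_like(d)
            return z, z
        eps, r0, w = self.attraction
        g = np.exp(-((d - r0) ** 2) / (2.0 * w**2))
        v = -eps * g
        dv = eps * (d - r0) / w**2 * g
        return v, dv

    def nonbonded_terms(self, d):
        """(V_rep, V_attr, dV/dd, n_clamped) for pair distances d, with the
        cutoff shift applied and both terms zero beyond the cutoff."""
        d = np.asarray(d, dtype=float)
        cut = np.asarray([self.cutoff])
        v_rep, dv_rep, clamped = self._rep_raw(d)
        v_att, dv_att = self._attr_raw(d)
        rep_shift = self._rep_raw(cut)[0][0]
        att_shift = self._attr_raw(cut)[0][0]
        inside = d < self.cutoff
        v_rep = np.where(inside, v_rep - rep_shift, 0.0)
        v_att = np.where(inside, v_att - att_shift, 0.0)
        dv = np.where(inside, dv_rep + dv_att, 0.0)
        return v_rep, v_att, dv, int(np.count_nonzero(clamped & inside))


@dataclass
class FiberState:
    """Instantaneous mechanical state of the fiber."""

    positions: np.ndarray  # (N, 3) Å
    velocities: np.ndarray  # (N, 3) Å/ps
    masses: np.ndarray  # (N,) Da
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.array(self.positions, dtype=float)
        self.velocities = np.array(self.velocities, dtype=float)
        self.masses = np.array(self.masses, dtype=float)
        n = len(self.positions)
        if self.velocities.shape != (n, 3) or self.masses.shape != (n,):
            raise ConfigurationError("inconsistent state array shapes")

    def copy(self) -> "FiberState":
        return FiberState(
            self.positions.copy(), self.velocities.copy(), self.masses.copy(), self.time
        )

    def kinetic_energy(self) -> float:
        """Kinetic energy in kcal/mol."""
        ke_int = 0.5 * float(np.sum(self.masses[:, None] * self.velocities**2))
        return ke_int / KCAL_TO_DA_A2_PS2

    def kinetic_temperature(self) -> float:
        """Instantaneous temperature from equipartition over 3N dof, K."""
        ke_int = 0.5 * float(np.sum(self.masses[:, None] * self.velocities**2))
        kB_int = KB_KCAL * KCAL_TO_DA_A2_PS2
        return 2.0 * ke_int / (3.0 * len(self.masses) * kB_int)


@dataclass(frozen=True)
class SimConfig:
    """Langevin run configuration.

    friction in ps⁻¹ (0 gives the velocity-Verlet limit), dt in ps.
    ``bond_crash_factor``: any bond longer than this multiple of the bond
    rest length trips the crash detector, as does any non-finite value.
    """

    temperature: float = DEFAULT_TEMPERATURE
    friction: float = 1.0
    dt: float = 10.0
    n_steps: int = 10_000
    save_stride: int = 100
    seed: int = 0
    bond_crash_factor: float = 5.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.friction < 0:
            raise ConfigurationError("friction must be >= 0")
        if self.save_stride < 1 or self.n_steps < 1:
            raise ConfigurationError("need n_steps >= 1 and save_stride >= 1")


def build_ring_fiber(
    N: int,
    bond_length: float = 225.0,
    geometry: str = "circle",
    seed: int = 0,
    stack_distance: float = 60.0,
    temperature: float = DEFAULT_TEMPERATURE,
    mass: float = 2.0e5,
):
    """Initial topology and state of an N-bead covalently closed fiber.

    ``circle`` places beads at the vertices of a regular N-gon with side
    equal to ``bond_length`` (perimeter N·bond_length).  ``stacked-zigzag``
    builds a two-start ring: two concentric 50-bead-style stacks whose
    in-stack neighbors (beads i and i+2) sit ``stack_distance`` apart —
    the vicinity of the stacked-nucleosome crystal separation — while the
    bonded neighbors (i, i+1) zigzag between the stacks at ``bond_length``.
    Velocities are Maxwell–Boltzmann at ``temperature`` with total
    momentum zeroed.
    """
    topo = FiberTopology(N)
    if geometry == "circle":
        R = bond_length / (2.0 * math.sin(math.pi / N))
        ang = 2.0 * math.pi * np.arange(N) / N
        pos = np.stack([R * np.cos(ang), R * np.sin(ang), np.zeros(N)], axis=1)
    elif geometry == "stacked-zigzag":
        if N % 2 != 0:
            raise ConfigurationError("stacked-zigzag geometry needs an even bead count")
        half = N // 2
        R = stack_distance / (2.0 * math.sin(2.0 * math.pi / N))
        chord = 2.0 * R * math.sin(math.pi / N)  # half-step in-plane offset
        if bond_length <= chord:
            raise ConfigurationError(
                "bond length too short to close the zigzag; increase it or "
                "shrink the stacking distance"
            )
        h = math.sqrt(bond_length**2 - chord**2)
        idx = np.arange(N)
        ang = 2.0 * math.pi * (idx / 2.0) / half  # half-integer steps for odd beads
        z = np.where(idx % 2 == 0, 0.0, h)
        pos = np.stack([R * np.cos(ang), R * np.sin(ang), z], axis=1)
    else:
        raise ConfigurationError(f"unknown geometry {geometry!r}")

    # refuse overlapping starts
    diff = pos[:, None, :] - pos[None, :, :]
    dmat = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dmat, np.inf)
    if dmat.min() < 1.0:
        raise ConfigurationError("geometry places beads closer than 1 Å")

    masses = np.full(N, float(mass))
    rng = np.random.default_rng(seed)
    kB_int = KB_KCAL * KCAL_TO_DA_A2_PS2
    sigma_v = np.sqrt(kB_int * temperature / masses)
    vel = sigma_v[:, None] * rng.standard_normal((N, 3))
    vel -= (masses[:, None] * vel).sum(axis=0) / masses.sum()  # zero net momentum
    return topo, FiberState(positions=pos, velocities=vel, masses=masses)


def _bond_vectors(positions, topo):
    rij = positions[topo.bonds[:, 1]] - positions[topo.bonds[:, 0]]
    return rij, np.linalg.norm(rij, axis=1)


def total_energy(state: FiberState, topo: FiberTopology, ff: ForceField):
    """(bond, nonbonded-repulsion, attraction) energies in kcal/mol."""
    _, db = _bond_vectors(state.positions, topo)
    e_bond = float(np.sum(ff.bond(db)))
    rij = state.positions[topo.pairs_j] - state.positions[topo.pairs_i]
    d = np.linalg.norm(rij, axis=1)
    v_rep, v_att, _, _ = ff.nonbonded_terms(d)
    return e_bond, float(v_rep.sum()), float(v_att.sum())


def forces(state: FiberState, topo: FiberTopology, ff: ForceField):
    """Analytic forces, kcal/mol/Å; also returns the clamped-pair count."""
    pos = state.positions
    F = np.zeros_like(pos)

    rb, db = _bond_vectors(pos, topo)
    fb = -ff.bond.derivative(db)  # magnitude along the bond direction
    fvec = (fb / db)[:, None] * rb
    np.add.at(F, topo.bonds[:, 1], fvec)
    np.add.at(F, topo.bonds[:, 0], -fvec)

    rij = pos[topo.pairs_j] - pos[topo.pairs_i]
    d = np.linalg.norm(rij, axis=1)
    _, _, dv, n_clamped = ff.nonbonded_terms(d)
    fvec = (-dv / d)[:, None] * rij
    np.add.at(F, topo.pairs_j, fvec)
    np.add.at(F, topo.pairs_i, -fvec)
    return F, n_clamped


@dataclass
class CrashRecord:
    step: int
    reason: str


@dataclass
class FiberTrajectory:
    """Saved frames of a Langevin run plus per-frame observables."""

    times: np.ndarray
    positions: np.ndarray  # (n_frames, N, 3)
    e_bond: np.ndarray
    e_nonbonded: np.ndarray
    e_attraction: np.ndarray
    e_kinetic: np.ndarray
    kinetic_temperature: np.ndarray
    n_clamped: np.ndarray
    crash: Optional[CrashRecord]
    final_state: FiberState
    topology: FiberTopology = None
    forcefield: ForceField = None

    @property
    def n_frames(self):
        return len(self.times)

    def total_energy_series(self):
        return self.e_bond + self.e_nonbonded + self.e_attraction + self.e_kinetic

    def radius_of_gyration(self) -> np.ndarray:
        com = self.positions.mean(axis=1, keepdims=True)
        return np.sqrt(np.mean(np.sum((self.positions - com) ** 2, axis=2), axis=1))


def _max_stable_dt(ff: ForceField, masses: np.ndarray) -> float:
    """Refuse time steps beyond 0.05 of the fastest bond period."""
    k_int = ff.bond.k * KCAL_TO_DA_A2_PS2
    # reduced mass of a bonded pair; uniform masses -> m/2
    nu_max = math.sqrt(k_int / (masses.min() / 2.0)) / (2.0 * math.pi)  # ps^-1
    return 0.05 / nu_max


def run_langevin(
    state: FiberState, topo: FiberTopology, ff: ForceField, config: SimConfig
) -> FiberTrajectory:
    """BAOAB Langevin integration of the bead fiber.

    Frames (positions + energies + kinetic temperature) are saved every
    ``save_stride`` steps, including the initial frame.  A non-finite
    force or position, or any bond stretched beyond
    ``bond_crash_factor``·d0, terminates the run with a crash record; the
    trajectory up to the failure is returned, never an exception.
    """
    dt_max = _max_stable_dt(ff, state.masses)
    if config.dt > dt_max:
        raise ConfigurationError(
            f"dt = {config.dt} ps exceeds the stability bound {dt_max:.3g} ps "
            "for this bond stiffness and bead mass"
        )
    rng = np.random.default_rng(config.seed)
    s = state.copy()
    kB_int = KB_KCAL * KCAL_TO_DA_A2_PS2
    kT_int = kB_int * config.temperature
    m = s.masses[:, None]
    c1 = math.exp(-config.friction * config.dt)
    c2 = math.sqrt(max(0.0, (1.0 - c1**2)) * 1.0)
    sigma_v = np.sqrt(kT_int / m)
    dt = config.dt
    d0 = ff.bond.d0
    crash_len = config.bond_crash_factor * d0

    frames, times = [], []
    eb_l, enb_l, eat_l, ek_l, kt_l, ncl_l = [], [], [], [], [], []
    crash = None

    def record(step_clamped):
        eb, enb, eat = total_energy(s, topo, ff)
        frames.append(s.positions.copy())
        times.append(s.time)
        eb_l.append(eb)
        enb_l.append(enb)
        eat_l.append(eat)
        ek_l.append(s.kinetic_energy())
        kt_l.append(s.kinetic_temperature())
        ncl_l.append(step_clamped)

    F, n_cl = forces(s, topo, ff)
    F_int = F * KCAL_TO_DA_A2_PS2
    record(n_cl)
    for step in range(1, config.n_steps + 1):
        s.velocities += 0.5 * dt * F_int / m  # B
        s.positions += 0.5 * dt * s.velocities  # A
        if config.friction > 0 and config.temperature > 0:
            s.velocities = c1 * s.velocities + c2 * sigma_v * rng.standard_normal(
                s.velocities.shape
            )  # O
        elif config.friction > 0:
            s.velocities = c1 * s.velocities
        s.positions += 0.5 * dt * s.velocities  # A
        F, n_cl = forces(s, topo, ff)
        if not np.all(np.isfinite(F)) or not np.all(np.isfinite(s.positions)):
            crash = CrashRecord(step=step, reason="non-finite force or position")
            break
        F_int = F * KCAL_TO_DA_A2_PS2
        s.velocities += 0.5 * dt * F_int / m  # B
        s.time += dt
        _, db = _bond_vectors(s.positions, topo)
        if db.max() > crash_len:
            record(n_cl)
            crash = CrashRecord(
                step=step, reason=f"bond stretched beyond {config.bond_crash_factor}x d0"
            )
            break
        if step % config.save_stride == 0:
            record(n_cl)

    return FiberTrajectory(
        times=np.array(times),
        positions=np.array(frames),
        e_bond=np.array(eb_l),
        e_nonbonded=np.array(enb_l),
        e_attraction=np.array(eat_l),
        e_kinetic=np.array(ek_l),
        kinetic_temperature=np.array(kt_l),
        n_clamped=np.array(ncl_l),
        crash=crash,
        final_state=s,
        topology=topo,
        forcefield=ff,
    )


@dataclass
class StabilityReport:
    crashed: bool
    first_failure_step: Optional[int]
    max_bond_deviation: float
    rg_series: np.ndarray
    contact_counts: np.ndarray
    initial_contact_retention: float
    energy_drift: float
    mean_kinetic_temperature: float

    def summary(self) -> str:
        status = (
            f"CRASHED at step {self.first_failure_step}" if self.crashed else "stable"
        )
        return (
            f"{status}; max |d_bond - d0| = {self.max_bond_deviation:.2f} Å; "
            f"Rg {self.rg_series[0]:.1f} -> {self.rg_series[-1]:.1f} Å; "
            f"stacked contacts {self.contact_counts[0]} -> {self.contact_counts[-1]} "
            f"({100 * self.initial_contact_retention:.1f}% of initial pairs retained); "
            f"energy drift {self.energy_drift:.3g} kcal/mol; "
            f"<T_kin> = {self.mean_kinetic_temperature:.1f} K"
        )


def stability_report(
    traj: FiberTrajectory,
    topo: FiberTopology = None,
    config: SimConfig = None,
    contact_distance: float = 70.0,
) -> StabilityReport:
    """Diagnostics of a fiber run.

    Stacked contacts are non-bonded pairs within ``contact_distance``;
    ``initial_contact_retention`` is the fraction of the first frame's
    contact pairs still in contact at the final frame.  Energy drift is
    the change of total (kinetic + potential) energy between the first
    and last saved frames.
    """
    if traj.n_frames < 2:
        raise ConfigurationError("stability report needs >= 2 frames")
    topo = topo or traj.topology
    ff = traj.forcefield

    def pair_dists(frame):
        rij = frame[topo.pairs_j] - frame[topo.pairs_i]
        return np.linalg.norm(rij, axis=1)

    contact_counts = np.array(
        [int(np.count_nonzero(pair_dists(f) < contact_distance)) for f in traj.positions]
    )
    initial = pair_dists(traj.positions[0]) < contact_distance
    if initial.any():
        final = pair_dists(traj.positions[-1]) < contact_distance
        retention = float(np.count_nonzero(initial & final) / np.count_nonzero(initial))
    else:
        retention = float("nan")

    max_dev = 0.0
    if ff is not None:
        for f in traj.positions:
            rb = f[topo.bonds[:, 1]] - f[topo.bonds[:, 0]]
            db = np.linalg.norm(rb, axis=1)
            max_dev = max(max_dev, float(np.max(np.abs(db - ff.bond.d0))))

    etot = traj.total_energy_series()
    return StabilityReport(
        crashed=traj.crash is not None,
        first_failure_step=traj.crash.step if traj.crash else None,
        max_bond_deviation=max_dev,
        rg_series=traj.radius_of_gyration(),
        contact_counts=contact_counts,
        initial_contact_retention=retention,
        energy_drift=float(etot[-1] - etot[0]),
        mean_kinetic_temperature=float(traj.kinetic_temperature.mean()),
    )
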