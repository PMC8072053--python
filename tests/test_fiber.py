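import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import chromocg as c
from chromocg.constants import KB_KCAL
from chromocg.errors import ConfigurationError
from chromocg.fiber import FiberState, FiberTopology, forces

BOND = c.HarmonicModel(k=0.01, d0=225.0)
REPULSION = c.ExponentialModel(alpha=0.1213, beta=9.2086)
T = 303.15


def dimer(separation=225.0, mass=100.0):
    topo = FiberTopology(2)
    state = FiberState(
        positions=np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]]),
        velocities=np.zeros((2, 3)),
        masses=np.full(2, mass),
    )
    return topo, state


class TestRingConstruction:
    def test_circle_bond_lengths_exact(self):
        topo, state = c.build_ring_fiber(100, 225.0, "circle", seed=0)
        db = np.linalg.norm(
            state.positions[topo.bonds[:, 1]] - state.positions[topo.bonds[:, 0]], axis=1
        )
        assert db.shape == (100,)
        assert np.all(np.abs(db - 225.0) < 1e-6)

    def test_ring_closure(self):
        topo, _ = c.build_ring_fiber(100, 225.0, "circle", seed=0)
        assert [99, 0] in topo.bonds.tolist() or [0, 99] in topo.bonds.tolist()

    def test_total_momentum_zeroed(self):
        _, state = c.build_ring_fiber(64, 225.0, "circle", seed=3)
        p = (state.masses[:, None] * state.velocities).sum(axis=0)
        assert np.allclose(p, 0.0, atol=1e-9)

    def test_zigzag_stacking_and_bonds(self):
        topo, state = c.build_ring_fiber(
            100, 225.0, "stacked-zigzag", seed=0, stack_distance=60.0
        )
        db = np.linalg.norm(
            state.positions[topo.bonds[:, 1]] - state.positions[topo.bonds[:, 0]], axis=1
        )
        assert np.all(np.abs(db - 225.0) < 1e-6)
        # in-stack neighbors (i, i+2) sit at the stacking distance
        d2 = np.linalg.norm(
            state.positions[(np.arange(100) + 2) % 100] - state.positions, axis=1
        )
        assert np.all(np.abs(d2 - 60.0) < 1e-6)

    def test_overlapping_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            c.build_ring_fiber(100, 0.5, "circle", seed=0)

    def test_odd_zigzag_rejected(self):
        with pytest.raises(ConfigurationError):
            c.build_ring_fiber(99, 225.0, "stacked-zigzag", seed=0)


class TestEnergiesAndForces:
    def test_dimer_at_rest_length_zero_energy(self):
        topo, state = dimer(225.0)
        ff = c.ForceField(bond=BOND, nonbonded=REPULSION)
        eb, enb, eat = c.total_energy(state, topo, ff)
        assert eb == pytest.approx(0.0, abs=1e-12)
        assert enb == 0.0 and eat == 0.0  # bonded pair is excluded

    def test_equilateral_triangle_hand_oracle(self):
        """Three beads at mutual distance d0: bond energy 0; with the bonded
        exclusions lifted, the repulsion sums to 3·exp(beta - alpha·d0)."""
        d0 = 225.0
        topo = FiberTopology(3)
        # lift exclusions: all three pairs interact non-bonded
        topo.pairs_i = np.array([0, 0, 1])
        topo.pairs_j = np.array([1, 2, 2])
        h = d0 * np.sqrt(3.0) / 2.0
        state = FiberState(
            positions=np.array([[0.0, 0.0, 0.0], [d0, 0.0, 0.0], [d0 / 2.0, h, 0.0]]),
            velocities=np.zeros((3, 3)),
            masses=np.full(3, 1.0),
        )
        ff = c.ForceField(bond=BOND, nonbonded=REPULSION)
        eb, enb, _ = c.total_energy(state, topo, ff)
        hand = 3.0 * np.exp(9.2086 - 0.1213 * d0)
        assert eb == pytest.approx(0.0, abs=1e-12)
        assert enb == pytest.approx(hand, rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_isometry_invariance(self, seed):
        topo, state = c.build_ring_fiber(20, 225.0, "circle", seed=seed)
        rng = np.random.default_rng(seed)
        state.positions += 10.0 * rng.standard_normal(state.positions.shape)
        ff = c.ForceField(bond=BOND, nonbonded=REPULSION, attraction=(1.0, 60.0, 5.0))
        e0 = c.total_energy(state, topo, ff)
        rot = Rotation.random(rng=np.random.default_rng(seed + 7))
        moved = state.copy()
        moved.positions = rot.apply(state.positions) + np.array([100.0, -50.0, 3.0])
        e1 = c.total_energy(moved, topo, ff)
        assert e1 == pytest.approx(e0, rel=1e-9)

    @pytest.mark.parametrize(
        "nonbonded",
        [REPULSION, c.ShiftedCoulombModel(A=39.53, B=52.82)],
        ids=["exponential", "shifted-coulomb"],
    )
    def test_forces_match_finite_differences(self, nonbonded):
        topo, state = c.build_ring_fiber(
            16, 225.0, "stacked-zigzag", seed=2, stack_distance=60.0
        )
        rng = np.random.default_rng(5)
        state.positions += 2.0 * rng.standard_normal(state.positions.shape)
        ff = c.ForceField(bond=BOND, nonbonded=nonbonded, attraction=(1.0, 60.0, 5.0))
        F, _ = forces(state, topo, ff)
        h = 1e-5
        for _ in range(8):
            i, ax = rng.integers(16), rng.integers(3)
            sp, sm = state.copy(), state.copy()
            sp.positions[i, ax] += h
            sm.positions[i, ax] -= h
            fd = -(sum(c.total_energy(sp, topo, ff)) - sum(c.total_energy(sm, topo, ff))) / (
                2 * h
            )
            assert F[i, ax] == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_coulomb_singularity_clamped_not_overflowing(self):
        nb = c.ShiftedCoulombModel(A=39.53, B=52.82)
        topo, state = dimer(225.0)
        topo.pairs_i, topo.pairs_j = np.array([0]), np.array([1])  # force a nb pair
        state.positions[1, 0] = 52.0  # inside the singular region
        ff = c.ForceField(bond=BOND, nonbonded=nb)
        F, n_clamped = forces(state, topo, ff)
        assert np.all(np.isfinite(F)) and n_clamped == 1


class TestLangevinIntegration:
    def test_energy_conservation_zero_friction(self):
        """friction = 0, T = 0 reduces to velocity Verlet: total energy drift
        over 1e4 steps below 1e-3 of the initial potential energy."""
        topo, state = c.build_ring_fiber(12, 225.0, "circle", seed=0)
        rng = np.random.default_rng(1)
        state.positions += 5.0 * rng.standard_normal(state.positions.shape)
        state.velocities[:] = 0.0
        ff = c.ForceField(bond=BOND, nonbonded=REPULSION)
        cfg = c.SimConfig(
            temperature=0.0, friction=0.0, dt=5.0, n_steps=10_000, save_stride=500, seed=0
        )
        traj = c.run_langevin(state, topo, ff, cfg)
        et = traj.total_energy_series()
        pe0 = traj.e_bond[0] + traj.e_nonbonded[0] + traj.e_attraction[0]
        assert abs(et[-1] - et[0]) < 1e-3 * abs(pe0)

    def test_stationary_at_energy_minimum(self):
        topo, state = dimer(225.0)
        ff = c.ForceField(bond=BOND, nonbonded=REPULSION)
        cfg = c.SimConfig(temperature=0.0, friction=1.0, dt=1.0, n_steps=500,
                          save_stride=50, seed=0)
        traj = c.run_langevin(state, topo, ff, cfg)
        assert np.allclose(traj.positions[-1], traj.positions[0], atol=1e-10)

    def test_same_seed_identical_trajectories(self):
        topo, state = c.build_ring_fiber(10, 225.0, "circle", seed=4)
        ff = c.ForceField(bond=BOND, nonbonded=REPULSION)
        cfg = c.SimConfig(dt=5.0, n_steps=200, save_stride=20, seed=9)
        t1 = c.run_langevin(state.copy(), topo, ff, cfg)
        t2 = c.run_langevin(state.copy(), topo, ff, cfg)
        assert np.array_equal(t1.positions, t2.positions)

    def test_unstable_dt_refused(self):
        topo, state = dimer(225.0, mass=1.0)  # light beads: fast bond
        ff = c.ForceField(bond=BOND, nonbonded=REPULSION)
        with pytest.raises(ConfigurationError):
            c.run_langevin(state, topo, ff, c.SimConfig(dt=10.0, n_steps=10, seed=0))

    def test_bond_crash_detected_with_step_index(self):
        topo, state = dimer(225.0)
        state.velocities[1, 0] = 50.0  # flying apart far faster than thermal
        ff = c.ForceField(bond=c.HarmonicModel(k=1e-6, d0=225.0), nonbonded=REPULSION)
        cfg = c.SimConfig(
            temperature=0.0, friction=0.0, dt=1.0, n_steps=500, save_stride=50,
            seed=0, bond_crash_factor=1.5,
        )
        traj = c.run_langevin(state, topo, ff, cfg)
        assert traj.crash is not None
        # 0.5 * d0 = 112.5 Å of stretch at 50 Å/ps -> trips within ~3 steps
        assert 1 <= traj.crash.step <= 5
        rep = c.stability_report(traj, topo, cfg)
        assert rep.crashed and rep.first_failure_step == traj.crash.step


class TestThermalStatistics:
    @pytest.fixture(scope="class")
    def thermal_dimer_run(self):
        topo, state = dimer(225.0, mass=100.0)
        ff = c.ForceField(bond=BOND, nonbonded=REPULSION)
        cfg = c.SimConfig(
            temperature=T, friction=1.0, dt=0.5, n_steps=150_000, save_stride=15, seed=14
        )
        return c.run_langevin(state, topo, ff, cfg)

    def test_bond_length_variance_matches_equipartition(self, thermal_dimer_run):
        """After removing the d² shell Jacobian, the bond-length variance of
        a thermal harmonic dimer is kBT/k."""
        traj = thermal_dimer_run
        db = np.linalg.norm(traj.positions[:, 1] - traj.positions[:, 0], axis=1)
        db = db[len(db) // 10 :]  # discard equilibration
        w = 1.0 / db**2
        w /= w.sum()
        mu = np.sum(w * db)
        var = np.sum(w * (db - mu) ** 2)
        assert var == pytest.approx(KB_KCAL * T / BOND.k, rel=0.05)

    def test_kinetic_temperature_matches_thermostat(self, thermal_dimer_run):
        traj = thermal_dimer_run
        t_kin = traj.kinetic_temperature[len(traj.kinetic_temperature) // 10 :]
        assert t_kin.mean() == pytest.approx(T, rel=0.02)


class TestStabilityDiagnostics:
    def test_stationary_trajectory_clean_report(self):
        topo, state = dimer(225.0)
        ff = c.ForceField(bond=BOND, nonbonded=REPULSION)
        cfg = c.SimConfig(temperature=0.0, friction=1.0, dt=1.0, n_steps=100,
                          save_stride=10, seed=0)
        rep = c.stability_report(c.run_langevin(state, topo, ff, cfg), topo, cfg)
        assert not rep.crashed
        assert rep.energy_drift == pytest.approx(0.0, abs=1e-9)

    def test_attraction_preserves_stacked_contacts(self):
        """Paired ring runs from the stacked two-start start, identical
        seeds: the run with the attraction well keeps a strictly larger
        fraction of the initial stacked contacts than the bare-repulsion
        run, which sheds them."""
        results = {}
        for eps in (0.0, 1.0):
            attraction = (eps, 60.0, 5.0) if eps > 0 else None
            ff = c.ForceField(bond=BOND, nonbonded=REPULSION, attraction=attraction)
            topo, state = c.build_ring_fiber(100, 225.0, "stacked-zigzag", seed=8)
            cfg = c.SimConfig(dt=10.0, n_steps=1000, save_stride=100, seed=8)
            traj = c.run_langevin(state, topo, ff, cfg)
            results[eps] = c.stability_report(traj, topo, cfg)
        assert not results[1.0].crashed and not results[0.0].crashed
        assert results[0.0].initial_contact_retention < 1.0  # bare repulsion sheds
        assert (
            results[1.0].initial_contact_retention
            > results[0.0].initial_contact_retention
        )
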