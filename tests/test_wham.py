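import numpy as np
import pytest

import chromocg as c
from chromocg.constants import kBT
from chromocg.errors import ConfigurationError, ConvergenceError, EmptyAnalysisError
from chromocg.wham import adjacent_overlap_report

from ._mbar_oracle import mbar_pmf

T = 303.15


def make_traj(samples, d0=100.0, k=0.0, window_id="w", offset=0.0):
    return c.BiasedTrajectory(
        window_id=window_id, bias=c.BiasSpec(d0=d0, k=k, offset=offset), samples=samples
    )


class TestHistograms:
    def test_identical_values_fill_one_bin(self):
        h = c.build_histograms([make_traj(np.full(100, 50.0))], bin_width=0.5, range=(49, 51))
        assert h.counts.max() == 100 and h.counts.sum() == 100

    def test_count_conservation_with_out_of_range(self):
        samples = np.array([1.0, 2.0, 3.0, 100.0])
        h = c.build_histograms([make_traj(samples)], bin_width=0.5, range=(0.0, 5.0))
        assert h.n_samples[0] + h.n_out_of_range[0] == 4
        assert h.n_out_of_range[0] == 1

    def test_halving_bin_width_preserves_totals(self):
        rng = np.random.default_rng(0)
        trajs = [make_traj(rng.uniform(10, 20, 500))]
        h1 = c.build_histograms(trajs, bin_width=1.0, range=(10, 20))
        h2 = c.build_histograms(trajs, bin_width=0.5, range=(10, 20))
        assert h1.counts.sum() == h2.counts.sum() == 500

    def test_all_out_of_range_rejected(self):
        with pytest.raises(EmptyAnalysisError):
            c.build_histograms([make_traj(np.full(5, 99.0))], range=(0.0, 1.0))


class TestWhamSolve:
    def test_single_unbiased_window_is_boltzmann_inversion(self):
        """With one window and no bias, WHAM must reduce to
        F = -kBT ln(normalized counts), anchored at zero."""
        rng = np.random.default_rng(1)
        samples = rng.normal(100.0, 2.0, 20_000)
        h = c.build_histograms([make_traj(samples)], bin_width=0.5)
        pmf = c.wham_solve(h, T=T)
        counts = h.counts[0][pmf.occupied]
        direct = -kBT(T) * np.log(counts / counts.sum())
        direct -= direct.min()
        assert np.allclose(pmf.F[pmf.occupied], direct, atol=1e-10)

    def test_gauge_invariance_under_bias_offset(self):
        """Adding a constant to one window's bias energies shifts that
        window's free energy but leaves the profile untouched."""
        rng = np.random.default_rng(2)
        trajs, trajs_off = [], []
        for i, d0 in enumerate((95.0, 100.0, 105.0)):
            s = rng.normal(d0, 2.0, 5000)
            trajs.append(make_traj(s, d0=d0, k=0.15, window_id=f"w{i}"))
            off = 3.7 if i == 1 else 0.0
            trajs_off.append(make_traj(s, d0=d0, k=0.15, window_id=f"w{i}", offset=off))
        kwargs = dict(bin_width=0.5, range=(85.0, 115.0))
        p1 = c.wham_solve(c.build_histograms(trajs, **kwargs), T=T)
        p2 = c.wham_solve(c.build_histograms(trajs_off, **kwargs), T=T)
        assert np.allclose(p1.F[p1.occupied], p2.F[p2.occupied], atol=1e-6)
        assert p2.meta["f"][1] - p1.meta["f"][1] == pytest.approx(3.7, abs=1e-6)

    def test_flat_reference_recovered_flat(self, toy_campaign):
        """Two heavily overlapping windows on a flat landscape give a flat
        profile within twice the bootstrap uncertainty."""
        ref = c.reference_pmf("flat")
        params = c.LangevinParams(seed=12, n_steps=5000, save_stride=10, n_chains=10)
        trajs = [
            c.sample_biased_trajectory(
                ref, c.BiasSpec.from_kj(500.0 + sh, 2.0), params, window_id=f"f{sh}"
            )
            for sh in (0.0, 1.0)
        ]
        pmf = c.bootstrap_pmf(trajs, T=T, n_boot=24, seed=5)
        occ = pmf.occupied & np.isfinite(pmf.F_err) & (pmf.F_err > 0)
        # drop sparse edge bins: keep the central 90% of probability mass
        h = c.build_histograms(trajs, bin_width=0.5)
        dense = h.counts.sum(axis=0) > 0.005 * h.counts.sum()
        occ &= dense
        resid = pmf.F[occ] - pmf.F[occ].mean()
        assert np.all(np.abs(resid) < 2.0 * np.maximum(pmf.F_err[occ], 0.05))

    def test_residual_monotone_over_final_iterations(self, toy_campaign):
        _, _, trajs = toy_campaign
        pmf = c.wham_solve(c.build_histograms(trajs, bin_width=0.5), T=T)
        hist = np.asarray(pmf.meta["residual_history"][-10:])
        assert np.all(np.diff(hist) <= 1e-15)

    def test_nonconvergence_signals_with_best_iterate(self, toy_campaign):
        _, _, trajs = toy_campaign
        h = c.build_histograms(trajs, bin_width=0.5)
        with pytest.raises(ConvergenceError) as exc:
            c.wham_solve(h, T=T, tol=1e-14, max_iter=5)
        assert exc.value.result is not None
        assert exc.value.residual > 0

    def test_misaligned_biases_rejected(self, toy_campaign):
        _, _, trajs = toy_campaign
        h = c.build_histograms(trajs, bin_width=0.5)
        with pytest.raises(ConfigurationError):
            c.wham_solve(h, biases=list(h.biases)[:-1], T=T)

    def test_agrees_with_mbar_oracle(self, toy_campaign):
        """Binned WHAM and sample-wise MBAR are different estimators of the
        same profile; on a small campaign they must agree within the
        statistical uncertainty of either."""
        _, _, trajs = toy_campaign
        h = c.build_histograms(trajs, bin_width=0.5)
        pmf = c.bootstrap_pmf(trajs, T=T, n_boot=24, seed=9)
        F_ref = mbar_pmf(trajs, T, h.edges)
        occ = pmf.occupied & np.isfinite(F_ref) & np.isfinite(pmf.F_err)
        diff = pmf.F[occ] - F_ref[occ]
        diff -= diff.mean()  # common anchor gauge
        sigma = np.sqrt(np.mean(pmf.F_err[occ] ** 2))
        assert np.sqrt(np.mean(diff**2)) < 2.0 * sigma


class TestBootstrap:
    def test_fixed_seed_reproducible(self, toy_campaign):
        _, _, trajs = toy_campaign
        p1 = c.bootstrap_pmf(trajs, T=T, n_boot=8, seed=13)
        p2 = c.bootstrap_pmf(trajs, T=T, n_boot=8, seed=13)
        assert np.array_equal(p1.F_err, p2.F_err, equal_nan=True)

    def test_degenerate_windows_have_zero_uncertainty(self):
        trajs = [
            make_traj(np.full(200, 100.0), d0=100.0, k=1.0, window_id="a"),
            make_traj(np.full(200, 100.2), d0=100.2, k=1.0, window_id="b"),
        ]
        pmf = c.bootstrap_pmf(trajs, T=T, n_boot=8, seed=0, hist_range=(99.9, 100.4))
        occ = pmf.occupied & np.isfinite(pmf.F_err)
        assert np.all(pmf.F_err[occ] < 1e-12)

    def test_uncertainty_shrinks_with_more_samples(self):
        """Quadrupling every window's sample count shrinks the mean
        bootstrap uncertainty over the well-sampled region (~2x for
        independent samples); averaged over seeds to tame run-to-run noise."""
        ref = c.reference_pmf("LN-like")
        sched = c.make_window_schedule((220.0, 230.0, 2.5), k_spec=2.0, label="s")
        rng_range = (217.0, 233.0)

        def mean_err(n_steps, seed):
            params = c.LangevinParams(
                seed=seed, n_steps=n_steps, save_stride=20, n_chains=10
            )
            trajs = c.generate_campaign(ref, sched, params)
            pmf = c.bootstrap_pmf(
                trajs, T=T, n_boot=16, seed=seed, hist_range=rng_range
            )
            h = c.build_histograms(trajs, bin_width=0.5, range=rng_range)
            dense = h.counts.sum(axis=0) >= 0.01 * h.counts.sum(axis=0).max()
            sel = pmf.occupied & dense & np.isfinite(pmf.F_err)
            return np.mean(pmf.F_err[sel])

        small = np.mean([mean_err(2000, s) for s in (20, 22, 24)])
        big = np.mean([mean_err(8000, s) for s in (21, 23, 25)])
        assert big < small

    def test_requires_at_least_two_replicates(self, toy_campaign):
        _, _, trajs = toy_campaign
        with pytest.raises(ConfigurationError):
            c.bootstrap_pmf(trajs, T=T, n_boot=1, seed=0)


class TestStatisticalInefficiency:
    def test_white_noise_is_near_one(self):
        x = np.random.default_rng(0).standard_normal(20_000)
        assert c.statistical_inefficiency(x) == pytest.approx(1.0, abs=0.15)

    def test_correlated_series_exceeds_one(self):
        rng = np.random.default_rng(1)
        x = np.empty(20_000)
        x[0] = 0.0
        phi = 0.9  # AR(1): g = (1+phi)/(1-phi) = 19
        for i in range(1, len(x)):
            x[i] = phi * x[i - 1] + rng.standard_normal()
        g = c.statistical_inefficiency(x)
        assert 10.0 < g < 30.0

    def test_constant_series_returns_one(self):
        assert c.statistical_inefficiency(np.full(100, 3.0)) == 1.0


class TestOverlap:
    def test_identical_histograms_overlap_one(self):
        t = make_traj(np.random.default_rng(0).normal(100, 2, 1000))
        t2 = c.BiasedTrajectory(window_id="v", bias=t.bias, samples=t.samples.copy())
        O = c.overlap_matrix(c.build_histograms([t, t2], bin_width=0.5))
        assert O[0, 1] == pytest.approx(1.0)

    def test_disjoint_supports_overlap_zero(self):
        trajs = [
            make_traj(np.random.default_rng(0).normal(50, 0.5, 500), window_id="a"),
            make_traj(np.random.default_rng(1).normal(90, 0.5, 500), window_id="b"),
        ]
        O = c.overlap_matrix(c.build_histograms(trajs, bin_width=0.5))
        assert O[0, 1] == 0.0

    def test_symmetry_and_bounds(self, toy_campaign):
        _, _, trajs = toy_campaign
        O = c.overlap_matrix(c.build_histograms(trajs, bin_width=0.5))
        assert np.allclose(O, O.T)
        assert np.all((O >= 0) & (O <= 1 + 1e-12))
        assert np.allclose(np.diag(O), 1.0)

    def test_adjacent_report_flags_gaps(self):
        trajs = [
            make_traj(np.random.default_rng(0).normal(50, 0.5, 500), d0=50, window_id="a"),
            make_traj(np.random.default_rng(1).normal(90, 0.5, 500), d0=90, window_id="b"),
        ]
        _, overlaps, flagged = adjacent_overlap_report(
            c.build_histograms(trajs, bin_width=0.5)
        )
        assert flagged.all() and overlaps[0] == 0.0


class TestJacobianCorrection:
    def test_none_is_identity(self, toy_campaign):
        _, _, trajs = toy_campaign
        pmf = c.wham_solve(c.build_histograms(trajs, bin_width=0.5), T=T)
        assert c.jacobian_correction(pmf, "none") is pmf

    def test_radial_round_trip(self):
        centers = np.linspace(50.0, 100.0, 101)
        F = 0.01 * (centers - 75.0) ** 2
        pmf = c.PMFProfile(centers=centers, F=F, temperature=T)
        corrected = c.jacobian_correction(pmf, "radial")
        back = corrected.F - 2.0 * kBT(T) * np.log(centers)
        back -= back.min()
        assert np.allclose(back, F - F.min(), atol=1e-10)

    def test_flat_profile_gains_logarithmic_term(self):
        centers = np.linspace(50.0, 100.0, 101)
        pmf = c.PMFProfile(centers=centers, F=np.zeros_like(centers), temperature=T)
        out = c.jacobian_correction(pmf, "radial")
        expected = 2.0 * kBT(T) * np.log(centers / centers[0])
        assert np.allclose(out.F, expected, atol=1e-12)
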