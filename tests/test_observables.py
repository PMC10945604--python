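import numpy as np
import pytest

from softcells import (
    CellPopulation,
    CorrelationSeries,
    RadiusDistributionSpec,
    SimParams,
    TrajectoryStore,
    first_peak_position,
    log_tau_histogram,
    make_fixture,
    overlap_distribution,
    pair_correlation,
    per_cell_relaxation_times,
    relaxation_time,
    run_simulation,
    self_intermediate_scattering,
    waiting_time_fs,
)
from softcells.observables import INV_E, RadialDistribution


def _static_traj(pop: CellPopulation, n_frames: int = 5) -> TrajectoryStore:
    frames = np.repeat(pop.positions[None, :, :], n_frames, axis=0)
    return TrajectoryStore(
        frame_times=np.arange(n_frames) * 10.0,
        positions_unwrapped=frames,
        radii=pop.radii,
        box_length=pop.box_length,
    )


class TestPairCorrelation:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(0)
        L, N, F = 100.0, 400, 30
        frames = rng.uniform(0, L, size=(F, N, 2))
        traj = TrajectoryStore(
            frame_times=np.arange(F) * 10.0,
            positions_unwrapped=frames,
            radii=np.full(N, 1.0),
            box_length=L,
        )
        g = pair_correlation(traj, bin_width=1.0)
        interior = g.g[(g.r > 5) & (g.r < 45)]
        assert abs(interior.mean() - 1.0) < 0.01
        assert interior.std() < 0.05

    def test_two_particles_fixed_separation_analytic_weight(self):
        # a single pair at distance d: the only occupied bin must carry
        # g = 2 / (N rho * shell area) with N=2
        L, d = 50.0, 7.3
        pop = CellPopulation(
            radii=np.array([1.0, 1.0]),
            positions=np.array([[10.0, 10.0], [10.0 + d, 10.0]]),
            box_length=L,
        )
        traj = _static_traj(pop, n_frames=9)
        bw = 0.5
        g = pair_correlation(traj, bin_width=bw)
        k = int(d / bw)
        shell = np.pi * (((k + 1) * bw) ** 2 - (k * bw) ** 2)
        expected = 2.0 / (2 * (2 / L**2) * shell)
        assert g.g[k] == pytest.approx(expected, rel=1e-12)
        others = np.delete(g.g, k)
        assert np.all(others == 0)

    def test_count_sum_rule_random_configurations(self):
        # rho * integral g(r) 2 pi r dr over [0, r_max] ~ mean neighbours
        rng = np.random.default_rng(3)
        L, N, F = 80.0, 300, 10
        frames = rng.uniform(0, L, size=(F, N, 2))
        traj = TrajectoryStore(
            frame_times=np.arange(F) * 10.0,
            positions_unwrapped=frames,
            radii=np.full(N, 1.0),
            box_length=L,
        )
        g = pair_correlation(traj, bin_width=0.5, r_max=30.0)
        rho = N / L**2
        integral = rho * np.sum(g.g * 2 * np.pi * g.r * g.bin_width)
        expected = (N - 1) * (np.pi * 30.0**2) / L**2
        assert integral == pytest.approx(expected, rel=0.02)

    def test_invalid_inputs(self, pair_h1):
        traj = _static_traj(pair_h1)
        with pytest.raises(ValueError):
            pair_correlation(traj, bin_width=0.0)
        with pytest.raises(ValueError):
            pair_correlation(traj, r_max=pair_h1.box_length)


class TestFirstPeak:
    def test_single_bin_spike(self):
        g = RadialDistribution(
            r=np.arange(0.25, 10, 0.5),
            g=np.eye(1, 20, 7).ravel() * 5.0,
            bin_width=0.5,
        )
        assert first_peak_position(g) == pytest.approx(g.r[7])

    def test_analytic_unimodal_profile(self):
        r = np.arange(0.25, 30, 0.5)
        g = RadialDistribution(
            r=r, g=np.exp(-((r - 17.0) ** 2) / 8.0), bin_width=0.5
        )
        assert first_peak_position(g) == pytest.approx(17.0, abs=0.25)

    def test_no_peak_raises(self):
        g = RadialDistribution(
            r=np.arange(0.5, 10, 1.0), g=np.linspace(0, 1, 10), bin_width=1.0
        )
        with pytest.raises(ValueError):
            first_peak_position(g)


class TestSelfIntermediateScattering:
    def test_unity_at_zero_and_frozen(self, lattice16):
        traj = _static_traj(lattice16, n_frames=20)
        fs = self_intermediate_scattering(traj, q=0.37)
        assert fs.value[0] == 1.0
        np.testing.assert_allclose(fs.value, 1.0)

    def test_gaussian_displacements_closed_form(self):
        # sigma^2(t) = 0.25 * (t / 10 s): Fs must equal exp(-q^2 sigma^2/2)
        traj = make_fixture("gauss_traj")
        q = 0.35
        fs = self_intermediate_scattering(traj, q, max_origins=400)
        sigma2 = 0.25 * fs.t / 10.0
        expected = np.exp(-(q**2) * sigma2 / 2.0)
        np.testing.assert_allclose(fs.value, expected, atol=0.02)

    def test_bounded_by_one(self):
        traj = make_fixture("gauss_traj")
        fs = self_intermediate_scattering(traj, q=1.1)
        assert np.all(np.abs(fs.value) <= 1.0 + 1e-12)

    def test_uses_unwrapped_not_wrapped_coordinates(self):
        # free diffusion across the periodic boundary must keep decaying;
        # recomputing from wrapped coordinates saturates instead
        traj = make_fixture("gauss_traj")
        q = 0.2  # q L small: wrapped |dr| <= L/sqrt(2) keeps J0 positive
        wrapped = TrajectoryStore(
            frame_times=traj.frame_times,
            positions_unwrapped=np.mod(traj.positions_unwrapped, 10.0),
            radii=traj.radii,
            box_length=traj.box_length,
        )
        fs_true = self_intermediate_scattering(traj, q)
        fs_wrapped = self_intermediate_scattering(wrapped, q)
        assert fs_true.value[-1] < 0.15          # keeps decaying
        assert fs_wrapped.value[-1] > 0.4        # spurious plateau

    def test_invalid_q(self):
        traj = make_fixture("gauss_traj")
        with pytest.raises(ValueError):
            self_intermediate_scattering(traj, q=0.0)


class TestRelaxationTime:
    def _series(self, t, v):
        return CorrelationSeries(t=t, value=v, n_origins=np.ones(len(t), int))

    def test_exponential_recovered(self):
        t = np.concatenate([[0.0], np.geomspace(1, 1e4, 200)])
        tau = relaxation_time(self._series(t, np.exp(-t / 137.0)))
        assert tau == pytest.approx(137.0, rel=1e-3)

    def test_stretched_exponential_one_over_e_time_is_tau(self):
        t = np.concatenate([[0.0], np.geomspace(1, 1e5, 300)])
        v = np.exp(-((t / 412.0) ** 0.5))
        assert relaxation_time(self._series(t, v)) == pytest.approx(
            412.0, rel=1e-3
        )

    def test_unrelaxed_series_returns_none(self):
        t = np.concatenate([[0.0], np.geomspace(1, 100, 50)])
        assert relaxation_time(self._series(t, 1.0 - 0.3 * t / 100)) is None

    def test_grid_refinement_invariance(self):
        for n in (50, 400):
            t = np.concatenate([[0.0], np.geomspace(0.1, 1e4, n)])
            tau = relaxation_time(self._series(t, np.exp(-t / 55.0)))
            assert tau == pytest.approx(55.0, rel=5e-3)


class TestPerCellTaus:
    def test_identical_free_diffusers_agree(self):
        traj = make_fixture("gauss_traj")
        table = per_cell_relaxation_times(traj, q=0.6, max_origins=400)
        assert table["relaxed"].all()
        taus = table["tau_alpha"]
        # origins within one run are correlated; the effective number of
        # independent samples is ~ t_total / tau, so allow a broad spread
        assert taus.std() / taus.mean() < 0.4

    def test_frozen_cell_censored(self):
        traj = make_fixture("gauss_traj")
        pos = traj.positions_unwrapped.copy()
        pos[:, 0, :] = pos[0, 0, :]          # freeze cell 0
        frozen = TrajectoryStore(
            frame_times=traj.frame_times, positions_unwrapped=pos,
            radii=traj.radii, box_length=traj.box_length,
        )
        table = per_cell_relaxation_times(frozen, q=0.6)
        assert not table.loc[0, "relaxed"]
        assert np.isnan(table.loc[0, "tau_alpha"])
        assert table.loc[1:, "relaxed"].all()

    def test_global_fs_is_mean_of_per_cell(self):
        from softcells.observables import _fs_per_cell, _log_lags

        traj = make_fixture("gauss_traj")
        q = 0.5
        lags, per_cell, _ = _fs_per_cell(traj, q, _log_lags(traj.n_frames))
        fs = self_intermediate_scattering(traj, q)
        np.testing.assert_allclose(per_cell.mean(axis=1), fs.value, rtol=1e-12)


class TestLogTauHistogram:
    def test_equal_values_single_occupied_bin(self):
        hist = log_tau_histogram(np.full(20, 100.0))
        assert np.count_nonzero(hist.density) == 1
        assert hist.n_finite == 20

    def test_lognormal_sample_matches_generating_gaussian(self):
        rng = np.random.default_rng(5)
        taus = np.exp(rng.normal(5.0, 0.8, size=20_000))
        hist = log_tau_histogram(taus)
        from scipy.stats import norm

        expected = norm.pdf(hist.centers, 5.0, 0.8)
        np.testing.assert_allclose(hist.density, expected, atol=0.05)

    def test_censored_counted_not_binned(self):
        taus = np.concatenate([np.full(15, 50.0), [np.nan, np.nan]])
        hist = log_tau_histogram(taus)
        assert hist.n_censored == 2

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            log_tau_histogram(np.full(5, 10.0))


class TestWaitingTimeFs:
    def test_stationary_process_collapses(self):
        traj = make_fixture("gauss_traj")
        q = 0.5
        curves = waiting_time_fs(traj, q, [0.0, 500.0, 1500.0],
                                 origin_span=300.0)
        taus = [relaxation_time(c) for c in curves.values()]
        assert all(t is not None for t in taus)
        spread = (max(taus) - min(taus)) / np.mean(taus)
        assert spread < 0.2

    def test_nonstationary_process_ordered_by_waiting_time(self):
        # deliberately aging oracle: step size grows linearly with time,
        # so later origins decay faster -> smaller tau_alpha
        rng = np.random.default_rng(8)
        F, N = 400, 150
        scale = 0.3 * (1.0 + 3.0 * np.arange(F - 1) / F)[:, None, None]
        steps = rng.normal(size=(F - 1, N, 2)) * scale
        pos = np.concatenate(
            [np.zeros((1, N, 2)), np.cumsum(steps, axis=0)], axis=0
        )
        traj = TrajectoryStore(
            frame_times=np.arange(F) * 10.0,
            positions_unwrapped=pos + 100.0,
            radii=np.full(N, 5.0),
            box_length=300.0,
        )
        curves = waiting_time_fs(traj, 0.8, [0.0, 1000.0, 2000.0],
                                 origin_span=300.0)
        taus = [relaxation_time(c) for c in curves.values()]
        assert taus[0] > taus[1] > taus[2]

    def test_excessive_waiting_time_rejected(self):
        traj = make_fixture("gauss_traj")
        with pytest.raises(ValueError):
            waiting_time_fs(traj, 0.5, [1e9])


class TestOverlapDistribution:
    def test_no_contacts_empty(self, lattice16):
        stats = overlap_distribution(_static_traj(lattice16))
        assert stats.mean_h == 0.0
        assert stats.n_pairs == 0

    def test_single_pair_delta_at_one(self, pair_h1):
        stats = overlap_distribution(_static_traj(pair_h1))
        assert stats.mean_h == pytest.approx(1.0)
        assert stats.n_pairs == 5
        # all mass inside the bin(s) containing h=1
        m = np.abs(stats.bin_centers - 1.0) < 0.5
        assert np.sum(stats.density[m]) > 0

    def test_mean_overlap_increases_with_phi(self):
        means = []
        for phi in (0.85, 0.89, 0.92):
            params = SimParams(
                n_cells=60, target_phi=phi, n_steps_grow=500,
                n_steps_equil=2000, n_steps_prod=1000, save_every=200,
                rng_seed=7,
            )
            traj = run_simulation(params)
            means.append(overlap_distribution(traj).mean_h)
        assert means[0] < means[1] < means[2]
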