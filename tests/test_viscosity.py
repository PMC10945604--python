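import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

from softcells import (
    CellPopulation,
    CorrelationSeries,
    SimParams,
    TrajectoryStore,
    fit_long_time,
    green_kubo_viscosity,
    make_fixture,
    smooth_short_time,
    stress_autocorrelation,
    virial_stress,
)
from softcells.fitting import stretched_exponential
from softcells.viscosity import stretched_exp_integral, viscosity_vs_phi

from test_forces import HERTZ_H1_R85


def _series(t, v):
    return CorrelationSeries(t=t, value=v, n_origins=np.ones(len(t), int))


def _stress_traj(series, dt=10.0):
    n = len(series)
    return TrajectoryStore(
        frame_times=np.array([0.0, dt]),
        positions_unwrapped=np.zeros((2, 1, 2)) + 5.0,
        radii=np.array([1.0]),
        box_length=50.0,
        stress_times=np.arange(1, n + 1) * dt,
        stress_xy=np.asarray(series, dtype=float),
    )


class TestVirialStress:
    def test_no_overlaps_zero(self, lattice16):
        s = virial_stress(lattice16, SimParams(n_cells=16, target_phi=0.5))
        assert s.p_xy == 0.0 and s.p_xx == 0.0 and s.p_yy == 0.0

    def test_single_pair_hand_evaluated(self):
        # diagonal pair, separation 16 at 45 deg: r_x = r_y = 16/sqrt(2),
        # f_x = f_y = F/sqrt(2) with F the h=1 Hertz magnitude
        L = 60.0
        d = 16.0 / np.sqrt(2.0)
        pop = CellPopulation(
            radii=np.array([8.5, 8.5]),
            positions=np.array([[15.0, 15.0], [15.0 + d, 15.0 + d]]),
            box_length=L,
        )
        s = virial_stress(pop, SimParams(n_cells=2, target_phi=0.5))
        expected = d * (HERTZ_H1_R85 / np.sqrt(2.0)) / L**2
        assert s.p_xy == pytest.approx(expected, rel=1e-12)
        assert s.p_yx == s.p_xy

    def test_symmetry_on_random_configuration(self):
        params = SimParams(n_cells=50, target_phi=0.93, rng_seed=6)
        pop = CellPopulation.random(params, rng=np.random.default_rng(6))
        s = virial_stress(pop, params)
        assert s.p_xy == s.p_yx


class TestStressAutocorrelation:
    def test_constant_series_flat_square(self):
        traj = _stress_traj(np.full(500, 0.3))
        acf = stress_autocorrelation(traj, subtract_mean=False)
        np.testing.assert_allclose(acf.value, 2 * 0.3**2, rtol=1e-10)

    def test_white_noise_vanishes_beyond_lag_zero(self):
        rng = np.random.default_rng(0)
        traj = _stress_traj(rng.normal(size=200_000))
        acf = stress_autocorrelation(traj)
        assert acf.value[0] == pytest.approx(2.0, rel=0.02)
        assert np.max(np.abs(acf.value[1:])) < 0.1

    def test_ar1_decay_rate_recovered(self):
        # AR(1): x_{t+1} = a x_t + noise has ACF a^k
        rng = np.random.default_rng(1)
        a, n = 0.95, 400_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = a * x[i - 1] + eps[i]
        acf = stress_autocorrelation(_stress_traj(x), max_lag_fraction=0.001)
        k = np.arange(acf.t.size)
        np.testing.assert_allclose(
            acf.normalized[:50], a ** k[:50], atol=0.03
        )

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            stress_autocorrelation(_stress_traj([1.0]))


class TestSmoothShortTime:
    def test_uniform_grid_returned_at_nodes(self):
        t = np.arange(0.0, 200.0, 10.0)
        v = np.cos(t / 40.0)
        grid, smoothed = smooth_short_time(_series(t, v), t_end=190.0)
        np.testing.assert_allclose(grid, t)
        np.testing.assert_allclose(smoothed, v, rtol=1e-12)

    def test_cubic_polynomial_reproduced_between_nodes(self):
        t = np.array([0.0, 25.0, 60.0, 110.0, 170.0])
        poly = lambda x: 1.0 - 0.01 * x + 2e-4 * x**2 - 5e-7 * x**3
        grid, smoothed = smooth_short_time(_series(t, poly(t)), t_end=170.0)
        np.testing.assert_allclose(smoothed, poly(grid), rtol=1e-9)

    def test_derivative_continuity_at_interior_nodes(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 300, 12))
        t[0] = 0.0
        v = rng.normal(size=12)
        from scipy.interpolate import CubicSpline

        spline = CubicSpline(t, v, bc_type="natural")
        eps = 1e-6
        for tk in t[1:-1]:
            for der in (1, 2):
                left = spline(tk - eps, der)
                right = spline(tk + eps, der)
                assert left == pytest.approx(right, rel=1e-4, abs=1e-6)

    def test_needs_enough_points(self):
        t = np.array([0.0, 10.0, 20.0])
        with pytest.raises(ValueError):
            smooth_short_time(_series(t, np.ones(3)), t_end=25.0)


class TestFitLongTime:
    def test_exact_model_recovered(self):
        t = np.arange(0.0, 5000.0, 10.0)
        v = stretched_exponential(t, 0.8, 450.0, 0.6)
        fit = fit_long_time(_series(t, v), t_start=100.0)
        assert fit["C_s"] == pytest.approx(0.8, rel=1e-6)
        assert fit["tau"] == pytest.approx(450.0, rel=1e-6)
        assert fit["beta"] == pytest.approx(0.6, rel=1e-6)

    def test_pure_exponential_gives_beta_one(self):
        t = np.arange(0.0, 3000.0, 10.0)
        fit = fit_long_time(_series(t, np.exp(-t / 300.0)), t_start=0.0)
        assert fit["beta"] == pytest.approx(1.0, rel=1e-4)

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 6000.0, 10.0)
        clean = stretched_exponential(t, 1.0, 500.0, 0.65)
        errs = []
        for _ in range(25):
            noisy = clean + rng.normal(0, 0.1 * clean + 1e-4)
            fit = fit_long_time(_series(t, noisy), t_start=50.0)
            errs.append(abs(fit["tau"] - 500.0) / 500.0)
        assert np.median(errs) < 0.1


class TestGreenKubo:
    def test_rectangular_acf_integrates_to_ct(self):
        # C on [0, T], 0 after -> eta = C*T within quadrature error;
        # raw-data tail mode, since a step is not stretched-exponential
        C, T = 0.8, 2000.0
        t = np.arange(0.0, 4000.0, 10.0)
        v = np.where(t <= T, C, 0.0)
        eta, _ = green_kubo_viscosity(
            _series(t, v), t1=1000.0, long_time="data"
        )
        assert eta == pytest.approx(C * T, rel=0.01)

    def test_exponential_closed_form(self):
        t = np.arange(0.0, 20_000.0, 10.0)
        C, tau = 0.7, 800.0
        eta, _ = green_kubo_viscosity(
            _series(t, C * np.exp(-t / tau)), t1=400.0
        )
        assert eta == pytest.approx(C * tau, rel=0.01)

    def test_stretched_exponential_closed_form(self):
        t = np.arange(0.0, 30_000.0, 10.0)
        C, tau, beta = 0.5, 600.0, 0.55
        v = stretched_exponential(t, C, tau, beta)
        eta, spliced = green_kubo_viscosity(_series(t, v), t1=300.0)
        expected = C * tau * gamma_fn(1.0 / beta) / beta
        assert eta == pytest.approx(expected, rel=0.01)
        assert spliced.gap < 1e-6

    def test_quadrature_refinement_stable(self):
        t = np.arange(0.0, 20_000.0, 10.0)
        v = np.exp(-t / 500.0)
        eta10, _ = green_kubo_viscosity(_series(t, v), t1=250.0, delta=10.0)
        eta5, _ = green_kubo_viscosity(_series(t, v), t1=250.0, delta=5.0)
        assert abs(eta5 - eta10) / eta10 < 1e-3

    def test_discontinuous_splice_rejected(self):
        # short-time data inconsistent with the tail: force a mismatch
        t = np.arange(0.0, 5000.0, 10.0)
        v = np.exp(-t / 300.0)
        v[t <= 500.0] += 5.0
        with pytest.raises(ValueError, match="discontinuous"):
            green_kubo_viscosity(_series(t, v), t1=500.0, fit_start=600.0)

    def test_synthetic_stress_process_matches_closed_form(self):
        # circulant-embedding series with exact stretched-exponential ACF
        traj = make_fixture("acf_stretch_b06")
        acf = stress_autocorrelation(traj, max_lag_fraction=0.2)
        eta, _ = green_kubo_viscosity(acf, t1=100.0)
        expected = 2.0 * 300.0 * gamma_fn(1 / 0.6) / 0.6  # factor 2: xy+yx
        assert eta == pytest.approx(expected, rel=0.25)


class TestViscosityVsPhi:
    def test_identical_replicates_zero_spread(self):
        base = make_fixture("acf_stretch_b06")
        base.params = SimParams(n_cells=1, target_phi=0.8)
        table = viscosity_vs_phi([base, base])
        assert len(table) == 1
        assert table.loc[0, "eta_std"] == 0.0
        assert table.loc[0, "n_replicates"] == 2

    def test_mixed_parameters_rejected(self):
        t = np.arange(0.0, 20_000.0, 10.0)
        series = 0.1 * np.sin(t / 50.0) * np.exp(-t / 2000.0)
        a = _stress_traj(series)
        b = _stress_traj(series)
        a.params = SimParams(n_cells=1, target_phi=0.8, mu_activity=0.045)
        b.params = SimParams(n_cells=1, target_phi=0.8, mu_activity=0.09)
        with pytest.raises(ValueError):
            viscosity_vs_phi([a, b])
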