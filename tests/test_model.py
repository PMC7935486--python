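"""Unit and property tests for the 1D mechanochemical chain model."""

import math

import numpy as np
import pytest

import cochleaflow as cf
from cochleaflow.model import ChainInstabilityError, ModelParams


def hand_step(state, p, mode):
    """Independent per-equation scalar evaluation of one Euler update."""
    N = p.N
    xd = [0.0]
    for i in range(1, N):
        xd.append((p.k * (state.eps[i] - state.eps[i - 1]) + state.F[i]) / p.eta_c)
    xd.append((-p.k * state.eps[N - 1] + p.F_tip) / p.eta_c)
    x = [state.x[i] + p.dt * xd[i] for i in range(N + 1)]
    eps = [(x[j + 1] - x[j]) / p.L - 1.0 for j in range(N)]
    if mode == "coupled":
        E = [state.E[j] + p.dt * (math.tanh(p.alpha * eps[j]) - state.E[j]) / p.eta_E
             for j in range(N)]
    else:
        E = [0.5 * (math.sin(math.pi * (0.5 * (x[j] + x[j + 1])
                                        + p.v * (state.t + p.dt)) / p.w) + 1.0)
             for j in range(N)]
    F = [state.F[j] + p.dt * (p.lam * E[j] - state.F[j]) / p.eta_F for j in range(N)]
    return x, eps, E, F


class TestParamsAndInit:
    def test_default_params_coupled(self):
        p = cf.default_params("coupled")
        assert (p.eta_c, p.k, p.F_tip, p.alpha) == (40.0, 20.0, 6.0, 3.0)
        assert (p.eta_E, p.eta_F, p.lam) == (30.0, 10.0, 9.0)
        assert (p.N, p.dt, p.L) == (1000, 0.01, 5.0)

    def test_default_params_uncoupled_carries_wave(self):
        p = cf.default_params("uncoupled")
        assert (p.w, p.v) == (84.0, 0.42)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            cf.default_params("x")
        with pytest.raises(ValueError):
            ModelParams(mode="weird")

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(k=-1.0)
        with pytest.raises(ValueError):
            ModelParams(N=1)
        with pytest.raises(ValueError):
            ModelParams(dt=50.0)  # explicit-Euler stability guard
        with pytest.raises(ValueError):
            ModelParams(mode="uncoupled")  # w, v missing

    def test_init_chain_rest_state(self):
        p = ModelParams(N=3)
        s = cf.init_chain(p)
        assert np.allclose(s.x, [0, 5, 10, 15])
        assert np.all(s.eps == 0) and np.all(s.E == 0) and np.all(s.F == 0)
        s1000 = cf.init_chain(cf.default_params("coupled"))
        assert s1000.x[-1] == 5000.0


class TestEulerStep:
    @pytest.mark.parametrize("mode", ["coupled", "uncoupled"])
    def test_matches_per_equation_oracle(self, mode, rng):
        kw = {"w": 84.0, "v": 0.42} if mode == "uncoupled" else {}
        p = ModelParams(mode=mode, N=5, **kw)
        s = cf.init_chain(p)
        # random but ordered state
        s.x = np.sort(rng.uniform(0, 40, p.N + 1))
        s.eps = np.diff(s.x) / p.L - 1.0
        s.E = rng.uniform(-1, 1, p.N)
        s.F = rng.uniform(-5, 5, p.N)
        s.t = 3.7
        out = cf.euler_step(s, p)
        x, eps, E, F = hand_step(s, p, mode)
        assert np.allclose(out.x, x, rtol=0, atol=1e-14)
        assert np.allclose(out.eps, eps, rtol=0, atol=1e-13)
        assert np.allclose(out.E, E, rtol=0, atol=1e-14)
        assert np.allclose(out.F, F, rtol=0, atol=1e-14)

    def test_interior_velocity_value(self):
        # net elastic strain difference 0.1 and force 6 nN: (20*0.1+6)/40
        p = ModelParams(N=3)
        eps = np.array([0.0, 0.1, 0.0])
        F = np.array([0.0, 6.0, 0.0])
        from cochleaflow.model import _velocities
        xd = _velocities(np.array([0.0, 5, 10, 15]), eps, F, p, "conventional")
        assert xd[1] == pytest.approx((20 * 0.1 + 6) / 40)

    def test_relaxation_fixed_points(self):
        # eps=0, E=0 is a fixed point of the ERK relaxation; E=1, F=9 of the
        # force relaxation with lam=9
        p = ModelParams(N=2, F_tip=0.0)
        s = cf.init_chain(p)
        out = cf.euler_step(s, p)
        assert np.all(out.E == 0) and np.all(out.F == 0)
        s.E = np.ones(2)
        s.F = np.full(2, 9.0)
        out = cf.euler_step(s, p)
        assert np.allclose(out.F, 9.0)

    def test_junction_crossing_raises(self):
        p = ModelParams(N=2, dt=1.0, eta_E=30.0, eta_F=10.0)
        s = cf.init_chain(p)
        s.F = np.array([0.0, -1000.0])  # huge rearward pull inverts a cell
        with pytest.raises(ChainInstabilityError):
            cf.euler_step(s, p)

    def test_run_consistent_with_euler_step(self):
        p = ModelParams(mode="coupled", N=8, dt=0.01)
        traj = cf.run(p, duration=0.1, record_interval=0.01, discard=0.0,
                      init="rest")
        s = cf.init_chain(p)
        for i in range(1, len(traj)):
            s = cf.euler_step(s, p)
            assert np.allclose(traj.x[i], s.x, atol=1e-12)
            assert np.allclose(traj.E[i], s.E, atol=1e-12)


class TestImposedWave:
    def test_range_and_wavelength(self):
        p = cf.default_params("uncoupled")
        X = np.linspace(0, 1000, 5001)
        E = cf.imposed_erk(X, 17.0, p)
        assert np.all((E >= 0) & (E <= 1))
        assert np.allclose(cf.imposed_erk(X + 168.0, 17.0, p), E, atol=1e-12)
        assert not np.allclose(cf.imposed_erk(X + 84.0, 17.0, p), E, atol=1e-3)

    def test_crest_travels_toward_base(self):
        # the phase is constant along X = c - v t: the pattern moves toward -X
        p = cf.default_params("uncoupled")
        X = np.linspace(0, 500, 2001)
        e0 = cf.imposed_erk(X, 100.0, p)
        e1 = cf.imposed_erk(X - p.v * 30.0, 130.0, p)
        assert np.allclose(e0, e1, atol=1e-12)

    def test_requires_uncoupled_mode(self):
        with pytest.raises(ValueError):
            cf.imposed_erk(0.0, 0.0, cf.default_params("coupled"))


class TestRunInvariants:
    def test_equilibrium_without_drives(self):
        p = ModelParams(mode="coupled", N=20, F_tip=0.0, lam=0.0)
        traj = cf.run(p, duration=50.0, record_interval=5.0, discard=0.0,
                      init="rest")
        assert np.all(traj.eps == 0)
        assert np.all(traj.E == 0)
        assert np.all(traj.F == 0)
        assert np.allclose(traj.x, traj.x[0])

    def test_erk_bounded(self, small_coupled_traj):
        assert np.all(np.abs(small_coupled_traj.E) <= 1.0 + 1e-9)

    def test_force_bounded(self, small_coupled_traj):
        lam = small_coupled_traj.params.lam
        assert np.all(np.abs(small_coupled_traj.F) <= lam + 1e-9)

    def test_flipped_orientation_is_unstable(self):
        p = ModelParams(mode="coupled", N=200)
        with pytest.raises(ChainInstabilityError):
            cf.run(p, duration=100.0, record_interval=1.0, discard=0.0,
                   orientation="flipped", strict=True, seed=0)

    def test_retrograde_waves_against_forward_flow(self, small_coupled_traj):
        """ERK stripes travel tip-to-base while the junctions drift
        base-to-tip (the retrograde pattern)."""
        traj = small_coupled_traj
        # Eulerian resampling of E onto a fixed lab grid
        centers = 0.5 * (traj.x[:, :-1] + traj.x[:, 1:])
        xg = np.arange(100.0, traj.x[:, -1].min() - 100.0, 5.0)
        Eul = np.vstack([np.interp(xg, centers[i], traj.E[i])
                         for i in range(len(traj))])
        # stripe displacement over 50 min by profile cross-correlation
        i0 = len(traj) // 2
        a, b = Eul[i0], Eul[i0 + 50]
        r = cf.xcorr_lag(a, b, 40.0, dt=5.0)  # dt here is the 5-µm grid step
        stripe_shift_um = r.peak_lag  # >0 means profile moved toward -x
        assert r.peak_corr > 0.5
        assert stripe_shift_um > 0, "ERK stripes should move toward the base"
        mean_cell_velocity = (traj.x[-1] - traj.x[0]).mean() / (
            traj.record_times[-1] - traj.record_times[0])
        assert mean_cell_velocity > 0, "cells should flow toward the apex"


class TestRateSeries:
    def test_constant_strain_has_zero_rate(self):
        p = ModelParams(N=4)
        traj = cf.run(ModelParams(mode="coupled", N=4, F_tip=0.0, lam=0.0),
                      duration=10.0, record_interval=1.0, discard=0.0,
                      init="rest")
        ext, erk = cf.model_rate_series(traj)
        assert np.allclose(ext, 0) and np.allclose(erk, 0)

    def test_sinusoid_rate_matches_analytic_derivative(self):
        # synthetic trajectory with eps_j(t) = A sin(w t)
        p = ModelParams(N=3)
        t = np.arange(0.0, 200.0, 0.5)
        A, om = 0.05, 2 * np.pi / 50.0
        eps = A * np.sin(om * t)[:, None] * np.ones(3)
        traj = cf.Trajectory(record_times=t, record_interval=0.5,
                             x=np.zeros((len(t), 4)), eps=eps,
                             E=np.zeros_like(eps), F=np.zeros_like(eps),
                             params=p)
        ext, _ = cf.model_rate_series(traj, kind="eps_rate")
        expected = A * om * np.cos(om * t)
        assert np.abs(ext[2:-2, 0] - expected[2:-2]).max() < 2e-4

    def test_strain_rate_is_log_length_derivative(self, small_coupled_traj):
        traj = small_coupled_traj
        ext, _ = cf.model_rate_series(traj, kind="strain_rate")
        # compare against direct velocity-gradient evaluation at one cell
        j = 150
        v = np.gradient(traj.x, traj.record_interval, axis=0)
        direct = (v[:, j + 1] - v[:, j]) / (traj.x[:, j + 1] - traj.x[:, j])
        # central differences of log-length agree away from inversion events
        ok = np.abs(direct) < 0.05
        assert np.corrcoef(ext[ok, j], direct[ok])[0, 1] > 0.99

    def test_too_few_snapshots_rejected(self):
        p = ModelParams(N=3)
        traj = cf.Trajectory(record_times=np.array([0.0, 1.0]),
                             record_interval=1.0, x=np.zeros((2, 4)),
                             eps=np.zeros((2, 3)), E=np.zeros((2, 3)),
                             F=np.zeros((2, 3)), params=p)
        with pytest.raises(ValueError):
            cf.model_rate_series(traj)


class TestXcorr:
    def test_constructed_shift_gives_negative_lag(self):
        t = np.arange(400.0)
        a = np.sin(2 * np.pi * t / 100)
        b = np.sin(2 * np.pi * (t - 24) / 100)  # b delayed: a leads
        r = cf.xcorr_lag(a, b, 60.0)
        # within one sampling interval (the constant-denominator taper can
        # shift a slow oscillation's peak by a fraction of a sample)
        assert abs(r.peak_lag - (-24.0)) <= 1.0
        assert r.peak_corr > 0.9

    def test_identity(self):
        a = np.sin(np.arange(300.0) / 7.0)
        r = cf.xcorr_lag(a, a, 50.0)
        assert r.peak_lag == 0.0
        assert r.peak_corr == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cf.xcorr_lag(np.ones(50), np.arange(50.0), 10.0)

    def test_ties_break_toward_smaller_lag(self):
        # period-8 square-ish wave: correlation at lag 0 and +/-8 equal
        a = np.tile([1.0, 1, -1, -1], 64)
        r = cf.xcorr_lag(a, a, 16.0)
        assert r.peak_lag == 0.0

    def test_lag_in_grid_and_corr_bounded(self, rng):
        a = rng.standard_normal(256)
        b = rng.standard_normal(256)
        r = cf.xcorr_lag(a, b, 30.0)
        assert r.peak_lag in r.lags
        assert r.peak_corr == r.corr.max()

    def test_dt_convergence_of_lag(self):
        """Halving dt leaves the measured lag unchanged within one
        recording interval (reduced chain)."""
        lags = []
        for dt in (0.02, 0.01):
            p = ModelParams(mode="uncoupled", N=200, dt=dt, w=84.0, v=0.42)
            traj = cf.run(p, duration=900.0, record_interval=1.0, discard=200.0)
            lags.append(cf.rate_lag_analysis(traj, edge_cells=10)["median_lag"])
        assert abs(lags[0] - lags[1]) <= 1.0
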