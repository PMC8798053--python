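"""Solver correctness: closed-form oracles (free decay, driven steady state),
superposition, fourth-order convergence, warm-up, and force bookkeeping."""

import math

import numpy as np
import pytest

from per2osc.core import BinnedSignal
from per2osc.oscillator import (DT, Forcing, OscState, OscillatorParams,
                                build_forcing, force_summary, integrate_rk4,
                                peri_force, peri_only_solution,
                                predict_observable, warmup,
                                _rk4_affine, _rk4_reference)
from per2osc.protocols import Protocol, repeated_4h_sd


def zero_forcing(n, t0=0.0):
    return Forcing(t0=t0, dt=DT, f_wake=np.zeros(n), f_peri=np.zeros(n))


def peri_forcing(n, A, phi, omega, t0=0.0):
    t = t0 + DT * np.arange(n)
    return Forcing(t0=t0, dt=DT, f_wake=np.zeros(n),
                   f_peri=peri_force(t, A, phi, omega))


class TestBuildForcing:
    def test_pure_circadian_component(self):
        lma = BinnedSignal(0.0, DT, np.zeros(480))
        f = build_forcing(lma, beta=0.0, A=2e-3, phi=1.0)
        assert np.allclose(f.f_wake, 0.0)
        assert np.allclose(f.f_peri, 2e-3 * np.sin(
            2 * np.pi / 23.7 * lma.times_h + 1.0))

    def test_constant_activity_gives_constant_wake_force(self):
        lma = BinnedSignal(0.0, DT, np.full(240, 80.0))
        f = build_forcing(lma, beta=5e-5, A=0.0, phi=0.0)
        assert np.allclose(f.f_wake, 5e-5 * 80.0)
        assert np.allclose(f.f_peri, 0.0)

    def test_default_circadian_period(self):
        """The default angular velocity corresponds to a 23.7-h period."""
        from per2osc.oscillator import OMEGA_PERI
        assert 2 * np.pi / OMEGA_PERI == pytest.approx(23.7)

    def test_sd_imputation_inside_forcing(self):
        lma = BinnedSignal(0.0, DT, np.full(480, 10.0))
        proto = Protocol(name="x", sd_intervals=((10.0, 14.0),))
        f = build_forcing(lma, beta=1.0, A=0.0, phi=0.0, protocol=proto,
                          baseline_mean_lma=100.0)
        in_sd = proto.in_sd(lma.times_h)
        assert np.allclose(f.f_wake[in_sd], 240.0)
        assert np.allclose(f.f_wake[~in_sd], 10.0)

    def test_wrong_grid_rejected(self):
        lma = BinnedSignal(0.0, 0.5, np.zeros(48))
        with pytest.raises(ValueError):
            build_forcing(lma, beta=0.0, A=0.0, phi=0.0)


class TestIntegrator:
    def test_rest_stays_at_rest(self):
        p = OscillatorParams(gamma=0.1, omega0=0.3, beta=0, intercept=1,
                             A=0, phi=0)
        traj = integrate_rk4(p, zero_forcing(100))
        assert np.all(traj.x1 == 0.0)
        assert np.all(traj.x2 == 0.0)

    def test_undamped_free_oscillation_matches_cosine(self):
        """gamma=0, x0=(1,0): x1(t) = cos(omega0 t) to 1e-6 over 100 h."""
        p = OscillatorParams(gamma=0.0, omega0=0.288, beta=0, intercept=0,
                             A=0, phi=0)
        traj = integrate_rk4(p, zero_forcing(1000), OscState(1.0, 0.0))
        assert np.max(np.abs(traj.x1 - np.cos(0.288 * traj.t))) < 1e-6

    def test_driven_steady_state_amplitude(self):
        """After a 500-h transient the response amplitude matches
        A / sqrt((w0^2-w^2)^2 + (gamma w)^2) within 0.1%."""
        p = OscillatorParams(gamma=0.0155, omega0=0.288, beta=0, intercept=0,
                             A=3.87e-3, phi=2.78)
        # transient decays as exp(-gamma t / 2); run until it is < 1e-5
        t_settle = 2.0 / p.gamma * math.log(1e5)
        n = round((t_settle + 237.0) / DT)
        traj = integrate_rk4(p, peri_forcing(n, p.A, p.phi, p.omega))
        R, _ = peri_only_solution(p)
        tail = traj.x1[traj.t > t_settle]
        amp = 0.5 * (tail.max() - tail.min())
        assert amp == pytest.approx(R, rel=1e-3)

    def test_affine_and_loop_paths_agree(self):
        rng = np.random.default_rng(0)
        F = rng.normal(size=500)
        a1, a2 = _rk4_affine(0.0155, 0.288, F, (0.3, -0.1), DT)
        r1, r2 = _rk4_reference(0.0155, 0.288, F, (0.3, -0.1), DT)
        assert np.max(np.abs(a1 - r1)) < 1e-12
        assert np.max(np.abs(a2 - r2)) < 1e-12

    def test_superposition(self):
        """Response to Fa+Fb equals response to Fa plus response to Fb."""
        rng = np.random.default_rng(1)
        p = OscillatorParams(gamma=0.02, omega0=0.3, beta=0, intercept=0,
                             A=0, phi=0)
        Fa, Fb = rng.normal(size=300), rng.normal(size=300)
        mk = lambda F: Forcing(0.0, DT, F, np.zeros_like(F))
        xa = integrate_rk4(p, mk(Fa)).x1
        xb = integrate_rk4(p, mk(Fb)).x1
        xab = integrate_rk4(p, mk(Fa + Fb)).x1
        assert np.max(np.abs(xab - (xa + xb))) < 1e-9

    def test_fourth_order_convergence(self):
        """Halving dt shrinks the error by ~2^4 (free oscillation vs cosine)."""
        w0 = 0.288
        t_end = 100.0
        errs = {}
        for dt in (0.2, 0.1, 0.05):
            n = round(t_end / dt)
            x1, _ = _rk4_reference(0.0, w0, np.zeros(n), (1.0, 0.0), dt)
            errs[dt] = abs(x1[-1] - math.cos(w0 * t_end))
        r1 = errs[0.2] / errs[0.1]
        r2 = errs[0.1] / errs[0.05]
        assert r1 == pytest.approx(16.0, rel=0.2)
        assert r2 == pytest.approx(16.0, rel=0.2)

    def test_energy_decay_envelope(self):
        """With F=0 and gamma>0 the envelope decays as exp(-gamma t/2)."""
        g, w0 = 0.04, 0.5
        p = OscillatorParams(gamma=g, omega0=w0, beta=0, intercept=0, A=0,
                             phi=0)
        n = round(5 * (2.0 / g) / DT)  # five decay time constants
        traj = integrate_rk4(p, zero_forcing(n), OscState(1.0, 0.0))
        wd = math.sqrt(w0 ** 2 - g ** 2 / 4)
        # amplitude envelope from x1 and x1' (phase-independent)
        env = np.sqrt(traj.x1 ** 2 +
                      ((traj.x2 + 0.5 * g * traj.x1) / wd) ** 2)
        expected = np.exp(-0.5 * g * traj.t)
        assert np.max(np.abs(env - expected) / expected) < 0.01

    def test_force_bookkeeping_identity(self):
        """Stored components reconstruct the acceleration: the state-equation
        right-hand side equals f_wake + f_peri + f_gamma + f_omega."""
        p = OscillatorParams(gamma=0.0155, omega0=0.288, beta=0, intercept=0,
                             A=3e-3, phi=1.0)
        traj = integrate_rk4(p, peri_forcing(480, p.A, p.phi, p.omega))
        rhs = traj.f_wake + traj.f_peri + traj.f_gamma + traj.f_omega
        direct = traj.f_wake + traj.f_peri - p.gamma * traj.x2 \
            - p.omega0 ** 2 * traj.x1
        assert np.allclose(rhs, direct, atol=1e-15)


class TestWarmup:
    def params(self, **kw):
        base = dict(gamma=0.0155, omega0=0.288, beta=6.81e-5, intercept=0.92,
                    A=2.92e-3, phi=4.73)
        base.update(kw)
        return OscillatorParams(**base)

    def test_unforced_warmup_stays_at_rest(self):
        p = self.params(beta=0.0, A=0.0)
        state = warmup(p, np.zeros(240))
        assert state.x1 == 0.0 and state.x2 == 0.0

    def _envelope(self, p, state):
        """Phase-independent oscillation scale of a state vector."""
        return math.hypot(state.x1, state.x2 / p.omega0)

    def test_periodic_forcing_reaches_steady_state(self):
        """The warm-up transient decays as exp(-gamma t / 2): day 20 sits
        within that bound of the fully converged periodic state."""
        rng = np.random.default_rng(2)
        day = rng.uniform(0, 150, 240)
        p = self.params()
        s20 = warmup(p, day, days=20)
        s60 = warmup(p, day, days=60)  # e^(-11) transient: converged
        scale = self._envelope(p, s60)
        resid = math.hypot(s20.x1 - s60.x1, (s20.x2 - s60.x2) / p.omega0)
        bound = math.exp(-0.5 * p.gamma * 20 * 24.0)
        assert resid / scale < 2.0 * bound

    def test_doubling_warmup_days_converges_geometrically(self):
        rng = np.random.default_rng(2)
        day = rng.uniform(0, 150, 240)
        p = self.params()
        s20, s40, s60 = (warmup(p, day, days=d) for d in (20, 40, 60))
        d20 = math.hypot(s20.x1 - s60.x1, (s20.x2 - s60.x2) / p.omega0)
        d40 = math.hypot(s40.x1 - s60.x1, (s40.x2 - s60.x2) / p.omega0)
        # 20 extra days shrink the transient by ~exp(-gamma*240) ~ 0.024
        assert d40 < 0.1 * d20

    def test_wrong_day_length_rejected(self):
        with pytest.raises(ValueError):
            warmup(self.params(), np.zeros(100))


class TestPredictObservable:
    def test_zero_trajectory_returns_intercept(self):
        p = OscillatorParams(gamma=0.1, omega0=0.3, beta=0, intercept=0.92,
                             A=0, phi=0)
        traj = integrate_rk4(p, zero_forcing(480))
        pred = predict_observable(traj, 0.92, 0.0, 0.5, 96)
        assert np.allclose(pred.values, 0.92)

    def test_linear_trajectory_bin_means(self):
        """For x1 = t the 30-min bin mean is the mean of its grid points."""
        n = 100
        traj_t = DT * np.arange(n + 1)
        from per2osc.oscillator import Trajectory
        z = np.zeros(n + 1)
        traj = Trajectory(t=traj_t, x1=traj_t.copy(), x2=z, f_wake=z,
                          f_peri=z, f_gamma=z, f_omega=z)
        pred = predict_observable(traj, 1.0, 0.0, 0.5, 10)
        expected = 1.0 + (np.arange(10) * 0.5 + np.mean(DT * np.arange(5)))
        assert np.allclose(pred.values, expected, atol=1e-12)

    def test_coverage_gap_rejected(self):
        p = OscillatorParams(gamma=0.1, omega0=0.3, beta=0, intercept=0,
                             A=0, phi=0)
        traj = integrate_rk4(p, zero_forcing(10))
        with pytest.raises(ValueError):
            predict_observable(traj, 0.0, 0.0, 0.5, 10)


class TestPeriOnlySolution:
    def test_quasi_static_limit(self):
        p = OscillatorParams(gamma=0.0, omega0=1.0, beta=0, intercept=0,
                             A=2e-3, phi=0, omega=1e-4)
        R, delta = peri_only_solution(p)
        assert R == pytest.approx(2e-3, rel=1e-4)
        assert delta == pytest.approx(0.0, abs=1e-4)

    def test_resonance_rejected(self):
        p = OscillatorParams(gamma=0.0, omega0=0.2651, beta=0, intercept=0,
                             A=1e-3, phi=0, omega=0.2651)
        with pytest.raises(ZeroDivisionError):
            peri_only_solution(p)

    def test_nonzero_wake_coupling_rejected(self):
        p = OscillatorParams(gamma=0.01, omega0=0.3, beta=1e-5, intercept=0,
                             A=1e-3, phi=0)
        with pytest.raises(ValueError):
            peri_only_solution(p)

    def test_matches_rk4_after_transient(self):
        p = OscillatorParams(gamma=0.0155, omega0=0.288, beta=0, intercept=0,
                             A=2.92e-3, phi=4.73)
        R, delta = peri_only_solution(p)
        t_settle = 2.0 / p.gamma * math.log(1e4)
        n = round((t_settle + 100.0) / DT)
        traj = integrate_rk4(p, peri_forcing(n, p.A, p.phi, p.omega))
        tail = traj.t > t_settle
        # the zero-order hold of the forcing (one value per 0.1-h step)
        # delays the response by half a step; compare against the closed
        # form shifted by dt/2
        closed = R * np.sin(p.omega * (traj.t[tail] - DT / 2) + p.phi - delta)
        assert np.max(np.abs(traj.x1[tail] - closed)) < 1e-3 * R


class TestForceSummary:
    def test_sinusoid_mean_absolute_value(self):
        """mean|A sin| over whole periods approaches 2A/pi."""
        A, phi = 3.87e-3, 2.78
        p = OscillatorParams(gamma=0.0155, omega0=0.288, beta=0, intercept=0,
                             A=A, phi=phi)
        n = round(237.0 / DT)  # ten full periods
        traj = integrate_rk4(p, peri_forcing(n, A, phi, p.omega))
        s = force_summary(traj, (0.0, 237.0))
        assert s["mean_abs_peri"] == pytest.approx(2 * A / np.pi, rel=2e-3)

    def test_zero_everything_is_zero(self):
        p = OscillatorParams(gamma=0.1, omega0=0.3, beta=0, intercept=0,
                             A=0, phi=0)
        s = force_summary(integrate_rk4(p, zero_forcing(100)), (0.0, 10.0))
        assert all(v == 0.0 for v in s.values())

    def test_triangle_inequality(self):
        rng = np.random.default_rng(4)
        p = OscillatorParams(gamma=0.02, omega0=0.3, beta=0, intercept=0,
                             A=0, phi=0)
        f = Forcing(0.0, DT, rng.normal(size=400), rng.normal(size=400))
        s = force_summary(integrate_rk4(p, f), (0.0, 40.0))
        assert s["mean_abs_sum"] <= s["sum_of_mean_abs"] + 1e-12
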