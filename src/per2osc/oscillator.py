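"""Driven damped harmonic oscillator for PER2-bioluminescence dynamics.

The displacement ``x`` of relative PER2 bioluminescence around its equilibrium
(the model intercept) obeys

    x'' + gamma * x' + omega0**2 * x = F(t)

with two driving forces,

    F(t) = beta * LMA(t) + A * sin(omega * t + phi)

* ``beta * LMA(t)`` — the sleep-wake force: locomotor activity (LMA, counts
  per 6-min bin) is the proxy for time spent awake.
* ``A * sin(omega*t + phi)`` — a peripheral circadian force independent of
  both the SCN and the sleep-wake distribution; its angular velocity
  ``omega`` is fixed to 2*pi/23.7 rad/h, the free-running period of the
  residual rhythm in SCN-lesioned animals.

The second-order ODE is integrated as the first-order system
``x1' = x2; x2' = F - gamma*x2 - omega0**2*x1`` with classic fixed-step
fourth-order Runge-Kutta (RK4) at 0.1-h steps.  LMA is 6-min binned, so
bins and integration steps coincide and the forcing is held piecewise
constant per step (including at RK4 half-steps).

Because the system is linear and the forcing is constant within a step, a
single RK4 step is an affine map; :func:`integrate_rk4` exploits this to run
the recursion through a C-level IIR filter while remaining bit-for-bit
faithful to textbook RK4 (see ``_rk4_reference`` and the solver tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .core import BinnedSignal
from .protocols import Protocol

#: Default integration step, hours (equals the 6-min LMA bin width).
DT = 0.1

#: Fixed angular velocity of the circadian force, rad/h (23.7-h period).
OMEGA_PERI = 2.0 * math.pi / 23.7


@dataclass(frozen=True)
class OscillatorParams:
    """Free parameters of the model plus the fixed circadian angular velocity.

    Units: ``gamma`` 1/h, ``omega0`` rad/h, ``beta`` h^-2 per LMA count,
    ``intercept`` relative bioluminescence, ``A`` h^-2, ``phi`` rad,
    ``omega`` rad/h.
    """

    gamma: float
    omega0: float
    beta: float
    intercept: float
    A: float
    phi: float
    omega: float = OMEGA_PERI

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.omega0 <= 0:
            raise ValueError("omega0 must be > 0")
        if self.A < 0:
            raise ValueError("A must be >= 0")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")

    @property
    def natural_period_h(self) -> float:
        """Intrinsic period of the oscillator, 2*pi/omega0 (hours)."""
        return 2.0 * math.pi / self.omega0

    def replace(self, **kw) -> "OscillatorParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class OscState:
    """Oscillator position (relative bioluminescence) and velocity (per hour)."""

    x1: float = 0.0
    x2: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x1) and math.isfinite(self.x2)):
            raise ValueError("oscillator state must be finite")


@dataclass(frozen=True)
class Forcing:
    """Per-step forcing on the integration grid.

    ``f_wake[i]`` and ``f_peri[i]`` apply over ``[t0 + i*dt, t0 + (i+1)*dt)``.
    """

    t0: float
    dt: float
    f_wake: np.ndarray
    f_peri: np.ndarray

    def __post_init__(self) -> None:
        fw = np.asarray(self.f_wake, dtype=float)
        fp = np.asarray(self.f_peri, dtype=float)
        if fw.shape != fp.shape or fw.ndim != 1:
            raise ValueError("force components must be 1-D and equal length")
        object.__setattr__(self, "f_wake", fw)
        object.__setattr__(self, "f_peri", fp)

    @property
    def n_steps(self) -> int:
        return int(self.f_wake.size)

    @property
    def total(self) -> np.ndarray:
        return self.f_wake + self.f_peri


@dataclass(frozen=True)
class Trajectory:
    """Integrated oscillator path with its force decomposition.

    All arrays share the grid ``t`` (step 0.1 h, ``n_steps + 1`` points).
    ``f_gamma = -gamma*x2`` and ``f_omega = -omega0**2 * x1`` are the damping
    and string ("restoring") forces; ``f_wake``/``f_peri`` are the driving
    forces sampled at the grid points (last point repeats the final step).
    """

    t: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    f_wake: np.ndarray
    f_peri: np.ndarray
    f_gamma: np.ndarray
    f_omega: np.ndarray

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        return (self.t >= t0 - 1e-9) & (self.t < t1 - 1e-9)


def peri_force(t: np.ndarray, A: float, phi: float,
               omega: float = OMEGA_PERI) -> np.ndarray:
    """Circadian force ``A*sin(omega*t + phi)`` evaluated at times ``t`` (h)."""
    return A * np.sin(omega * np.asarray(t, dtype=float) + phi)


def impute_sd_lma(lma: BinnedSignal, protocol: Protocol,
                  baseline_mean_lma: float) -> np.ndarray:
    """LMA values with enforced-wakefulness bins replaced by the imputed level.

    Activity cannot be measured during sleep deprivations; bins whose start
    falls in an SD interval are set to ``2.4 * baseline_mean_lma``, the
    empirical activity elevation of mice kept awake by gentle handling
    relative to mean baseline activity.
    """
    values = lma.values.copy()
    if not protocol.is_empty:
        in_sd = protocol.in_sd(lma.times_h)
        values[in_sd] = 2.4 * baseline_mean_lma
    return values


def build_forcing(lma: BinnedSignal, beta: float, A: float, phi: float,
                  omega: float = OMEGA_PERI, protocol: Protocol | None = None,
                  baseline_mean_lma: float | None = None) -> Forcing:
    """Assemble the per-step forcing from 6-min LMA and the circadian sinewave.

    The LMA grid must match the integration step (0.1 h); resample upstream
    otherwise.  When ``protocol`` has SD intervals, ``baseline_mean_lma`` is
    required for the imputation of activity during enforced wakefulness.
    """
    if not math.isclose(lma.bin_width, DT, rel_tol=1e-9):
        raise ValueError(
            f"LMA bin width {lma.bin_width} h != integration step {DT} h; "
            "resample before building the forcing"
        )
    if protocol is not None and not protocol.is_empty:
        if baseline_mean_lma is None:
            raise ValueError("baseline_mean_lma required when protocol has SDs")
        values = impute_sd_lma(lma, protocol, baseline_mean_lma)
    else:
        values = lma.values
    f_wake = beta * values
    f_peri = peri_force(lma.times_h, A, phi, omega)
    return Forcing(t0=lma.start_time, dt=lma.bin_width, f_wake=f_wake,
                   f_peri=f_peri)


# ---------------------------------------------------------------------------
# RK4 integration


def _rk4_reference(gamma: float, omega0: float, F: np.ndarray,
                   x0: tuple[float, float], dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Textbook RK4 loop; the oracle the fast path is tested against."""
    w2 = omega0 * omega0
    n = F.size
    x1 = np.empty(n + 1)
    x2 = np.empty(n + 1)
    x1[0], x2[0] = x0

    def deriv(p: float, v: float, f: float) -> tuple[float, float]:
        return v, f - gamma * v - w2 * p

    for i in range(n):
        f = F[i]
        p, v = x1[i], x2[i]
        k1p, k1v = deriv(p, v, f)
        k2p, k2v = deriv(p + 0.5 * dt * k1p, v + 0.5 * dt * k1v, f)
        k3p, k3v = deriv(p + 0.5 * dt * k2p, v + 0.5 * dt * k2v, f)
        k4p, k4v = deriv(p + dt * k3p, v + dt * k3v, f)
        x1[i + 1] = p + dt / 6.0 * (k1p + 2 * k2p + 2 * k3p + k4p)
        x2[i + 1] = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    return x1, x2


def _rk4_step_maps(gamma: float, omega0: float,
                   dt: float) -> tuple[np.ndarray, np.ndarray]:
    """One RK4 step as the affine map ``y_(n+1) = M y_n + s F_n``.

    For the linear system y' = A y + [0, F] with F constant over the step,
    classic RK4 gives M = sum_{k<=4} (dt A)^k / k! and
    s = dt*(I + dt A/2 + (dt A)^2/6 + (dt A)^3/24) @ [0, 1].
    """
    A = np.array([[0.0, 1.0], [-omega0 * omega0, -gamma]])
    I = np.eye(2)
    dA = dt * A
    dA2 = dA @ dA
    dA3 = dA2 @ dA
    dA4 = dA3 @ dA
    M = I + dA + dA2 / 2.0 + dA3 / 6.0 + dA4 / 24.0
    S = dt * (I + dA / 2.0 + dA2 / 6.0 + dA3 / 24.0)
    return M, S[:, 1]


def _rk4_affine(gamma: float, omega0: float, F: np.ndarray,
                x0: tuple[float, float], dt: float) -> tuple[np.ndarray, np.ndarray]:
    """RK4 via the affine one-step map, run through a C-level IIR filter.

    Diagonalizes the step map and solves each eigen-mode's first-order
    recursion with :func:`scipy.signal.lfilter`.  Falls back to the plain
    loop near critical damping where the map is defective.
    """
    M, s = _rk4_step_maps(gamma, omega0, dt)
    lam, V = np.linalg.eig(M)
    if abs(lam[0] - lam[1]) < 1e-9 * max(1.0, abs(lam[0])):
        return _rk4_reference(gamma, omega0, F, x0, dt)
    Vinv = np.linalg.inv(V)
    z0 = Vinv @ np.asarray(x0, dtype=float)
    u = np.outer(Vinv @ s, F)  # (2, n) per-mode inputs
    n = F.size
    z = np.empty((2, n + 1), dtype=complex)
    z[:, 0] = z0
    for i in range(2):
        drive = u[i].astype(complex)
        drive[0] += lam[i] * z0[i]
        z[i, 1:] = lfilter([1.0], [1.0, -lam[i]], drive)
    y = V @ z
    if np.iscomplexobj(y):
        y = y.real
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("oscillator state became non-finite")
    return np.ascontiguousarray(y[0]), np.ascontiguousarray(y[1])


def integrate_rk4(params: OscillatorParams, forcing: Forcing,
                  x0: OscState | None = None, dt: float = DT,
                  method: str = "affine") -> Trajectory:
    """Integrate the oscillator over the forcing's support.

    ``method="affine"`` (default) uses the exact affine-map formulation of
    the RK4 step; ``method="loop"`` runs the explicit RK4 loop.  Both yield
    the same trajectory to floating-point round-off.
    """
    if not math.isclose(forcing.dt, dt, rel_tol=1e-9):
        raise ValueError("forcing step does not match integration step")
    x0 = x0 or OscState()
    F = forcing.total
    if method == "affine":
        x1, x2 = _rk4_affine(params.gamma, params.omega0, F, (x0.x1, x0.x2), dt)
    elif method == "loop":
        x1, x2 = _rk4_reference(params.gamma, params.omega0, F, (x0.x1, x0.x2), dt)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.all(np.isfinite(x1)):
        raise FloatingPointError("oscillator state became non-finite")
    t = forcing.t0 + dt * np.arange(F.size + 1)
    pad = lambda a: np.concatenate([a, a[-1:]])
    return Trajectory(
        t=t, x1=x1, x2=x2,
        f_wake=pad(forcing.f_wake), f_peri=pad(forcing.f_peri),
        f_gamma=-params.gamma * x2, f_omega=-params.omega0 ** 2 * x1,
    )


def warmup(params: OscillatorParams, baseline_lma_day: np.ndarray,
           days: int = 20, dt: float = DT) -> OscState:
    """Initial state after spinning the model up on tiled baseline activity.

    The baseline day's 6-min LMA (240 per-step values covering 24 h, already
    SD-free) is replicated ``days`` times *before* time 0; the circadian
    force runs continuously through the warm-up so its phase at time 0 equals
    ``phi``.  Returns the oscillator state at the end of the warm-up, used as
    the initial condition for the experiment proper.
    """
    lma_day = np.asarray(baseline_lma_day, dtype=float)
    steps_per_day = round(24.0 / dt)
    if lma_day.size != steps_per_day:
        raise ValueError(
            f"baseline day must cover exactly 24 h ({steps_per_day} steps), "
            f"got {lma_day.size}"
        )
    F_lma = np.tile(lma_day, days)
    t0 = -24.0 * days
    t = t0 + dt * np.arange(F_lma.size)
    forcing = Forcing(t0=t0, dt=dt, f_wake=params.beta * F_lma,
                      f_peri=peri_force(t, params.A, params.phi, params.omega))
    traj = integrate_rk4(params, forcing, OscState(0.0, 0.0), dt=dt)
    return OscState(float(traj.x1[-1]), float(traj.x2[-1]))


def predict_observable(traj: Trajectory, intercept: float,
                       obs_start: float, obs_width: float, n_bins: int,
                       mode: str = "mean") -> BinnedSignal:
    """Model prediction of binned bioluminescence from a trajectory.

    ``mode="mean"`` (default) averages ``x1`` over each observation bin's
    integration grid points; ``mode="point"`` samples ``x1`` at the grid
    point nearest the bin midpoint.  Either way the intercept (equilibrium
    position) is added.
    """
    dt = float(traj.t[1] - traj.t[0])
    per = obs_width / dt
    per_i = round(per)
    if not math.isclose(per, per_i, rel_tol=1e-9):
        raise ValueError("observation width must be a multiple of the grid step")
    start_idx = (obs_start - traj.t[0]) / dt
    i0 = round(start_idx)
    if not math.isclose(start_idx, i0, rel_tol=0, abs_tol=1e-6):
        raise ValueError("observation grid does not align with trajectory grid")
    need = i0 + n_bins * per_i
    if i0 < 0 or need > traj.x1.size - 1:
        raise ValueError("trajectory does not cover the observation grid")
    if mode == "mean":
        seg = traj.x1[i0:need].reshape(n_bins, per_i)
        vals = intercept + seg.mean(axis=1)
    elif mode == "point":
        mid = i0 + per_i // 2 + np.arange(n_bins) * per_i
        vals = intercept + traj.x1[mid]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return BinnedSignal(start_time=obs_start, bin_width=obs_width,
                        values=vals, units="rel. bioluminescence")


def peri_only_solution(params: OscillatorParams) -> tuple[float, float]:
    """Steady-state sinusoid of the circadian-force-only model.

    With ``beta = 0`` the unperturbed oscillator settles on the particular
    solution ``x1(t) = R * sin(omega*t + phi - delta)`` with amplitude
    ``R = A / sqrt((omega0^2 - omega^2)^2 + (gamma*omega)^2)`` and phase lag
    ``delta = atan2(gamma*omega, omega0^2 - omega^2)``.  Returns ``(R, delta)``.
    """
    if params.beta != 0.0:
        raise ValueError("closed-form solution requires beta = 0")
    d1 = params.omega0 ** 2 - params.omega ** 2
    d2 = params.gamma * params.omega
    denom = math.hypot(d1, d2)
    if denom < 1e-12:
        raise ZeroDivisionError(
            "undamped resonance: omega -> omega0 with gamma -> 0 has no "
            "bounded steady state"
        )
    return params.A / denom, math.atan2(d2, d1)


def force_summary(traj: Trajectory, window: tuple[float, float]) -> dict[str, float]:
    """Time-averaged absolute force components (h^-2) over a window.

    Returns the mean absolute value of each component (wake, circadian,
    damping, string) and of their signed sum (the net force ``x2'``).
    """
    m = traj.window_mask(*window)
    if not m.any():
        raise ValueError("window does not intersect the trajectory")
    comps = {
        "wake": traj.f_wake[m],
        "peri": traj.f_peri[m],
        "gamma": traj.f_gamma[m],
        "omega": traj.f_omega[m],
    }
    out = {f"mean_abs_{k}": float(np.mean(np.abs(v))) for k, v in comps.items()}
    total = sum(comps.values())
    out["mean_abs_sum"] = float(np.mean(np.abs(total)))
    out["sum_of_mean_abs"] = float(sum(np.mean(np.abs(v)) for v in comps.values()))
    return out
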