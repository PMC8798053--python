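"""Parameter estimation and model comparison for the oscillator model.

The observed 30-min relative bioluminescence is fit by box-constrained
nonlinear least squares: the residual sum of squares (RSS) between the
predicted oscillator position (plus intercept) and the observations is
minimized over the free parameters.  Model variants drop one of the two
driving forces; variants are compared through the Bayesian information
criterion

    BIC = n*ln(RSS/n) + k*ln(n),   k = number of optimized parameters + 1,

and against an intercept-only flat model via an approximate Bayes factor.
Parameter uncertainty comes from a parametric (Monte-Carlo) bootstrap:
Gaussian noise at the estimated residual sd is added to the fitted
prediction, the model refit, and 95% CIs taken as empirical quantiles.

Fitting is multi-start (the first start from configurable initial values,
the rest drawn uniformly inside the bounds) because the phase parameter
creates local minima for single-start local optimizers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import BinnedSignal
from .oscillator import (DT, Forcing, OscState, OscillatorParams, OMEGA_PERI,
                         impute_sd_lma, integrate_rk4, peri_force, warmup)
from .protocols import Protocol

PARAM_NAMES = ("gamma", "omega0", "beta", "intercept", "A", "phi")

#: Generous physical ranges bracketing plausible estimates.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "gamma": (1e-4, 1.0),
    "omega0": (2 * math.pi / 40.0, 2 * math.pi / 12.0),
    "beta": (0.0, 1e-2),
    "intercept": (0.5, 1.5),
    "A": (0.0, 0.1),
    "phi": (0.0, 2 * math.pi),
}

DEFAULT_INIT: dict[str, float] = {
    "gamma": 0.02,
    "omega0": 2 * math.pi / 24.0,
    "beta": 5e-5,
    "intercept": 1.0,
    "A": 3e-3,
    "phi": math.pi,
}

#: Free-parameter sets per model variant.  ``flat`` is handled analytically.
VARIANT_FREE: dict[str, tuple[str, ...]] = {
    "full": PARAM_NAMES,
    "wake_only": ("gamma", "omega0", "beta", "intercept"),
    "peri_only": ("gamma", "omega0", "intercept", "A", "phi"),
    "flat": ("intercept",),
}
#: Dropped-force values pinned per variant.
VARIANT_FIXED: dict[str, dict[str, float]] = {
    "full": {},
    "wake_only": {"A": 0.0, "phi": 0.0},
    "peri_only": {"beta": 0.0},
    "flat": {"gamma": 0.1, "omega0": DEFAULT_INIT["omega0"], "beta": 0.0,
             "A": 0.0, "phi": 0.0},
}


@dataclass(frozen=True)
class FitSpec:
    """What to optimize: variant, free/fixed split, bounds, initial values."""

    variant: str = "full"
    fixed: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    init: dict[str, float] = field(default_factory=dict)
    omega: float = OMEGA_PERI
    n_starts: int = 8

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_FREE:
            raise ValueError(f"unknown variant {self.variant!r}")
        unknown = set(self.fixed) | set(self.bounds) | set(self.init)
        unknown -= set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names {sorted(unknown)}")

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(p for p in VARIANT_FREE[self.variant]
                     if p not in self.fixed)

    @property
    def k(self) -> int:
        """BIC parameter count: optimized parameters + 1."""
        return len(self.free_names) + 1

    def fixed_values(self) -> dict[str, float]:
        vals = dict(VARIANT_FIXED[self.variant])
        vals.update(self.fixed)
        return vals

    def bounds_for(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, DEFAULT_BOUNDS[name])

    def init_for(self, name: str) -> float:
        lo, hi = self.bounds_for(name)
        return min(max(self.init.get(name, DEFAULT_INIT[name]), lo), hi)


@dataclass(frozen=True)
class FitResult:
    """A fitted model with its goodness-of-fit and uncertainty summaries."""

    spec: FitSpec
    params: OscillatorParams
    rss: float
    n: int
    k: int
    bic: float
    bayes_factor_vs_flat: float | None
    ci95: dict[str, tuple[float, float]] | None
    n_starts: int
    seed: int | None
    start_rss: tuple[float, ...] = ()

    def summary_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"variant": self.spec.variant}
        for name in PARAM_NAMES:
            row[name] = getattr(self.params, name)
        row.update(rss=self.rss, n=self.n, k=self.k, bic=self.bic)
        if self.bayes_factor_vs_flat is not None:
            row["bayes_factor_vs_flat"] = self.bayes_factor_vs_flat
        return row


class OscFitProblem:
    """Precomputed fitting problem: observations, forcing inputs, alignment.

    Holds the imputed activity trace on the integration grid and the mapping
    from trajectory steps to observation bins, so each objective evaluation
    is a single integration plus a reshape.
    """

    def __init__(self, obs: BinnedSignal, lma: BinnedSignal,
                 protocol: Protocol | None = None,
                 baseline_mean_lma: float | None = None,
                 x0: OscState | None = None, use_warmup: bool = False,
                 predict_mode: str = "mean") -> None:
        if not math.isclose(lma.bin_width, DT, rel_tol=1e-9):
            raise ValueError("activity must be on the 6-min (0.1-h) grid")
        ratio = obs.bin_width / DT
        self.per = round(ratio)
        if not math.isclose(ratio, self.per, rel_tol=1e-9):
            raise ValueError("observation width must be a multiple of 0.1 h")
        if not obs.valid.any():
            raise ValueError("no valid observation bins")
        off = (obs.start_time - lma.start_time) / DT
        self.i0 = round(off)
        if not math.isclose(off, self.i0, rel_tol=0, abs_tol=1e-6) or self.i0 < 0:
            raise ValueError("observation grid does not align with activity grid")
        if self.i0 + obs.n_bins * self.per > lma.n_bins:
            raise ValueError("activity trace does not cover the observations")

        protocol = protocol or Protocol()
        if not protocol.is_empty:
            if baseline_mean_lma is None:
                if protocol.baseline is None:
                    raise ValueError("baseline_mean_lma required for SD imputation")
                sl = lma.window_slice(*protocol.baseline)
                baseline_mean_lma = float(lma.values[sl].mean())
            self.lma_values = impute_sd_lma(lma, protocol, baseline_mean_lma)
        else:
            self.lma_values = lma.values.astype(float)
        self.baseline_mean_lma = baseline_mean_lma
        self.t_steps = lma.times_h
        self.t0 = lma.start_time
        self.obs = obs
        self.protocol = protocol
        self.x0 = x0 or OscState()
        self.use_warmup = use_warmup
        self.predict_mode = predict_mode
        self.valid = obs.valid
        self.y = obs.values[self.valid]
        self.n = int(self.valid.sum())
        steps_per_day = round(24.0 / DT)
        self._warm_day = self.lma_values[:steps_per_day].copy()

    def predict(self, params: OscillatorParams) -> np.ndarray:
        """Model prediction for every observation bin (valid or not)."""
        forcing = Forcing(
            t0=self.t0, dt=DT,
            f_wake=params.beta * self.lma_values,
            f_peri=peri_force(self.t_steps, params.A, params.phi, params.omega),
        )
        x0 = warmup(params, self._warm_day) if self.use_warmup else self.x0
        traj = integrate_rk4(params, forcing, x0)
        x1 = traj.x1[self.i0:self.i0 + self.obs.n_bins * self.per]
        if self.predict_mode == "mean":
            pos = x1.reshape(self.obs.n_bins, self.per).mean(axis=1)
        else:
            pos = x1[self.per // 2::self.per][: self.obs.n_bins]
        return params.intercept + pos

    def residuals(self, params: OscillatorParams) -> np.ndarray:
        return self.predict(params)[self.valid] - self.y

    def rss(self, params: OscillatorParams) -> float:
        r = self.residuals(params)
        return float(r @ r)


def objective_rss(params: OscillatorParams, obs: BinnedSignal,
                  lma: BinnedSignal, protocol: Protocol | None = None,
                  **kw) -> tuple[float, int]:
    """RSS of the model against valid observation bins; returns ``(rss, n)``."""
    prob = OscFitProblem(obs, lma, protocol, **kw)
    return prob.rss(params), prob.n


def bic(rss: float, n: int, k: int) -> float:
    """Bayesian information criterion ``n*ln(RSS/n) + k*ln(n)``."""
    if n <= 0:
        raise ValueError("n must be positive")
    if rss <= 0:
        raise ValueError("BIC undefined for a zero (perfect-fit) RSS")
    return n * math.log(rss / n) + k * math.log(n)


def bayes_factor(bic_model: float, bic_flat: float) -> float:
    """Approximate Bayes factor of the model against the flat model.

    Computed as ``exp((BIC_flat - BIC_model)/2)`` so a model *better* than
    flat (lower BIC) gets BF > 1; >100 counts as decisive support.
    """
    arg = 0.5 * (bic_flat - bic_model)
    if arg > 700.0:
        return math.inf
    return math.exp(arg)


def fit_flat(obs: BinnedSignal) -> FitResult:
    """Intercept-only reference model, solved analytically."""
    y = obs.valid_values()
    n = y.size
    mean = float(y.mean())
    rss = float(np.sum((y - mean) ** 2))
    spec = FitSpec(variant="flat", n_starts=1)
    params = OscillatorParams(**{**VARIANT_FIXED["flat"], "intercept": mean},
                              omega=OMEGA_PERI)
    return FitResult(spec=spec, params=params, rss=rss, n=n, k=2,
                     bic=bic(rss, n, 2), bayes_factor_vs_flat=1.0,
                     ci95=None, n_starts=1, seed=None)


def _params_from_vector(theta: np.ndarray, free: tuple[str, ...],
                        fixed: dict[str, float], omega: float) -> OscillatorParams:
    vals = dict(fixed)
    vals.update(zip(free, theta))
    return OscillatorParams(omega=omega, **vals)


def _solve(problem: OscFitProblem, spec: FitSpec,
           theta0: np.ndarray) -> tuple[np.ndarray, float, bool]:
    free = spec.free_names
    fixed = spec.fixed_values()
    lo = np.array([spec.bounds_for(p)[0] for p in free])
    hi = np.array([spec.bounds_for(p)[1] for p in free])

    def resid(theta):
        return problem.residuals(_params_from_vector(theta, free, fixed,
                                                     spec.omega))

    sol = least_squares(resid, np.clip(theta0, lo, hi), bounds=(lo, hi),
                        x_scale="jac", xtol=1e-10, ftol=1e-10, gtol=1e-10)
    return sol.x, float(2.0 * sol.cost), bool(sol.success)


def fit_model(problem: OscFitProblem, spec: FitSpec | None = None,
              seed: int = 0, n_starts: int | None = None,
              with_flat: bool = True) -> FitResult:
    """Multi-start box-constrained least-squares fit of a model variant.

    The first start uses the spec's initial values; subsequent starts are
    drawn uniformly within the bounds from a seeded generator.  The best-RSS
    solution is kept.  The flat model is handled analytically.
    """
    spec = spec or FitSpec()
    if spec.variant == "flat":
        return fit_flat(problem.obs)
    n_starts = n_starts if n_starts is not None else spec.n_starts
    free = spec.free_names
    fixed = spec.fixed_values()
    rng = np.random.default_rng(seed)
    lo = np.array([spec.bounds_for(p)[0] for p in free])
    hi = np.array([spec.bounds_for(p)[1] for p in free])
    starts = [np.array([spec.init_for(p) for p in free])]
    starts += [rng.uniform(lo, hi) for _ in range(n_starts - 1)]

    best: tuple[np.ndarray, float] | None = None
    log: list[float] = []
    any_ok = False
    for theta0 in starts:
        try:
            theta, rss, ok = _solve(problem, spec, theta0)
        except FloatingPointError:
            log.append(math.inf)
            continue
        log.append(rss)
        any_ok = any_ok or ok
        if best is None or rss < best[1]:
            best = (theta, rss)
    if best is None or not any_ok:
        raise RuntimeError(f"all {n_starts} starts failed; per-start RSS: {log}")
    theta, rss = best
    params = _params_from_vector(theta, free, fixed, spec.omega)
    n, k = problem.n, spec.k
    # a numerically perfect fit has no finite BIC; flag it as -inf
    model_bic = bic(rss, n, k) if rss > 0 else -math.inf
    bf = None
    if with_flat:
        bf = bayes_factor(model_bic, fit_flat(problem.obs).bic)
    return FitResult(spec=spec, params=params, rss=rss, n=n, k=k,
                     bic=model_bic, bayes_factor_vs_flat=bf, ci95=None,
                     n_starts=n_starts, seed=seed, start_rss=tuple(log))


def residual_sd(fit: FitResult) -> float:
    """Residual noise estimate ``sqrt(RSS / (n - n_optimized))``."""
    dof = fit.n - (fit.k - 1)
    if dof <= 0:
        raise ValueError("not enough observations for a residual-sd estimate")
    return math.sqrt(fit.rss / dof)


def mc_confidence_intervals(fit: FitResult, problem: OscFitProblem,
                            n_sim: int = 500, seed: int = 0,
                            max_failure_frac: float = 0.10) -> FitResult:
    """Parametric-bootstrap 95% CIs for the free parameters.

    ``n_sim`` synthetic datasets are drawn as fitted prediction + Gaussian
    noise at the residual sd; each is refit from the point estimate (single
    start — the local-perturbation regime).  CIs are the empirical
    2.5%/97.5% quantiles of the refitted values.
    """
    if fit.spec.variant == "flat":
        raise ValueError("bootstrap CIs target the oscillator variants")
    sigma = residual_sd(fit)
    rng = np.random.default_rng(seed)
    free = fit.spec.free_names
    pred = problem.predict(fit.params)[problem.valid]
    theta_hat = np.array([getattr(fit.params, p) for p in free])
    draws: list[np.ndarray] = []
    failures = 0
    base_y = problem.y
    try:
        for _ in range(n_sim):
            problem.y = pred + rng.normal(0.0, sigma, pred.size)
            try:
                theta, _, ok = _solve(problem, fit.spec, theta_hat)
            except FloatingPointError:
                ok = False
            if not ok:
                failures += 1
                continue
            draws.append(theta)
    finally:
        problem.y = base_y
    if failures > max_failure_frac * n_sim:
        raise RuntimeError(
            f"{failures}/{n_sim} bootstrap refits failed to converge"
        )
    arr = np.vstack(draws)
    lo = np.quantile(arr, 0.025, axis=0)
    hi = np.quantile(arr, 0.975, axis=0)
    ci = {p: (float(l), float(h)) for p, l, h in zip(free, lo, hi)}
    return FitResult(**{**fit.__dict__, "ci95": ci})


def fit_sequence_scnx_then_2hOnOff(problem_scnx: OscFitProblem,
                                   problem_2h: OscFitProblem,
                                   seed: int = 0,
                                   n_starts: int | None = None
                                   ) -> tuple[FitResult, FitResult]:
    """Two-stage fit: shared dynamics from the lesioned animals, then the
    experiment-specific circadian force for the intact ones.

    Stage 1 fits the full model (6 free parameters) on the SCN-lesioned
    experiment.  Stage 2 freezes the damping constant, natural frequency and
    wake-force coefficient at the stage-1 estimates and refits only the
    intercept, amplitude and phase of the circadian force (k = 4) on the
    2hOnOff experiment.
    """
    fit1 = fit_model(problem_scnx, FitSpec(variant="full"), seed=seed,
                     n_starts=n_starts)
    frozen = {"gamma": fit1.params.gamma, "omega0": fit1.params.omega0,
              "beta": fit1.params.beta}
    spec2 = FitSpec(variant="full", fixed=frozen,
                    init={"intercept": fit1.params.intercept,
                          "A": fit1.params.A, "phi": fit1.params.phi})
    fit2 = fit_model(problem_2h, spec2, seed=seed + 1, n_starts=n_starts)
    return fit1, fit2
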