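"""Temperature-regulated host-virus population dynamics.

A spatially homogeneous habitat of carrying capacity ``C`` holds
nonsusceptible cells ``B+``, susceptible cells ``B-``, lysogens ``B_i^-``
(infected by ``i = 1..I_max`` distinct viral species) and free virus ``P``.
Cells grow logistically, scaled by a Gaussian temperature-fitness term
centred on the optimal growth temperature (OGT). Virus adsorbs at rate
``delta``; the number of distinct viral species entering a susceptible cell
is Poisson with mean ``lambda = (lambda0 + P/N) * B-/N``. A fraction
``alpha`` of infections lysogenize; the rest lyse immediately, releasing
``beta`` particles. Lysogens are induced to lyse at rate ``xi(T) = xi0 *
max(f_h, f_c)`` where ``f_h``/``f_c`` are heat- and cold-activated sigmoid
switches. Virus release (both immediate lysis and induction) acts with a
latent-period delay ``tau``: the source terms of ``dP/dt`` are evaluated on
the state at ``t - tau``.

Model-based specialization of the host population is the reciprocal of the
lysogen-weighted mean multiplicity of infection,
``d = S / sum_i(i * B_i^-)`` with ``S = sum_i B_i^-``, in (0, 1]: a
population whose lysogens each carry a single viral species is maximally
specialized (d = 1).

The total cell density ``N`` is maintained algebraically as
``B+ + B- + sum_i B_i^-``; an integrated copy of the printed ``dN/dt`` is
carried along purely as a conservation diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

logger = logging.getLogger(__name__)

SwitchMode = Literal["both", "heat_only", "cold_only", "off"]

__all__ = [
    "ModelParams", "ModelState", "Trajectory", "SweepPoint",
    "ParameterError", "IntegrationError", "NoLysogensError",
    "logistic_growth", "temperature_fitness", "induction_rate",
    "infection_lambda", "poisson_multiplicity", "rhs", "simulate",
    "model_specialization", "grsr_sweep", "SCENARIOS", "scenario_params",
]


class ParameterError(ValueError):
    """Invalid model parameter."""


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last valid time."""

    def __init__(self, message: str, t_last: float):
        super().__init__(f"{message} (last valid t = {t_last:.6g})")
        self.t_last = t_last


class NoLysogensError(ValueError):
    """Model specialization is undefined when no lysogens exist (S = 0)."""


@dataclass(frozen=True)
class ModelParams:
    """Constants of the infection-dynamics model.

    Rates are per day, temperatures in degrees C, densities per unit volume.
    Defaults describe a temperate-phage system in which virus production is
    induction-dominated (high lysogenization fraction ``alpha``), with lytic
    switches half-activated at 37 degC (heat) and 4 degC (cold).
    """

    C: float = 1e7                 # carrying capacity (cells/volume)
    V_plus: float = 2.0            # max growth rate, nonsusceptible (1/day)
    V_minus: float = 2.0           # max growth rate, susceptible (1/day)
    T_plus: float = 30.0           # OGT of nonsusceptible cells (degC)
    T_minus: float = 30.0          # OGT of susceptible cells (degC)
    sigma_plus: float = 10.0       # temperature niche breadth (degC)
    sigma_minus: float = 10.0
    delta: float = 1e-7            # adsorption rate (volume/(particle day))
    alpha: float = 0.9             # lysogenization fraction
    beta: float = 50.0             # burst size (particles/cell)
    lambda0: float = 1.0           # basic mean number of infecting species
    xi0: float = 1.0               # induction rate constant (1/day)
    k: float = 2.0                 # switch steepness (1/degC)
    T_h: float = 37.0              # heat half-induction temperature (degC)
    T_c: float = 4.0               # cold half-induction temperature (degC)
    tau: float = 0.5               # latent period (days)
    T_env: float = 30.0            # environmental temperature (degC)
    I_max: int = 10                # multiplicity truncation
    switch_mode: SwitchMode = "both"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ParameterError("C must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError("alpha must lie in [0, 1]")
        if self.beta < 0:
            raise ParameterError("beta must be nonnegative")
        if self.sigma_plus <= 0 or self.sigma_minus <= 0:
            raise ParameterError("temperature niche breadths must be positive")
        if self.I_max < 1:
            raise ParameterError("I_max must be >= 1")
        for name in ("V_plus", "V_minus", "delta", "lambda0", "xi0", "tau"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if self.switch_mode not in ("both", "heat_only", "cold_only", "off"):
            raise ParameterError(f"unknown switch_mode {self.switch_mode!r}")


@dataclass(frozen=True)
class ModelState:
    """Compartment densities at one instant."""

    b_plus: float
    b_minus: float
    b_lysogen: np.ndarray      # B_i^- for i = 1..I_max
    p: float

    @property
    def n(self) -> float:
        return self.b_plus + self.b_minus + float(np.sum(self.b_lysogen))

    @property
    def s(self) -> float:
        return float(np.sum(self.b_lysogen))

    def to_vector(self) -> np.ndarray:
        return np.concatenate(([self.b_plus, self.b_minus],
                               np.asarray(self.b_lysogen, float), [self.p]))

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "ModelState":
        return cls(float(y[0]), float(y[1]), np.array(y[2:-1]), float(y[-1]))


# invasion-style start: resident nonsusceptible population, rare susceptible
# cells and rare free virus, no lysogens yet
DEFAULT_INIT = ModelState(b_plus=1e5, b_minus=1e3,
                          b_lysogen=np.zeros(10), p=1e3)


@dataclass(frozen=True)
class Trajectory:
    """Simulation output on a fixed grid, with diagnostics."""

    times: np.ndarray
    b_plus: np.ndarray
    b_minus: np.ndarray
    b_lysogen: np.ndarray       # shape (n_times, I_max)
    p: np.ndarray
    lam: np.ndarray
    xi: float
    conservation_residual: np.ndarray
    floored: int = 0            # number of negative values clamped to 0

    @property
    def n(self) -> np.ndarray:
        return self.b_plus + self.b_minus + self.b_lysogen.sum(axis=1)

    @property
    def s(self) -> np.ndarray:
        return self.b_lysogen.sum(axis=1)

    def d_series(self) -> np.ndarray:
        """Model specialization d at each output time (NaN where S = 0)."""
        weights = np.arange(1, self.b_lysogen.shape[1] + 1)
        tot = self.b_lysogen @ weights
        s = self.s
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(s > 0, s / np.where(tot > 0, tot, 1.0), np.nan)


@dataclass(frozen=True)
class SweepPoint:
    scenario: str
    switch_mode: str
    v_minus: float
    d: float                    # NaN when status != "ok"
    status: str                 # "ok" | "no_lysogens" | "failed"


def logistic_growth(N: float, V: float, C: float) -> float:
    """Per-capita logistic rate V (1 - N/C); negative above capacity."""
    if C <= 0:
        raise ParameterError("C must be positive")
    return V * (1.0 - N / C)


def temperature_fitness(T: float, T_opt: float, sigma: float) -> float:
    """Gaussian thermal performance exp(-(T - T_opt)^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    return float(np.exp(-((T - T_opt) ** 2) / (2.0 * sigma**2)))


def induction_rate(T: float, params: ModelParams) -> float:
    """Temperature-gated induction xi(T) = xi0 * max(f_h, f_c).

    ``switch_mode`` restricts which sigmoid switches participate; "off"
    removes induction entirely (the no-lytic-switch variant).
    """
    if params.switch_mode == "off":
        return 0.0
    f_h = 1.0 / (1.0 + np.exp(np.clip(params.k * (params.T_h - T), -500, 500)))
    f_c = 1.0 / (1.0 + np.exp(np.clip(params.k * (T - params.T_c), -500, 500)))
    if params.switch_mode == "heat_only":
        f = f_h
    elif params.switch_mode == "cold_only":
        f = f_c
    else:
        f = max(f_h, f_c)
    return float(params.xi0 * f)


def infection_lambda(P: float, B_minus: float, N: float, lambda0: float) -> float:
    """Mean number of viral species infecting a susceptible cell,
    lambda = (lambda0 + P/N) * B-/N; 0 when no cells exist."""
    if N <= 0:
        return 0.0
    return max(0.0, (lambda0 + P / N) * (B_minus / N))


def poisson_multiplicity(lam: float, I_max: int) -> np.ndarray:
    """Pr(X = i) for i = 0..I_max, with Pr(X > I_max) folded into the top
    bin so the vector sums to 1 exactly."""
    if lam < 0:
        raise ParameterError("lambda must be nonnegative")
    pr = np.empty(I_max + 1)
    pr[0] = np.exp(-lam)
    for i in range(1, I_max + 1):
        pr[i] = pr[i - 1] * lam / i
    pr[-1] = max(0.0, 1.0 - pr[:-1].sum())
    return pr


def _derivatives(
    y: np.ndarray, y_delayed: np.ndarray, params: ModelParams, xi: float
) -> np.ndarray:
    """Compartment derivatives; virus-release sources use the delayed state."""
    undelayed = y_delayed is y
    y = np.maximum(y, 0.0)
    y_delayed = y if undelayed else np.maximum(y_delayed, 0.0)
    I = params.I_max
    b_plus, b_minus, lys, P = y[0], y[1], y[2:2 + I], y[2 + I]
    N = b_plus + b_minus + lys.sum()

    theta_p = temperature_fitness(params.T_env, params.T_plus, params.sigma_plus)
    theta_m = temperature_fitness(params.T_env, params.T_minus, params.sigma_minus)
    phi_p = logistic_growth(N, params.V_plus, params.C)
    phi_m = logistic_growth(N, params.V_minus, params.C)

    lam = infection_lambda(P, b_minus, N, params.lambda0)
    pr = poisson_multiplicity(lam, I)
    inf_flux = params.delta * b_minus * P

    db_plus = phi_p * theta_p * b_plus
    db_minus = phi_m * theta_m * b_minus - inf_flux + pr[0] * inf_flux
    dlys = phi_m * theta_m * lys + params.alpha * pr[1:] * inf_flux - xi * lys

    # virus release is delayed by the latent period tau
    if undelayed:
        lys_d, pr_d, inf_flux_d = lys, pr, inf_flux
    else:
        bd_minus = y_delayed[1]
        lys_d, P_d = y_delayed[2:2 + I], y_delayed[2 + I]
        N_d = y_delayed[0] + bd_minus + lys_d.sum()
        lam_d = infection_lambda(P_d, bd_minus, N_d, params.lambda0)
        pr_d = poisson_multiplicity(lam_d, I)
        inf_flux_d = params.delta * bd_minus * P_d
    lysis_src = (1.0 - params.alpha) * params.beta * inf_flux_d * pr_d[1:].sum()
    induction_src = params.beta * xi * lys_d.sum()
    dP = lysis_src + induction_src - params.delta * N * P

    dN = db_plus + db_minus + dlys.sum()   # conservation diagnostic
    return np.concatenate(([db_plus, db_minus], dlys, [dP, dN]))


def rhs(
    state: ModelState,
    t: float,
    params: ModelParams,
    history: Callable[[float], ModelState] | None = None,
) -> np.ndarray:
    """Derivatives [dB+, dB-, dB_1..dB_Imax, dP] at time t.

    ``history`` maps a time to the model state there; it is consulted at
    ``t - tau`` for the virus-release source terms. With no history (or
    tau = 0) the current state is used, giving plain ODE dynamics.
    """
    y = state.to_vector()
    if not np.isfinite(y).all():
        raise IntegrationError("non-finite state", t)
    if history is not None and params.tau > 0:
        y_del = history(t - params.tau).to_vector()
    else:
        y_del = y
    xi = induction_rate(params.T_env, params)
    return _derivatives(y, y_del, params, xi)[:-1]


class _History:
    """Piecewise dense history for the method of steps; constant before t0."""

    def __init__(self, y0: np.ndarray, t0: float = 0.0):
        self.y0 = y0
        self.t0 = t0
        self.segments: list[tuple[float, float, Callable]] = []

    def add(self, t_lo: float, t_hi: float, sol: Callable) -> None:
        self.segments.append((t_lo, t_hi, sol))

    def __call__(self, t: float) -> np.ndarray:
        if t <= self.t0 or not self.segments:
            return self.y0
        for t_lo, t_hi, sol in reversed(self.segments):
            if t_lo <= t <= t_hi + 1e-12:
                return np.asarray(sol(min(t, t_hi)))
        return self.y0


def simulate(
    params: ModelParams,
    init: ModelState | None = None,
    t_end: float = 30.0,
    dt_out: float = 0.1,
) -> Trajectory:
    """Integrate the model on [0, t_end] and sample every ``dt_out`` days.

    With ``tau > 0`` the delay is handled by the method of steps: the
    horizon is integrated in chunks of length tau, each chunk reading the
    delayed state from the dense solution of earlier chunks (constant
    pre-history equal to ``init``). ``tau = 0`` is a single initial-value
    integration. Compartments are floored at zero on output (flooring
    counted in the trajectory).
    """
    if t_end <= 0:
        raise ParameterError("t_end must be positive")
    if init is None:
        init = replace_lysogen_size(DEFAULT_INIT, params.I_max)
    if len(init.b_lysogen) != params.I_max:
        raise ParameterError(
            f"init has {len(init.b_lysogen)} lysogen bins, I_max = {params.I_max}"
        )
    y0 = np.concatenate((init.to_vector(), [init.n]))  # trailing N integral
    if (y0 < 0).any():
        raise ParameterError("initial state must be nonnegative")
    xi = induction_rate(params.T_env, params)
    hist = _History(y0)

    def f(t: float, y: np.ndarray) -> np.ndarray:
        y_del = hist(t - params.tau) if params.tau > 0 else y
        return _derivatives(y, y_del, params, xi)

    atol = np.full(y0.size, 1e-10 * params.C)
    chunk = params.tau if params.tau > 0 else t_end
    t_lo = 0.0
    sols = []
    while t_lo < t_end - 1e-12:
        t_hi = min(t_lo + chunk, t_end)
        sol = solve_ivp(f, (t_lo, t_hi), y0, method="RK45",
                        rtol=1e-8, atol=atol, dense_output=True)
        if not sol.success:
            raise IntegrationError(f"integrator failed: {sol.message}",
                                   float(sol.t[-1]))
        if not np.isfinite(sol.y[:, -1]).all():
            raise IntegrationError("non-finite state", float(sol.t[-1]))
        hist.add(t_lo, t_hi, sol.sol)
        sols.append((t_lo, t_hi, sol.sol))
        y0 = sol.y[:, -1]
        t_lo = t_hi

    times = np.arange(0.0, t_end + dt_out / 2, dt_out)
    Y = np.empty((times.size, y0.size))
    for idx, t in enumerate(times):
        for t_a, t_b, s in sols:
            if t_a - 1e-12 <= t <= t_b + 1e-12:
                Y[idx] = s(min(max(t, t_a), t_b))
                break
        else:
            Y[idx] = hist(t)
    floored = int((Y[:, :-1] < 0).sum())
    if floored:
        logger.debug("floored %d negative compartment values at output", floored)
    Y[:, :-1] = np.maximum(Y[:, :-1], 0.0)

    I = params.I_max
    b_plus, b_minus = Y[:, 0], Y[:, 1]
    lys, P, n_int = Y[:, 2:2 + I], Y[:, 2 + I], Y[:, 3 + I]
    n_alg = b_plus + b_minus + lys.sum(axis=1)
    residual = np.abs(n_int - n_alg) / np.maximum(n_alg, 1e-300)
    lam = np.array([
        infection_lambda(P[i], b_minus[i], n_alg[i], params.lambda0)
        for i in range(times.size)
    ])
    return Trajectory(times=times, b_plus=b_plus, b_minus=b_minus,
                      b_lysogen=lys, p=P, lam=lam, xi=xi,
                      conservation_residual=residual, floored=floored)


def replace_lysogen_size(state: ModelState, I_max: int) -> ModelState:
    """Return ``state`` with the lysogen vector resized (zero padded/truncated)."""
    lys = np.zeros(I_max)
    take = min(I_max, len(state.b_lysogen))
    lys[:take] = np.asarray(state.b_lysogen)[:take]
    return ModelState(state.b_plus, state.b_minus, lys, state.p)


def model_specialization(state: ModelState) -> float:
    """Specialization d = 1 / (lysogen-weighted mean multiplicity), in
    [1/I_max, 1]; raises :class:`NoLysogensError` when S = 0."""
    lys = np.asarray(state.b_lysogen, float)
    s = lys.sum()
    if s <= 0:
        raise NoLysogensError("no lysogens (S = 0); d undefined")
    mean_moi = float(np.sum(lys * np.arange(1, lys.size + 1)) / s)
    return 1.0 / mean_moi


def _load_scenarios() -> dict[str, dict[str, float]]:
    import yaml
    from importlib.resources import files

    text = (files("grsr") / "configs" / "scenarios.yaml").read_text()
    return yaml.safe_load(text)


# OGT / environmental temperature pairs of the three thermal guilds,
# shipped as a structured configuration file
SCENARIOS: dict[str, dict[str, float]] = _load_scenarios()


def scenario_params(base: ModelParams, scenario: str,
                    switch_mode: SwitchMode | None = None) -> ModelParams:
    """Model parameters for a named thermal-guild scenario."""
    if scenario not in SCENARIOS:
        raise ParameterError(
            f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    overrides = dict(SCENARIOS[scenario])
    if switch_mode is not None:
        overrides["switch_mode"] = switch_mode
    return replace(base, **overrides)


def grsr_sweep(
    params: ModelParams,
    growth_rates: Sequence[float],
    scenario: str = "custom",
    init: ModelState | None = None,
    t_end: float = 30.0,
    dt_out: float = 0.1,
    steady_fraction: float = 0.1,
) -> list[SweepPoint]:
    """Model-based GrSR curve: for each susceptible-cell growth rate
    ``V_minus``, simulate and report d averaged over the final
    ``steady_fraction`` of the trajectory.

    Failed points are marked and the sweep continues.
    """
    gr = np.asarray(growth_rates, float)
    if (gr <= 0).any():
        raise ParameterError("growth rates must be positive")
    if not np.all(np.diff(gr) >= 0):
        raise ParameterError("growth rates must be sorted ascending")
    points = []
    for v in gr:
        p = replace(params, V_minus=float(v))
        try:
            traj = simulate(p, init=init, t_end=t_end, dt_out=dt_out)
        except (IntegrationError, ParameterError) as exc:
            logger.warning("sweep point V_minus=%.4g failed: %s", v, exc)
            points.append(SweepPoint(scenario, params.switch_mode, float(v),
                                     float("nan"), "failed"))
            continue
        n_tail = max(1, int(np.ceil(steady_fraction * traj.times.size)))
        d_tail = traj.d_series()[-n_tail:]
        if np.isnan(d_tail).all():
            points.append(SweepPoint(scenario, params.switch_mode, float(v),
                                     float("nan"), "no_lysogens"))
        else:
            points.append(SweepPoint(scenario, params.switch_mode, float(v),
                                     float(np.nanmean(d_tail)), "ok"))
    return points
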