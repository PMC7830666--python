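"""Seed-controlled simulators for four benchmark chaotic systems.

The package validates its Lyapunov machinery on the classic test bed of
nonlinear dynamics: the logistic and Henon maps (discrete time) and the
Lorenz and Rossler attractors (continuous time, integrated with fixed-step
fourth-order Runge-Kutta and sampled through the x coordinate). Each system
is simulated with its canonical chaotic parameter set, and zero-mean
Gaussian noise can be injected to emulate the random component of
physiological signals.

Reference largest Lyapunov exponents for the canonical parameter sets
(per unit time): logistic 0.69, Henon 0.42, Lorenz 1.50, Rossler 0.09.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import numpy as np

from .errors import OrbitDivergenceError, ParameterError
from .series import TimeSeries

__all__ = [
    "SystemSpec",
    "SYSTEM_DEFAULTS",
    "REFERENCE_LLE",
    "iterate_logistic",
    "iterate_henon",
    "integrate_flow",
    "add_noise",
    "simulate",
]

#: canonical chaotic parameter sets, sampling periods and transient lengths
SYSTEM_DEFAULTS: dict[str, dict[str, Any]] = {
    "logistic": {"params": {"mu": 4.0}, "dt": 1.0, "n_transient": 1000},
    "henon": {"params": {"a": 1.4, "b": 0.3}, "dt": 1.0, "n_transient": 1000},
    "lorenz": {"params": {"sigma": 10.0, "R": 28.0, "b": 8.0 / 3.0},
               "dt": 0.01, "n_transient": 10_000},
    "rossler": {"params": {"a": 0.15, "b": 0.20, "c": 10.0},
                "dt": 0.1, "n_transient": 10_000},
}

#: literature values of the largest Lyapunov exponent, 1/s, for the defaults
REFERENCE_LLE = {"logistic": 0.69, "henon": 0.42, "lorenz": 1.50, "rossler": 0.09}

_HENON_ESCAPE = 1e6  # |x| beyond this means the orbit left the attractor basin


@dataclass(frozen=True)
class SystemSpec:
    """A fully specified simulation request for one benchmark system."""

    name: str
    params: Mapping[str, float] = field(default_factory=dict)
    dt: float | None = None
    n_transient: int | None = None
    n_samples: int = 5000
    seed: int | None = None

    def __post_init__(self):
        if self.name not in SYSTEM_DEFAULTS:
            raise ParameterError(
                f"unknown system {self.name!r}; choose from {sorted(SYSTEM_DEFAULTS)}")
        defaults = SYSTEM_DEFAULTS[self.name]
        params = {**defaults["params"], **dict(self.params)}
        object.__setattr__(self, "params", params)
        if self.dt is None:
            object.__setattr__(self, "dt", defaults["dt"])
        if self.n_transient is None:
            object.__setattr__(self, "n_transient", defaults["n_transient"])
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.n_samples < 100:
            raise ParameterError("n_samples must be at least 100")
        if self.n_transient < 0:
            raise ParameterError("n_transient must be non-negative")


def iterate_logistic(x0: float, mu: float = 4.0, n: int = 1) -> TimeSeries:
    """Iterate the logistic map x_{i+1} = mu * x_i * (1 - x_i).

    Returns ``x0`` followed by ``n`` iterates (length n + 1), with dt = 1 s.
    ``x0`` must lie strictly inside (0, 1); for mu = 4 the orbit then stays
    in [0, 1] forever.
    """
    if not (np.isfinite(x0) and 0.0 < x0 < 1.0):
        raise ParameterError(f"x0 must lie in the open interval (0, 1), got {x0}")
    if not np.isfinite(mu):
        raise ParameterError("mu must be finite")
    if n < 1:
        raise ParameterError("n must be >= 1")
    x = np.empty(n + 1)
    x[0] = x0
    for i in range(n):
        x[i + 1] = mu * x[i] * (1.0 - x[i])
    return TimeSeries(x, dt=1.0, meta={"system": "logistic", "mu": mu, "x0": x0})


def iterate_henon(x0: float, y0: float, a: float = 1.4, b: float = 0.3,
                  n: int = 1) -> TimeSeries:
    """Iterate the Henon map and return the x-coordinate sequence.

        x_{i+1} = 1 - a x_i^2 + y_i,   y_{i+1} = b x_i

    Returns ``x0`` followed by ``n`` iterates (length n + 1), dt = 1 s.
    Raises :class:`OrbitDivergenceError` (naming the step) if the orbit
    escapes |x| > 1e6, which signals a non-attractor parameter choice.
    """
    if not all(np.isfinite(v) for v in (x0, y0, a, b)):
        raise ParameterError("x0, y0, a, b must all be finite")
    if n < 1:
        raise ParameterError("n must be >= 1")
    xs = np.empty(n + 1)
    x, y = float(x0), float(y0)
    xs[0] = x
    for i in range(n):
        x, y = 1.0 - a * x * x + y, b * x
        if not math.isfinite(x) or abs(x) > _HENON_ESCAPE:
            raise OrbitDivergenceError(
                f"Henon orbit escaped (|x| > {_HENON_ESCAPE:g}) at step {i + 1}",
                step=i + 1)
        xs[i + 1] = x
    return TimeSeries(xs, dt=1.0,
                      meta={"system": "henon", "a": a, "b": b, "x0": x0, "y0": y0})


def _lorenz_rhs(state: np.ndarray, sigma: float, R: float, b: float) -> np.ndarray:
    x, y, z = state
    return np.array([sigma * (y - x), x * (R - z) - y, x * y - b * z])


def _rossler_rhs(state: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    x, y, z = state
    return np.array([-y - z, x + a * y, b + z * (x - c)])


def rk4_step(f: Callable[[np.ndarray], np.ndarray], state: np.ndarray,
             dt: float) -> np.ndarray:
    """One classical fourth-order Runge-Kutta step of size dt."""
    k1 = f(state)
    k2 = f(state + 0.5 * dt * k1)
    k3 = f(state + 0.5 * dt * k2)
    k4 = f(state + dt * k3)
    return state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate_flow(spec: SystemSpec, initial_state=None) -> TimeSeries:
    """Integrate the Lorenz or Rossler flow with fixed-step RK4.

    The first ``spec.n_transient`` steps are discarded and the x coordinate
    of the next ``spec.n_samples`` states is returned, sampled every
    ``spec.dt`` seconds. Default initial state is (1, 1, 1).
    """
    if spec.name == "lorenz":
        p = spec.params
        f = lambda s: _lorenz_rhs(s, p["sigma"], p["R"], p["b"])
    elif spec.name == "rossler":
        p = spec.params
        f = lambda s: _rossler_rhs(s, p["a"], p["b"], p["c"])
    else:
        raise ParameterError(
            f"integrate_flow handles 'lorenz' and 'rossler', not {spec.name!r}")
    state = np.array([1.0, 1.0, 1.0] if initial_state is None else initial_state,
                     dtype=float)
    if state.shape != (3,):
        raise ParameterError("initial_state must have three components")
    xs = np.empty(spec.n_samples)
    total = spec.n_transient + spec.n_samples
    for i in range(total):
        if i >= spec.n_transient:
            xs[i - spec.n_transient] = state[0]
        state = rk4_step(f, state, spec.dt)
        if not np.all(np.isfinite(state)):
            raise OrbitDivergenceError(
                f"{spec.name} state became non-finite at step {i + 1}", step=i + 1)
    return TimeSeries(xs, dt=spec.dt,
                      meta={"system": spec.name, **spec.params,
                            "n_transient": spec.n_transient})


def add_noise(ts: TimeSeries, sd: float, seed: int | None = None) -> TimeSeries:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation ``sd``.

    Length and dt are preserved; the same seed always yields the same output.
    """
    if not (np.isfinite(sd) and sd >= 0):
        raise ParameterError(f"noise sd must be >= 0, got {sd}")
    if sd == 0:
        return ts
    rng = np.random.default_rng(seed)
    noisy = ts.values + rng.normal(0.0, sd, size=len(ts))
    return ts.with_values(noisy, noise_sd=sd, noise_seed=seed)


def simulate(name: str, n_samples: int = 5000, seed: int | None = None,
             noise_sd: float = 0.0, **overrides: Any) -> TimeSeries:
    """Simulate a named benchmark system at its canonical chaotic parameters.

    Maps start from x0 drawn uniformly from (0.05, 0.95) with the given seed
    (Henon y0 = 0) and discard 1000 transient steps; flows start from
    (1, 1, 1) perturbed by a small seeded offset and discard 10000 RK4
    steps. The interior draw keeps map orbits away from unstable fixed
    points such as the logistic x = 0.5 preimage structure.

    ``overrides`` may adjust ``params``, ``dt`` or ``n_transient``.
    """
    spec = SystemSpec(name=name, n_samples=n_samples, seed=seed,
                      params=overrides.pop("params", {}), **overrides)
    rng = np.random.default_rng(seed)
    if name == "logistic":
        x0 = rng.uniform(0.05, 0.95)
        full = iterate_logistic(x0, spec.params["mu"],
                                spec.n_transient + n_samples - 1)
        ts = TimeSeries(full.values[spec.n_transient:], dt=spec.dt,
                        meta={**full.meta, "n_transient": spec.n_transient})
    elif name == "henon":
        x0 = rng.uniform(-0.5, 0.5)
        full = iterate_henon(x0, 0.0, spec.params["a"], spec.params["b"],
                             spec.n_transient + n_samples - 1)
        ts = TimeSeries(full.values[spec.n_transient:], dt=spec.dt,
                        meta={**full.meta, "n_transient": spec.n_transient})
    else:
        start = np.array([1.0, 1.0, 1.0]) + rng.uniform(-0.1, 0.1, size=3)
        ts = integrate_flow(spec, initial_state=start)
    ts = ts.with_values(ts.values, seed=seed, n_samples=n_samples)
    if noise_sd > 0:
        noise_seed = None if seed is None else seed + 1_000_003
        ts = add_noise(ts, noise_sd, seed=noise_seed)
    return ts
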