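"""Fixed-step time integration schemes.

Each scheme advances a state array one step ``dt`` given a frozen
right-hand-side ``f`` (the model derivative with coupling, local input and
any delayed terms held constant over the step) and an optional additive
``drive`` (stimulation), which is added to every evaluation of ``f``.

Deterministic: Euler, Heun (explicit trapezoidal), classical RK4 (ODEs
only — used for phase-plane trajectories).  Stochastic: Euler–Maruyama and
stochastic Heun; the Heun corrector reuses the predictor's Wiener
increment (Stratonovich-consistent construction), so zero noise intensity
degenerates exactly to the deterministic scheme.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "Integrator",
    "EulerDeterministic",
    "HeunDeterministic",
    "RungeKutta4",
    "EulerStochastic",
    "HeunStochastic",
    "convergence_order",
    "INTEGRATOR_REGISTRY",
]

Dfun = Callable[[np.ndarray], np.ndarray]


class Integrator:
    stochastic = False

    def __init__(self, dt: float = 0.0625):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.dt = dt
        self.noise = None

    def step(self, x: np.ndarray, f: Dfun, drive=0.0) -> np.ndarray:
        raise NotImplementedError

    def configure_noise(self, shape, stream) -> None:
        pass


class EulerDeterministic(Integrator):
    def step(self, x, f, drive=0.0):
        return x + self.dt * (f(x) + drive)


class HeunDeterministic(Integrator):
    def step(self, x, f, drive=0.0):
        k1 = f(x) + drive
        inter = x + self.dt * k1
        return x + self.dt / 2.0 * (k1 + f(inter) + drive)


class RungeKutta4(Integrator):
    """Classical 4th-order Runge–Kutta; deterministic problems only."""

    def step(self, x, f, drive=0.0):
        dt = self.dt
        k1 = f(x) + drive
        k2 = f(x + dt / 2.0 * k1) + drive
        k3 = f(x + dt / 2.0 * k2) + drive
        k4 = f(x + dt * k3) + drive
        return x + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


class _StochasticMixin:
    stochastic = True

    def __init__(self, dt: float = 0.0625, noise=None):
        Integrator.__init__(self, dt)
        if noise is None:
            from .noise import WhiteNoise

            noise = WhiteNoise()
        self.noise = noise

    def configure_noise(self, shape, stream) -> None:
        self.noise.configure(shape, self.dt, stream)


class EulerStochastic(_StochasticMixin, Integrator):
    def step(self, x, f, drive=0.0):
        z = self.noise.increment(x)
        return x + self.dt * (f(x) + drive) + z


class HeunStochastic(_StochasticMixin, Integrator):
    """Stochastic Heun: the same Wiener increment enters the predictor and
    the corrector, so D = 0 reproduces deterministic Heun bit-for-bit."""

    def step(self, x, f, drive=0.0):
        z = self.noise.increment(x)
        k1 = f(x) + drive
        inter = x + self.dt * k1 + z
        return x + self.dt / 2.0 * (k1 + f(inter) + drive) + z


def convergence_order(
    integrator_factory: Callable[[float], Integrator],
    dt: float = 0.05,
    t_end: float = 1.0,
    y0: float = 1.0,
    rate: float = -1.0,
) -> float:
    """Empirical order of a scheme on the linear test problem dy/dt = rate*y.

    Richardson estimate: integrate over ``t_end`` at steps ``dt`` and
    ``dt/2``, compare the endpoint errors against the exact exponential and
    return ``log2(err(dt) / err(dt/2))``.
    """
    exact = y0 * np.exp(rate * t_end)

    def endpoint_error(h: float) -> float:
        integ = integrator_factory(h)
        n = int(round(t_end / h))
        y = np.full((1, 1, 1), float(y0))
        f = lambda x: rate * x
        for _ in range(n):
            y = integ.step(y, f)
        return abs(float(y[0, 0, 0]) - exact)

    e1, e2 = endpoint_error(dt), endpoint_error(dt / 2.0)
    return float(np.log2(e1 / e2))


def build_integrator(scheme: str, dt: float, stochastic: bool = False, noise=None) -> Integrator:
    scheme = scheme.lower()
    if scheme == "rk4":
        if stochastic:
            raise ConfigurationError("rk4 is deterministic-only")
        return RungeKutta4(dt)
    table = {
        ("euler", False): EulerDeterministic,
        ("euler", True): EulerStochastic,
        ("heun", False): HeunDeterministic,
        ("heun", True): HeunStochastic,
    }
    try:
        cls = table[(scheme, stochastic)]
    except KeyError:
        raise ConfigurationError(f"unknown integration scheme: {scheme!r}") from None
    return cls(dt, noise) if stochastic else cls(dt)


INTEGRATOR_REGISTRY = {
    "euler": EulerDeterministic,
    "heun": HeunDeterministic,
    "rk4": RungeKutta4,
    "euler_stochastic": EulerStochastic,
    "heun_stochastic": HeunStochastic,
}
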