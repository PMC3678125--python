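"""Reproducible noise processes for stochastic integration.

Random numbers come from independently seedable streams
(:func:`make_stream`, a numpy PCG64 generator); the full stream state can
be saved and restored so that interrupted stochastic simulations continue
bit-exactly.

White noise contributes an increment with variance ``2*D*dt`` per step and
state variable (``D`` is the per-state-variable intensity).  Colored noise
is an Ornstein–Uhlenbeck process with correlation time ``tau_c`` advanced
by its exact update (no Euler discretisation of the noise itself), with
stationary variance ``D/tau_c``; its per-step contribution is ``eta(t)*dt``.

Multiplicative noise scales the increment by a user-supplied function of
the state (default ``g(x) = x``), evaluated at the pre-step state.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = [
    "make_stream",
    "get_stream_state",
    "set_stream_state",
    "WhiteNoise",
    "ColoredNoise",
    "MultiplicativeNoise",
]


def make_stream(seed: int | None) -> np.random.Generator:
    """Independently seeded random stream (PCG64)."""
    return np.random.default_rng(seed)


def get_stream_state(stream: np.random.Generator) -> dict:
    return stream.bit_generator.state


def set_stream_state(stream: np.random.Generator, state: dict) -> None:
    stream.bit_generator.state = state


class WhiteNoise:
    """Additive Gaussian white noise with per-state-variable intensity D."""

    is_multiplicative = False

    def __init__(self, nsig: float | np.ndarray = 1.0):
        nsig = np.atleast_1d(np.asarray(nsig, dtype=float))
        if np.any(nsig < 0):
            raise ValueError("noise intensity D must be non-negative")
        self.nsig = nsig
        self.shape: tuple[int, ...] | None = None

    def configure(self, shape: tuple[int, ...], dt: float, stream: np.random.Generator):
        """``shape`` is the state-array shape [n_nodes, n_svar, n_modes]."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        n_svar = shape[1]
        if self.nsig.size == 1:
            d = np.full(n_svar, self.nsig[0])
        elif self.nsig.size == n_svar:
            d = self.nsig
        else:
            raise ValueError(f"nsig must have length 1 or {n_svar}")
        self._d = d[None, :, None]
        self.shape = shape
        self.dt = dt
        self.stream = stream
        return self

    def increment(self, state: np.ndarray) -> np.ndarray:
        return np.sqrt(2.0 * self._d * self.dt) * self.stream.standard_normal(self.shape)

    # state beyond the stream (none for white noise)
    def get_state(self):
        return None

    def set_state(self, state) -> None:
        pass


class ColoredNoise(WhiteNoise):
    """Ornstein–Uhlenbeck (exponentially correlated) noise.

    ``<eta(t) eta(s)> = (D/tau_c) * exp(-|t-s|/tau_c)``; the process is
    advanced by the exact update ``eta' = rho*eta + sqrt(D/tau_c*(1-rho^2))*xi``
    with ``rho = exp(-dt/tau_c)``, initialised from its stationary law.
    """

    def __init__(self, nsig: float | np.ndarray = 1.0, tau_c: float = 10.0):
        super().__init__(nsig)
        if tau_c <= 0:
            raise ValueError("correlation time tau_c must be positive")
        self.tau_c = tau_c

    def configure(self, shape, dt, stream):
        super().configure(shape, dt, stream)
        self._rho = np.exp(-dt / self.tau_c)
        self._sigma_stat = np.sqrt(self._d / self.tau_c)
        self._eta = self._sigma_stat * stream.standard_normal(shape)
        return self

    def increment(self, state: np.ndarray) -> np.ndarray:
        rho = self._rho
        self._eta = rho * self._eta + self._sigma_stat * np.sqrt(1.0 - rho**2) * \
            self.stream.standard_normal(self.shape)
        return self._eta * self.dt

    def get_state(self):
        return None if self.shape is None else self._eta.copy()

    def set_state(self, state) -> None:
        if state is not None:
            self._eta = np.array(state, dtype=float)


class MultiplicativeNoise:
    """Wraps a base noise process; the increment is scaled by ``g(state)``."""

    is_multiplicative = True

    def __init__(self, base: WhiteNoise | None = None,
                 g: Callable[[np.ndarray], np.ndarray] | None = None):
        self.base = base if base is not None else WhiteNoise()
        self.g = g if g is not None else (lambda x: x)

    def configure(self, shape, dt, stream):
        self.base.configure(shape, dt, stream)
        return self

    @property
    def shape(self):
        return self.base.shape

    def increment(self, state: np.ndarray) -> np.ndarray:
        return self.g(state) * self.base.increment(state)

    def get_state(self):
        return self.base.get_state()

    def set_state(self, state) -> None:
        self.base.set_state(state)
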