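"""Neural-mass models: the local (per-node) dynamics of the network.

Each model is a system of first-order ODEs for the mean activity of a
neuronal population.  The network state is a rank-3 array
``[n_nodes, n_svar, n_modes]``; a model's ``dfun`` maps a state array plus
the long-range coupling input to the time-derivative array of identical
shape.  Model parameters may be scalars (applied to every node) or
per-node arrays (spatialised parameters).

Conventions
-----------
* Time is in milliseconds throughout.
* ``coupling`` passed to ``dfun`` has shape ``[n_nodes, n_cvar, n_modes]``
  where the coupling variables are the state variables listed in
  ``coupling_variables``; it already includes any instantaneous local
  (surface) coupling.  Each model documents the term it enters.
* Stimulation is a separate additive drive handled by the integrator, on
  the state variable indexed by ``stimulus_variable``.
"""

from __future__ import annotations

import math

import numpy as np

from .exceptions import DimensionError

__all__ = [
    "Model",
    "Generic2dOscillator",
    "WilsonCowan",
    "JansenRit",
    "ReducedWongWang",
    "StefanescuJirsa2D",
    "spatialize_parameter",
    "random_initial_state",
    "MODEL_REGISTRY",
    "GENERIC_2D_DEMO_PARAMS",
]


def spatialize_parameter(value, n_nodes: int) -> np.ndarray:
    """Broadcast a scalar/length-1 parameter to ``n_nodes``; pass through
    a length-``n_nodes`` array; reject anything else."""
    arr = np.asarray(value, dtype=float).ravel()
    if arr.size == 1:
        return np.full(n_nodes, arr[0])
    if arr.size == n_nodes:
        return arr.copy()
    raise DimensionError(
        f"parameter array has length {arr.size}; expected 1 or {n_nodes}"
    )


class Model:
    """Base class: holds parameters, spatialises them at configure time."""

    n_svar: int = 0
    n_modes: int = 1
    parameter_defaults: dict[str, float] = {}
    #: per-state-variable [low, high] used for random initial conditions
    state_ranges: list[tuple[float, float]] = []
    variables_of_interest: list[int] = [0]
    coupling_variables: list[int] = [0]
    stimulus_variable: int = 0

    def __init__(self, **params):
        unknown = set(params) - set(self.parameter_defaults)
        if unknown:
            raise ValueError(f"unknown parameters for {type(self).__name__}: {sorted(unknown)}")
        self.params = {**self.parameter_defaults, **params}
        self.n_nodes: int | None = None
        self._p: dict[str, np.ndarray] = {}

    def configure(self, n_nodes: int) -> "Model":
        """Spatialise every parameter to shape ``(n_nodes, 1)`` for
        broadcasting against ``[n_nodes, n_modes]`` state slices."""
        self.n_nodes = n_nodes
        self._p = {
            k: spatialize_parameter(v, n_nodes)[:, None] for k, v in self.params.items()
        }
        return self

    def set_parameters(self, **params) -> None:
        """Update parameter values (e.g. between continued runs)."""
        unknown = set(params) - set(self.parameter_defaults)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        self.params.update(params)
        if self.n_nodes is not None:
            self.configure(self.n_nodes)

    @property
    def n_cvar(self) -> int:
        return len(self.coupling_variables)

    def _check_shapes(self, state: np.ndarray, coupling: np.ndarray) -> None:
        if state.ndim != 3 or state.shape[1] != self.n_svar:
            raise DimensionError(
                f"state must be [n_nodes, {self.n_svar}, n_modes], got {state.shape}"
            )
        if coupling.shape != (state.shape[0], self.n_cvar, state.shape[2]):
            raise DimensionError(
                f"coupling must be [n_nodes, {self.n_cvar}, n_modes], "
                f"got {coupling.shape}"
            )

    def dfun(self, state: np.ndarray, coupling: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def initial_state_ranges(self) -> np.ndarray:
        return np.asarray(self.state_ranges, dtype=float)


class Generic2dOscillator(Model):
    """Generic plane oscillator with a cubic nullcline.

        dv/dt = d * tau * (alpha*w - f*v^3 + e*v^2 + g*v + gamma*I)
        dw/dt = d * (a + b*v + c*v^2 - beta*w) / tau

    ``I`` is the total input: the external current ``I_ext`` plus the
    long-range/local coupling input.  With ``f=1/3, g=1, e=0, alpha=1,
    b=-1, c=0`` the system reduces to the FitzHugh–Nagumo oscillator; the
    overall rate constant ``d`` (1/ms) sets the oscillation frequency and
    ``tau`` the time-scale separation between fast ``v`` and slow ``w``.
    """

    n_svar = 2
    parameter_defaults = {
        "tau": 2.0,
        "I_ext": 0.5,
        "a": -0.7,
        "b": -1.0,
        "c": 0.0,
        "d": 0.1,
        "e": 0.0,
        "f": 1.0 / 3.0,
        "g": 1.0,
        "alpha": 1.0,
        "beta": 0.8,
        "gamma": 1.0,
    }
    state_ranges = [(-2.0, 2.0), (-1.5, 1.5)]
    variables_of_interest = [0]
    coupling_variables = [0]
    stimulus_variable = 0

    def dfun(self, state, coupling):
        self._check_shapes(state, coupling)
        p = self._p
        v = state[:, 0, :]
        w = state[:, 1, :]
        c_in = coupling[:, 0, :]
        total_input = p["I_ext"] + c_in
        dv = p["d"] * p["tau"] * (
            p["alpha"] * w
            - p["f"] * v**3
            + p["e"] * v**2
            + p["g"] * v
            + p["gamma"] * total_input
        )
        dw = p["d"] * (p["a"] + p["b"] * v + p["c"] * v**2 - p["beta"] * w) / p["tau"]
        return np.stack([dv, dw], axis=1)


#: Parameter set calibrated so that a single isolated node oscillates with a
#: dominant spectral peak near 40 Hz (gamma band).  See docs/methods.md.
GENERIC_2D_DEMO_PARAMS = {
    "tau": 2.0,
    "I_ext": 0.5,
    "a": -0.7,
    "b": -1.0,
    "c": 0.0,
    "d": 0.375,
    "e": 0.0,
    "f": 1.0 / 3.0,
    "g": 1.0,
    "alpha": 1.0,
    "beta": 0.8,
    "gamma": 1.0,
}


class WilsonCowan(Model):
    """Two-population (excitatory/inhibitory) firing-rate model.

        tau_e * dE/dt = -E + (k_e - r_e*E) * S_e(c1*E - c2*I + P + c_in)
        tau_i * dI/dt = -I + (k_i - r_i*I) * S_i(c3*E - c4*I + Q)

    with the logistic response shifted so that ``S(0) = 0``:

        S(x) = 1/(1 + exp(-a*(x - theta))) - 1/(1 + exp(a*theta))

    Long-range coupling input enters the excitatory drive.  The origin
    ``E = I = 0`` is a fixed point when the external drives P, Q vanish.
    """

    n_svar = 2
    parameter_defaults = {
        "tau_e": 10.0,
        "tau_i": 10.0,
        "k_e": 1.0,
        "k_i": 1.0,
        "r_e": 1.0,
        "r_i": 1.0,
        "c1": 12.0,
        "c2": 4.0,
        "c3": 13.0,
        "c4": 11.0,
        "a_e": 1.2,
        "theta_e": 2.8,
        "a_i": 1.0,
        "theta_i": 4.0,
        "P": 0.0,
        "Q": 0.0,
    }
    state_ranges = [(0.0, 0.5), (0.0, 0.5)]
    variables_of_interest = [0]
    coupling_variables = [0]
    stimulus_variable = 0

    @staticmethod
    def _sigmoid(x, a, theta):
        return 1.0 / (1.0 + np.exp(-a * (x - theta))) - 1.0 / (1.0 + np.exp(a * theta))

    def dfun(self, state, coupling):
        self._check_shapes(state, coupling)
        p = self._p
        E = state[:, 0, :]
        I = state[:, 1, :]
        c_in = coupling[:, 0, :]
        x_e = p["c1"] * E - p["c2"] * I + p["P"] + c_in
        x_i = p["c3"] * E - p["c4"] * I + p["Q"]
        s_e = self._sigmoid(x_e, p["a_e"], p["theta_e"])
        s_i = self._sigmoid(x_i, p["a_i"], p["theta_i"])
        dE = (-E + (p["k_e"] - p["r_e"] * E) * s_e) / p["tau_e"]
        dI = (-I + (p["k_i"] - p["r_i"] * I) * s_i) / p["tau_i"]
        return np.stack([dE, dI], axis=1)


class JansenRit(Model):
    """Three-population cortical column model (pyramidal cells plus
    excitatory and inhibitory interneurons), six first-order equations.

    States: ``y0, y1, y2`` are the post-synaptic potentials of the three
    populations, ``y3, y4, y5`` their derivatives.  The EEG-like observable
    is the pyramidal membrane potential ``y1 - y2``.

        Sigm(v) = 2*e0 / (1 + exp(r*(v0 - v)))

        dy0/dt = y3;  dy3/dt = A*a*Sigm(y1 - y2)            - 2*a*y3 - a^2*y0
        dy1/dt = y4;  dy4/dt = A*a*(p + C2*Sigm(C1*y0) + c) - 2*a*y4 - a^2*y1
        dy2/dt = y5;  dy5/dt = B*b*C4*Sigm(C3*y0)           - 2*b*y5 - b^2*y2

    where ``c`` is the long-range input (difference of the delayed ``y1``
    and ``y2`` aggregates, i.e. afferent pyramidal potential).  Rate
    constants are per ms (a = 0.1/ms = 100/s); with the standard parameter
    set the column oscillates in the alpha band (~10 Hz).
    """

    n_svar = 6
    parameter_defaults = {
        "A": 3.25,        # mV, excitatory synaptic gain
        "B": 22.0,        # mV, inhibitory synaptic gain
        "a": 0.1,         # 1/ms, excitatory rate constant
        "b": 0.05,        # 1/ms, inhibitory rate constant
        "v0": 6.0,        # mV, sigmoid midpoint
        "e0": 0.0025,     # 1/ms, half-max firing rate
        "r": 0.56,        # 1/mV, sigmoid steepness
        "C": 135.0,
        "c1": 1.0,        # C1 = c1*C etc.
        "c2": 0.8,
        "c3": 0.25,
        "c4": 0.25,
        "p": 0.12,        # 1/ms, mean external drive (120/s)
    }
    state_ranges = [
        (-1.0, 1.0),
        (-50.0, 50.0),
        (-50.0, 50.0),
        (-1.0, 1.0),
        (-5.0, 5.0),
        (-5.0, 5.0),
    ]
    variables_of_interest = [1, 2]
    coupling_variables = [1, 2]
    stimulus_variable = 4

    @staticmethod
    def sigm(v, e0, r, v0):
        return 2.0 * e0 / (1.0 + np.exp(r * (v0 - v)))

    def dfun(self, state, coupling):
        self._check_shapes(state, coupling)
        p = self._p
        y0, y1, y2, y3, y4, y5 = (state[:, k, :] for k in range(6))
        # long-range afferent pyramidal potential: aggregate(y1) - aggregate(y2)
        c_in = coupling[:, 0, :] - coupling[:, 1, :]
        A, B, a, b = p["A"], p["B"], p["a"], p["b"]
        C1, C2 = p["c1"] * p["C"], p["c2"] * p["C"]
        C3, C4 = p["c3"] * p["C"], p["c4"] * p["C"]
        s_pyr = self.sigm(y1 - y2, p["e0"], p["r"], p["v0"])
        s_exc = self.sigm(C1 * y0, p["e0"], p["r"], p["v0"])
        s_inh = self.sigm(C3 * y0, p["e0"], p["r"], p["v0"])
        dy0 = y3
        dy1 = y4
        dy2 = y5
        dy3 = A * a * s_pyr - 2.0 * a * y3 - a**2 * y0
        dy4 = A * a * (p["p"] + C2 * s_exc + c_in) - 2.0 * a * y4 - a**2 * y1
        dy5 = B * b * C4 * s_inh - 2.0 * b * y5 - b**2 * y2
        return np.stack([dy0, dy1, dy2, dy3, dy4, dy5], axis=1)


class ReducedWongWang(Model):
    """Reduced two-variable decision/gating model.

    Two NMDA gating variables ``s1, s2`` (selective populations) with
    self-excitation and cross-inhibition:

        x_i    = J_ii*s_i - J_ij*s_j + I0 + J_ext*c_in   (c_in only for i=1)
        H(x)   = (a*x - b) / (1 - exp(-d*(a*x - b)))
        ds_i/dt = -s_i/tau_s + (1 - s_i) * gamma * H(x_i)

    ``H`` has a removable singularity at ``a*x = b`` where its value is
    ``1/d``.  Time constants are in ms (tau_s = 100 ms, gamma = 0.641/1000).
    """

    n_svar = 2
    parameter_defaults = {
        "a": 0.270,      # 1/nA (input-output gain)
        "b": 0.108,      # kHz
        "d": 154.0,      # ms
        "gamma": 0.641e-3,
        "tau_s": 100.0,  # ms
        "J11": 0.2609,
        "J22": 0.2609,
        "J12": 0.0497,
        "J21": 0.0497,
        "I0": 0.3255,    # nA
        "J_ext": 0.2609,
    }
    state_ranges = [(0.0, 1.0), (0.0, 1.0)]
    variables_of_interest = [0]
    coupling_variables = [0]
    stimulus_variable = 0

    @staticmethod
    def firing_rate(x, a, b, d):
        """H(x) with the removable singularity at a*x == b filled by 1/d."""
        u = a * x - b
        du = d * u
        small = np.abs(du) < 1e-9
        safe = np.where(small, 1.0, du)
        # near the removable singularity use the series u/(1-e^{-du}) ~ 1/d + u/2
        return np.where(small, 1.0 / d + u / 2.0, u / (1.0 - np.exp(-safe)))

    def dfun(self, state, coupling):
        self._check_shapes(state, coupling)
        p = self._p
        s1 = state[:, 0, :]
        s2 = state[:, 1, :]
        c_in = coupling[:, 0, :]
        x1 = p["J11"] * s1 - p["J12"] * s2 + p["I0"] + p["J_ext"] * c_in
        x2 = p["J22"] * s2 - p["J21"] * s1 + p["I0"]
        h1 = self.firing_rate(x1, p["a"], p["b"], p["d"])
        h2 = self.firing_rate(x2, p["a"], p["b"], p["d"])
        ds1 = -s1 / p["tau_s"] + (1.0 - s1) * p["gamma"] * h1
        ds2 = -s2 / p["tau_s"] + (1.0 - s2) * p["gamma"] * h2
        return np.stack([ds1, ds2], axis=1)


class StefanescuJirsa2D(Model):
    """Three-mode mean field of coupled excitatory/inhibitory
    FitzHugh–Nagumo populations with a Gaussian-dispersed input current.

    The dispersed parameter ``I ~ N(mu, sigma^2)`` partitions the population
    into three modes of equal probability mass; each mode ``i`` is driven by
    the conditional mean current ``I_i`` over its partition interval
    (computed by numerical quadrature of the Gaussian density at configure
    time), and modes interact through the population mean
    ``<x> = sum_k p_k x_k`` with ``p_k = 1/3``.

    Per mode (xi, eta: excitatory; alpha, beta: inhibitory):

        dxi/dt    = tau*(xi - xi^3/3 - eta) + K11*(<xi> - xi)
                    - K12*(<alpha> - xi) + tau*(I_i + c_in)
        deta/dt   = (xi - b_fhn*eta + m) / tau
        dalpha/dt = tau*(alpha - alpha^3/3 - beta) + K21*(<xi> - alpha)
                    + tau*I_i
        dbeta/dt  = (alpha - b_fhn*beta + n) / tau

    With ``sigma = 0`` all modes receive identical input and (from mode-
    symmetric initial conditions) their trajectories coincide.
    """

    n_svar = 4
    n_modes = 3
    parameter_defaults = {
        "tau": 3.0,
        "b_fhn": 0.9,
        "m": 0.0,
        "n": 0.0,
        "K11": 0.5,
        "K12": 0.15,
        "K21": 0.15,
        "mu": 0.35,
        "sigma": 0.35,
    }
    state_ranges = [(-4.0, 4.0), (-3.0, 3.0), (-4.0, 4.0), (-3.0, 3.0)]
    variables_of_interest = [0]
    coupling_variables = [0]
    stimulus_variable = 0

    def configure(self, n_nodes: int) -> "StefanescuJirsa2D":
        super().configure(n_nodes)
        mu = float(np.asarray(self.params["mu"]).ravel()[0])
        sigma = float(np.asarray(self.params["sigma"]).ravel()[0])
        self.mode_weights, self.mode_inputs = mode_coupling_table(mu, sigma)
        return self

    def dfun(self, state, coupling):
        self._check_shapes(state, coupling)
        p = self._p
        xi = state[:, 0, :]
        eta = state[:, 1, :]
        al = state[:, 2, :]
        be = state[:, 3, :]
        c_in = coupling[:, 0, :]
        pk = self.mode_weights  # (3,)
        Ii = self.mode_inputs   # (3,)
        mean_xi = (xi * pk).sum(axis=1, keepdims=True)
        mean_al = (al * pk).sum(axis=1, keepdims=True)
        tau, b = p["tau"], p["b_fhn"]
        dxi = (
            tau * (xi - xi**3 / 3.0 - eta)
            + p["K11"] * (mean_xi - xi)
            - p["K12"] * (mean_al - xi)
            + tau * (Ii + c_in)
        )
        deta = (xi - b * eta + p["m"]) / tau
        dal = (
            tau * (al - al**3 / 3.0 - be)
            + p["K21"] * (mean_xi - al)
            + tau * Ii
        )
        dbe = (al - b * be + p["n"]) / tau
        return np.stack([dxi, deta, dal, dbe], axis=1)


def mode_coupling_table(
    mu: float, sigma: float, n_grid: int = 200_001
) -> tuple[np.ndarray, np.ndarray]:
    """Mode weights and per-mode mean inputs for the dispersed parameter.

    The Gaussian density of the dispersed current is partitioned into three
    intervals of equal probability mass (boundaries at the 1/3 and 2/3
    quantiles); the table holds the mass ``p_i = 1/3`` and the conditional
    mean ``I_i = E[I | interval_i]`` of each interval, evaluated by
    trapezoidal quadrature of ``x * pdf(x)`` on a fine grid (tails clipped
    at 10 sigma).  Degenerate dispersion (sigma = 0) gives ``I_i = mu``.
    """
    weights = np.full(3, 1.0 / 3.0)
    if sigma <= 0:
        return weights, np.full(3, mu)
    # standard-normal quantiles of 1/3 and 2/3 via inverse error function
    from scipy.special import ndtri

    q1 = mu + sigma * ndtri(1.0 / 3.0)
    q2 = mu + sigma * ndtri(2.0 / 3.0)
    lo, hi = mu - 10.0 * sigma, mu + 10.0 * sigma
    bounds = [(lo, q1), (q1, q2), (q2, hi)]
    means = np.empty(3)
    for i, (a, b) in enumerate(bounds):
        x = np.linspace(a, b, n_grid)
        pdf = np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
        mass = np.trapezoid(pdf, x)
        means[i] = np.trapezoid(x * pdf, x) / mass
    return weights, means


def random_initial_state(
    model: Model, n_nodes: int, horizon: int, stream: np.random.Generator
) -> np.ndarray:
    """Uniform random history ``[horizon, n_nodes, n_svar, n_modes]`` drawn
    within each state variable's admissible range."""
    if horizon < 1:
        raise ValueError("horizon must be at least 1")
    ranges = model.initial_state_ranges()
    if ranges.size == 0 or np.any(~np.isfinite(ranges)):
        raise ValueError("model state ranges must be finite and non-empty")
    lo = ranges[:, 0][None, None, :, None]
    hi = ranges[:, 1][None, None, :, None]
    shape = (horizon, n_nodes, model.n_svar, model.n_modes)
    return lo + (hi - lo) * stream.uniform(size=shape)


MODEL_REGISTRY = {
    "generic2d": Generic2dOscillator,
    "wilson_cowan": WilsonCowan,
    "jansen_rit": JansenRit,
    "reduced_wong_wang": ReducedWongWang,
    "stefanescu_jirsa_2d": StefanescuJirsa2D,
}
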