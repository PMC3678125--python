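"""Online monitors: down-sampling observers and biophysical forward models.

Monitors watch the state stream while the simulation runs and emit samples
at their own period.  Raw-family monitors produce 4-D arrays
``[time, state_variables, space, modes]``; biophysical monitors (sensor
projections such as EEG/MEG/sEEG, and BOLD) produce ``[time, 1, sensors, 1]``.

The neural source signal fed to biophysical monitors is, per node, the sum
(or mean) over the model's configured variables of interest and modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DimensionError

__all__ = [
    "TimeSeriesResult",
    "Monitor",
    "RawMonitor",
    "SubSampleMonitor",
    "TemporalAverageMonitor",
    "SpatialAverageMonitor",
    "SensorProjectionMonitor",
    "BoldMonitor",
    "BalloonParams",
    "ProjectionMatrix",
    "seeg_gain",
    "MONITOR_REGISTRY",
]


@dataclass
class TimeSeriesResult:
    """4-D monitor output plus its sampling period and axis labels."""

    data: np.ndarray            # [time, svar, space, modes]
    sample_period: float        # ms
    t0: float = 0.0             # time of the first sample, ms
    labels: dict = field(default_factory=dict)

    @property
    def time(self) -> np.ndarray:
        return self.t0 + self.sample_period * np.arange(self.data.shape[0])

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


@dataclass
class ProjectionMatrix:
    """Lead-field/gain operator mapping sources to sensors."""

    gain: np.ndarray            # (n_sensors, n_sources)
    sensor_labels: list[str] | None = None
    source_space: str = "region"

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise DimensionError("gain must be a 2-D sensors x sources matrix")
        if self.sensor_labels is None:
            self.sensor_labels = [f"sensor_{k}" for k in range(self.gain.shape[0])]

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]


class Monitor:
    """Base: validates the period against dt, buffers emitted samples."""

    biophysical = False

    def __init__(self, period: float | None = None):
        self.period = period
        self._samples: list[np.ndarray] = []
        self._times: list[float] = []

    def configure(self, dt: float, model, n_nodes: int, node_labels=None) -> "Monitor":
        self.dt = dt
        self.model = model
        self.n_nodes = n_nodes
        self.node_labels = node_labels
        if self.period is None:
            self.period = dt
        self.istep = int(round(self.period / dt))
        if self.istep < 1 or abs(self.istep * dt - self.period) > 1e-9 * max(1.0, self.period):
            raise ConfigurationError(
                f"monitor period {self.period} ms is not a positive integer "
                f"multiple of dt = {dt} ms"
            )
        self.voi = list(model.variables_of_interest)
        return self

    def record(self, step: int, state: np.ndarray) -> None:
        """Offer the state at integration step ``step`` (time step*dt)."""
        raise NotImplementedError

    def _emit(self, step: int, sample: np.ndarray) -> None:
        self._times.append(step * self.dt)
        self._samples.append(sample)

    def drain(self) -> TimeSeriesResult:
        """Return and clear the samples accumulated so far."""
        if self._samples:
            data = np.stack(self._samples)
            t0 = self._times[0]
        else:
            data = np.empty((0, 0, 0, 0))
            t0 = 0.0
        self._samples, self._times = [], []
        return TimeSeriesResult(
            data=data, sample_period=self.period, t0=t0, labels=self._labels()
        )

    def _labels(self) -> dict:
        return {
            "state_variables": self.voi,
            "space": list(self.node_labels) if self.node_labels is not None else None,
        }

    # hooks for simulation continuation (monitors with internal state)
    def get_state(self):
        return None

    def set_state(self, state) -> None:
        pass


class RawMonitor(Monitor):
    """Every integration step, every state variable, every node."""

    def configure(self, dt, model, n_nodes, node_labels=None):
        super().configure(dt, model, n_nodes, node_labels)
        self.voi = list(range(model.n_svar))  # raw keeps the full state
        return self

    def record(self, step, state):
        self._emit(step, np.transpose(state, (1, 0, 2)).copy())


class SubSampleMonitor(Monitor):
    """Variables of interest, every ``period/dt``-th step."""

    def record(self, step, state):
        if step % self.istep == 0:
            self._emit(step, np.transpose(state[:, self.voi, :], (1, 0, 2)).copy())


class TemporalAverageMonitor(Monitor):
    """Mean of the variables of interest over each sampling window."""

    def configure(self, dt, model, n_nodes, node_labels=None):
        super().configure(dt, model, n_nodes, node_labels)
        self._acc = None
        self._count = 0
        return self

    def record(self, step, state):
        x = np.transpose(state[:, self.voi, :], (1, 0, 2))
        if self._acc is None:
            self._acc = np.zeros_like(x)
        self._acc += x
        self._count += 1
        if step % self.istep == 0:
            self._emit(step, self._acc / self._count)
            self._acc = np.zeros_like(x)
            self._count = 0

    def get_state(self):
        return (None if self._acc is None else self._acc.copy(), self._count)

    def set_state(self, state):
        self._acc = state[0]
        self._count = state[1]


class SpatialAverageMonitor(Monitor):
    """Average over node groups (whole network by default, or masks such as
    hemispheres), temporally sub-sampled."""

    def __init__(self, period=None, masks=None, mask_labels=None):
        super().__init__(period)
        self.masks = masks
        self.mask_labels = mask_labels

    def configure(self, dt, model, n_nodes, node_labels=None):
        super().configure(dt, model, n_nodes, node_labels)
        if self.masks is None:
            self.masks = [np.ones(n_nodes, dtype=bool)]
            self.mask_labels = ["network_mean"]
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        for m in self.masks:
            if m.size != n_nodes:
                raise DimensionError("spatial-average mask length must equal n_nodes")
        return self

    def record(self, step, state):
        if step % self.istep == 0:
            x = state[:, self.voi, :]  # [nodes, voi, modes]
            groups = [x[m].mean(axis=0) for m in self.masks]
            sample = np.transpose(np.stack(groups, axis=0), (1, 0, 2))
            self._emit(step, sample.copy())

    def _labels(self):
        return {"state_variables": self.voi, "space": self.mask_labels}


def _source_signal(state: np.ndarray, voi: list[int], reduction: str) -> np.ndarray:
    """Collapse [nodes, svar, modes] to one source signal per node."""
    x = state[:, voi, :]
    return x.mean(axis=(1, 2)) if reduction == "mean" else x.sum(axis=(1, 2))


class SensorProjectionMonitor(Monitor):
    """Linear sensor projection (EEG/MEG/sEEG): sample = gain . sources."""

    biophysical = True

    def __init__(self, projection: ProjectionMatrix, period=None, reduction: str = "sum"):
        super().__init__(period)
        self.projection = projection
        if reduction not in ("sum", "mean"):
            raise ValueError("reduction must be 'sum' or 'mean'")
        self.reduction = reduction

    def configure(self, dt, model, n_nodes, node_labels=None):
        super().configure(dt, model, n_nodes, node_labels)
        if self.projection.gain.shape[1] != n_nodes:
            raise DimensionError(
                f"gain has {self.projection.gain.shape[1]} source columns, "
                f"but the simulation has {n_nodes} nodes"
            )
        return self

    def record(self, step, state):
        if step % self.istep == 0:
            src = _source_signal(state, self.voi, self.reduction)
            sensors = self.projection.gain @ src
            self._emit(step, sensors[None, :, None])

    def _labels(self):
        return {"space": self.projection.sensor_labels}


def seeg_gain(
    source_positions: np.ndarray,
    source_orientations: np.ndarray,
    sensor_positions: np.ndarray,
    sigma: float = 1.0,
    sensor_labels=None,
) -> ProjectionMatrix:
    """Point-dipole gain in an infinite homogeneous medium (conductivity
    ``sigma``, S/m): ``g[k, i] = q_i . (r_k - r_i) / (4 pi sigma |r_k - r_i|^3)``
    for a unit dipole moment along ``q_i``."""
    src = np.asarray(source_positions, float)
    ori = np.asarray(source_orientations, float)
    sens = np.asarray(sensor_positions, float)
    diff = sens[:, None, :] - src[None, :, :]          # (k, i, 3)
    dist = np.linalg.norm(diff, axis=2)
    if np.any(dist == 0):
        raise ValueError("a sensor coincides with a source position")
    gain = (diff * ori[None, :, :]).sum(axis=2) / (4.0 * np.pi * sigma * dist**3)
    return ProjectionMatrix(gain=gain, sensor_labels=sensor_labels, source_space="region")


@dataclass
class BalloonParams:
    """Balloon–windkessel hemodynamic constants (SI-second based)."""

    kappa: float = 0.65   # 1/s, signal decay
    gamma: float = 0.41   # 1/s, feedback rate
    tau: float = 0.98     # s, transit time
    alpha: float = 0.32   # Grubb exponent
    rho: float = 0.34     # resting oxygen extraction
    V0: float = 0.02      # resting venous volume fraction
    k1: float | None = None  # defaults: 7*rho
    k2: float = 2.0
    k3: float | None = None  # defaults: 2*rho - 0.2

    def __post_init__(self):
        if self.tau <= 0 or self.alpha <= 0 or not (0 < self.rho < 1):
            raise ValueError("tau and alpha must be positive and 0 < rho < 1")
        if self.k1 is None:
            self.k1 = 7.0 * self.rho
        if self.k3 is None:
            self.k3 = 2.0 * self.rho - 0.2


def balloon_dfun(h: np.ndarray, x: np.ndarray, p: BalloonParams) -> np.ndarray:
    """RHS of the hemodynamic system; ``h = [s, f, v, q]`` per node, time in s.

        ds/dt = x - kappa*s - gamma*(f - 1)
        df/dt = s
        dv/dt = (f - v^(1/alpha)) / tau
        dq/dt = (f*E(f)/rho - v^(1/alpha) * q/v) / tau,  E(f) = 1-(1-rho)^(1/f)
    """
    s, f, v, q = h
    E = 1.0 - (1.0 - p.rho) ** (1.0 / f)
    vexp = v ** (1.0 / p.alpha)
    return np.stack([
        x - p.kappa * s - p.gamma * (f - 1.0),
        s,
        (f - vexp) / p.tau,
        (f * E / p.rho - vexp * q / v) / p.tau,
    ])


def bold_signal(h: np.ndarray, p: BalloonParams) -> np.ndarray:
    """BOLD read-out y = V0*(k1*(1-q) + k2*(1-q/v) + k3*(1-v))."""
    _, _, v, q = h
    return p.V0 * (p.k1 * (1.0 - q) + p.k2 * (1.0 - q / v) + p.k3 * (1.0 - v))


class BoldMonitor(Monitor):
    """Balloon–windkessel BOLD forward model.

    Per node, the hemodynamic ODEs are driven by the neural source signal
    (piecewise constant over each neural step) and advanced by one RK4
    sub-step per integration step; the BOLD signal is emitted every
    ``period`` ms (hundreds of ms — much slower than neural dynamics).
    The resting state (s, f, v, q) = (0, 1, 1, 1) maps to zero signal.
    """

    biophysical = True

    def __init__(self, period: float = 500.0, params: BalloonParams | None = None,
                 reduction: str = "sum"):
        super().__init__(period)
        self.params = params if params is not None else BalloonParams()
        self.reduction = reduction

    def configure(self, dt, model, n_nodes, node_labels=None):
        super().configure(dt, model, n_nodes, node_labels)
        h = np.zeros((4, n_nodes))
        h[1:] = 1.0
        self._h = h
        self._dt_s = dt / 1000.0
        return self

    def record(self, step, state):
        x = _source_signal(state, self.voi, self.reduction)
        h, dt = self._h, self._dt_s
        p = self.params
        k1 = balloon_dfun(h, x, p)
        k2 = balloon_dfun(h + dt / 2 * k1, x, p)
        k3 = balloon_dfun(h + dt / 2 * k2, x, p)
        k4 = balloon_dfun(h + dt * k3, x, p)
        self._h = h + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if step % self.istep == 0:
            y = bold_signal(self._h, p)
            self._emit(step, y[None, :, None])

    def get_state(self):
        return self._h.copy()

    def set_state(self, state):
        if state is not None:
            self._h = np.array(state, dtype=float)


MONITOR_REGISTRY = {
    "raw": RawMonitor,
    "subsample": SubSampleMonitor,
    "temporal_average": TemporalAverageMonitor,
    "spatial_average": SpatialAverageMonitor,
    "projection": SensorProjectionMonitor,
    "bold": BoldMonitor,
}
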