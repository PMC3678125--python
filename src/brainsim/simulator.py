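"""Simulation core: delay history, node coupling and the update loop.

The simulator couples a neural-mass model on every node of a connectome
through weighted connections with conduction delays (whole integration
steps).  Past coupling-variable activity lives in a ring buffer whose depth
(the *horizon*) is the maximum delay plus one slot for the current state.

Update loop (explicit convention): the state at step ``s+1`` is computed
from delayed coupling read at step ``s`` — entry ``(i, j)`` of the weights
matrix scales node ``j``'s coupling variables at step ``s - d[i, j]``; a
zero-step delay reads the current state.  Delayed input, local (surface)
coupling and stimulation are frozen over the step and fed to the
integration scheme.

Simulations can be stopped and continued: model parameters, coupling
constants and stimulation may change between segments, but not ``dt``, the
transmission speed or the spatial support, so that an unmodified continued
run reproduces an uninterrupted one bit-exactly.
"""

from __future__ import annotations

import numpy as np

from .connectome import Connectome, compute_delay_table
from .coupling import LinearCoupling
from .exceptions import (
    ConfigurationError,
    DimensionError,
    SimulationDivergenceError,
)
from .models import Model, random_initial_state
from .monitors import Monitor, TimeSeriesResult
from .noise import make_stream
from .integrators import Integrator, HeunDeterministic
from .surface import RegionSurface

__all__ = ["HistoryBuffer", "Simulator", "node_coupling"]


class HistoryBuffer:
    """Ring buffer of past coupling-variable states over the delay horizon.

    Slot ``s % horizon`` holds the coupling variables of step ``s``;
    reading delay ``d`` at step ``s`` returns the entry stored at step
    ``s - d``.  Writing step ``s`` overwrites the oldest slot.
    """

    def __init__(self, horizon: int, n_nodes: int, n_cvar: int, n_modes: int):
        if horizon < 1:
            raise ValueError("horizon must be at least 1")
        self.horizon = horizon
        self.buffer = np.zeros((horizon, n_nodes, n_cvar, n_modes))

    def initialize(self, history: np.ndarray) -> None:
        """Fill from ``[horizon, n_nodes, n_cvar, n_modes]`` history whose
        last entry (index -1) is the most recent state (step 0)."""
        if history.shape != self.buffer.shape:
            raise DimensionError(
                f"history shape {history.shape} != buffer {self.buffer.shape}"
            )
        for k in range(self.horizon):  # step -k lands in slot (-k) % horizon
            self.buffer[(-k) % self.horizon] = history[self.horizon - 1 - k]

    def write(self, step: int, cvars: np.ndarray) -> None:
        self.buffer[step % self.horizon] = cvars

    def read_delayed(self, step: int, delay_steps: np.ndarray,
                     col_idx: np.ndarray) -> np.ndarray:
        """Gather ``[i, j, c, m] = cvar of node j at step - d[i, j]``."""
        slots = (step - delay_steps) % self.horizon
        return self.buffer[slots, col_idx]


def node_coupling(
    history: HistoryBuffer,
    weights: np.ndarray,
    delay_steps: np.ndarray,
    coupling_fn,
    step: int,
) -> np.ndarray:
    """Long-range input per node: the weights-matrix dot product with the
    delayed coupling-variable states, passed through the coupling function.

    Returns ``[n_nodes, n_cvar, n_modes]``.  With ``apply_before_sum`` set
    on the coupling function the transform is applied per afferent before
    the weighted sum instead of once after it.
    """
    n = weights.shape[0]
    col_idx = np.arange(n)[None, :]
    delayed = history.read_delayed(step, delay_steps, col_idx)  # (i, j, c, m)
    if getattr(coupling_fn, "apply_before_sum", False):
        return np.einsum("ij,ijcm->icm", weights, coupling_fn(delayed))
    aggregate = np.einsum("ij,ijcm->icm", weights, delayed)
    return coupling_fn(aggregate)


class Simulator:
    """Assembles connectome, model, coupling, integrator, noise, stimulus
    and monitors, and runs the configure/step loop."""

    def __init__(
        self,
        connectome: Connectome,
        model: Model,
        integrator: Integrator | None = None,
        coupling=None,
        monitors: list[Monitor] | None = None,
        stimulus=None,
        surface: RegionSurface | None = None,
        local_kernel=None,
        initial_conditions: np.ndarray | None = None,
        seed: int | None = None,
    ):
        self.connectome = connectome
        self.model = model
        self.integrator = integrator if integrator is not None else HeunDeterministic()
        self.coupling = coupling if coupling is not None else LinearCoupling()
        self.monitors = monitors if monitors is not None else []
        self.stimulus = stimulus
        self.surface = surface
        self.local_kernel = local_kernel
        self.initial_conditions = initial_conditions
        self.seed = seed
        self._configured = False

    # ------------------------------------------------------------------
    def configure(self) -> "Simulator":
        """Compute delays/horizon, spatialise parameters, initialise the
        history (padding short initial conditions) and the monitors."""
        dt = self.integrator.dt
        self.delay_table = compute_delay_table(self.connectome, dt)
        self.stream = make_stream(self.seed)

        if self.surface is not None:
            self._configure_surface()
        else:
            self.n_nodes = self.connectome.n_regions
            self.weights = self.connectome.weights
            self.delay_steps = self.delay_table.delay_steps
            self.node_labels = list(self.connectome.region_labels)
            self._local = self.local_kernel

        self.horizon = int(self.delay_steps.max()) + 1
        self.model.configure(self.n_nodes)
        m = self.model
        self.cvar = list(m.coupling_variables)
        self._col_idx = np.arange(self.n_nodes)[None, :]

        history = self._build_history()
        self.history = HistoryBuffer(self.horizon, self.n_nodes, len(self.cvar), m.n_modes)
        self.history.initialize(history[:, :, self.cvar, :])
        self.state = history[-1].copy()
        self.current_step = 0

        if self.stimulus is not None and self.stimulus.n_nodes != self.n_nodes:
            raise DimensionError(
                f"stimulus weighting has {self.stimulus.n_nodes} entries for "
                f"{self.n_nodes} nodes"
            )

        if self.integrator.stochastic:
            self.integrator.configure_noise(
                (self.n_nodes, m.n_svar, m.n_modes), self.stream
            )

        for mon in self.monitors:
            mon.configure(dt, m, self.n_nodes, self.node_labels)

        ranges = m.initial_state_ranges()
        self._divergence_bound = 1e6 * float(np.max(ranges[:, 1] - ranges[:, 0]))
        self._configured = True
        return self

    def _build_history(self) -> np.ndarray:
        """Full-state history [horizon, nodes, svar, modes]; user-supplied
        initial conditions occupy the most recent slots, random padding
        (drawn from the model's state ranges) fills the older ones."""
        m = self.model
        shape = (self.horizon, self.n_nodes, m.n_svar, m.n_modes)
        if self.initial_conditions is None:
            return random_initial_state(m, self.n_nodes, self.horizon, self.stream)
        ic = np.asarray(self.initial_conditions, dtype=float)
        if ic.ndim == 3:
            ic = ic[None]
        if ic.shape[1:] != shape[1:]:
            raise ConfigurationError(
                f"initial_conditions per-step shape {ic.shape[1:]} does not match "
                f"(n_nodes, n_svar, n_modes) = {shape[1:]}"
            )
        if ic.shape[0] >= self.horizon:
            return ic[-self.horizon:].copy()
        history = random_initial_state(m, self.n_nodes, self.horizon, self.stream)
        history[-ic.shape[0]:] = ic
        return history

    def _configure_surface(self) -> None:
        """Vertex-level expansion of the region connectome: each vertex
        inherits its region's afferent weights (normalised by the source
        region's vertex count) and delays; non-cortical regions are
        appended as single point nodes."""
        surf = self.surface
        mapping = surf.region_mapping
        n_reg = self.connectome.n_regions
        cortical = np.unique(mapping)
        non_cortical = np.array([r for r in range(n_reg) if r not in set(cortical.tolist())])
        n_vert = surf.mesh.n_vertices
        self.n_nodes = n_vert + non_cortical.size

        # region index of every node (vertices then appended regions)
        node_region = np.concatenate([mapping, non_cortical]).astype(np.int64)
        counts = np.bincount(mapping, minlength=n_reg).astype(float)
        counts[non_cortical] = 1.0

        w_reg = self.connectome.weights
        d_reg = self.delay_table.delay_steps
        self.weights = w_reg[np.ix_(node_region, node_region)] / counts[node_region][None, :]
        self.delay_steps = d_reg[np.ix_(node_region, node_region)]
        self.node_region = node_region
        labels = [f"vertex_{k}" for k in range(n_vert)] + [
            self.connectome.region_labels[r] for r in non_cortical
        ]
        self.node_labels = labels

        if self.local_kernel is not None:
            k = self.local_kernel
            if k.shape[0] == n_vert and n_vert < self.n_nodes:
                from scipy import sparse

                pad = self.n_nodes - n_vert
                k = sparse.block_diag(
                    [k, sparse.csr_matrix((pad, pad))], format="csr"
                )
            self._local = k
        else:
            self._local = None

    # ------------------------------------------------------------------
    def _coupling_input(self, step: int) -> np.ndarray:
        c = node_coupling(self.history, self.weights, self.delay_steps,
                          self.coupling, step)
        if self._local is not None:
            cv = self.state[:, self.cvar, :]  # instantaneous neighbours
            for k in range(cv.shape[1]):
                c[:, k, :] = c[:, k, :] + self._local @ cv[:, k, :]
        return c

    def _stimulus_drive(self, t: float) -> np.ndarray | float:
        if self.stimulus is None:
            return 0.0
        drive = np.zeros((self.n_nodes, self.model.n_svar, self.model.n_modes))
        drive[:, self.model.stimulus_variable, :] = self.stimulus(t)[:, None]
        return drive

    def run(self, simulation_length: float) -> list[TimeSeriesResult]:
        """Integrate for ``round(length/dt)`` steps; one result per monitor."""
        if not self._configured:
            raise ConfigurationError("call configure() before run()")
        if simulation_length <= 0:
            raise ValueError("simulation_length must be positive")
        dt = self.integrator.dt
        n_steps = int(round(simulation_length / dt))
        model, integ = self.model, self.integrator

        for _ in range(n_steps):
            s = self.current_step
            cpl = self._coupling_input(s)
            drive = self._stimulus_drive(s * dt)
            f = lambda x: model.dfun(x, cpl)
            new_state = integ.step(self.state, f, drive)
            if not np.all(np.isfinite(new_state)) or \
                    np.any(np.abs(new_state) > self._divergence_bound):
                bad = ~np.isfinite(new_state) | (np.abs(new_state) > self._divergence_bound)
                node = int(np.argwhere(bad.any(axis=(1, 2)))[0][0])
                raise SimulationDivergenceError(step=s + 1, node=node)
            self.state = new_state
            self.current_step = s + 1
            self.history.write(self.current_step, self.state[:, self.cvar, :])
            for mon in self.monitors:
                mon.record(self.current_step, self.state)

        return [mon.drain() for mon in self.monitors]

    # ------------------------------------------------------------------
    _FORBIDDEN_MODIFICATIONS = (
        "integrator.dt", "dt", "connectome.speed", "speed", "connectome",
        "surface", "n_nodes",
    )

    def continue_run(
        self, additional_length: float, modified: dict | None = None
    ) -> list[TimeSeriesResult]:
        """Resume from the stored history and random-stream state.

        ``modified`` maps dotted names to new values: ``model.<param>``,
        ``coupling.<attribute>`` or ``stimulus`` (a new pattern or None).
        Changes to dt, transmission speed or the spatial support are
        rejected — they would alter the spatiotemporal domain.
        """
        if not self._configured:
            raise ConfigurationError("call configure() before continue_run()")
        for key, value in (modified or {}).items():
            if key in self._FORBIDDEN_MODIFICATIONS:
                raise ConfigurationError(
                    f"cannot change {key!r} on continuation: it alters the "
                    "spatiotemporal domain of the simulation"
                )
            section, _, name = key.partition(".")
            if section == "model" and name:
                self.model.set_parameters(**{name: value})
            elif section == "coupling" and name:
                if not hasattr(self.coupling, name):
                    raise ConfigurationError(f"coupling has no attribute {name!r}")
                setattr(self.coupling, name, value)
            elif key == "stimulus":
                if value is not None and value.n_nodes != self.n_nodes:
                    raise DimensionError("stimulus weighting length mismatch")
                self.stimulus = value
            else:
                raise ConfigurationError(f"cannot modify {key!r} on continuation")
        return self.run(additional_length)
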