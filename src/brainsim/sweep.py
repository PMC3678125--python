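"""Parameter-space exploration.

A sweep runs one simulation per cell of the outer product of two parameter
axes (e.g. global coupling strength x transmission speed), reduces each
run to scalar metrics and returns the metric grids.  Every cell is a pure
function of (base configuration, cell overrides, seed), so cells are
embarrassingly parallel: :func:`run_cell` can be handed to any external
parallel driver, and cell results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .config import build_simulator, set_config_value
from .metrics import METRIC_REGISTRY

__all__ = ["SweepResult", "parameter_sweep", "run_cell"]


@dataclass
class SweepResult:
    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    #: metric name -> grid of shape (len(axis1), len(axis2))
    metrics: dict[str, np.ndarray]
    seeds: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


def _resolve_metrics(metrics) -> dict[str, Callable]:
    out: dict[str, Callable] = {}
    for m in metrics:
        if callable(m):
            out[getattr(m, "__name__", str(m))] = m
        else:
            out[m] = METRIC_REGISTRY[m]
    return out


def run_cell(
    base_config: dict,
    overrides: dict,
    seed: int | None,
    metrics: dict[str, Callable],
    connectome=None,
) -> dict[str, float]:
    """One sweep cell: apply overrides, simulate, reduce to metrics.

    The metrics are computed on the first monitor's output.
    """
    cfg = base_config
    for key, value in overrides.items():
        cfg = set_config_value(cfg, key, value)
    if seed is not None:
        cfg = dict(cfg)
        cfg["seed"] = int(seed)
    sim = build_simulator(cfg, connectome=connectome)
    results = sim.run(cfg.get("simulation_length", 1000.0))
    return {name: fn(results[0]) for name, fn in metrics.items()}


def parameter_sweep(
    base_config: dict,
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
    metrics: Sequence = ("global_variance", "node_variance"),
    seed: int | None = None,
) -> SweepResult:
    """Run ``len(axis1) * len(axis2)`` simulations and tabulate metrics.

    Each cell uses an identical configuration apart from the two swept
    parameters (dotted names, e.g. ``("coupling.a", [...])`` for the global
    coupling strength and ``("connectome.speed", [...])``) and the same
    seed, so that differences across the grid reflect the parameters only.
    """
    name1, values1 = axis1
    name2, values2 = axis2
    values1 = np.asarray(list(values1), dtype=float)
    values2 = np.asarray(list(values2), dtype=float)
    fns = _resolve_metrics(metrics)
    # sweeping connectome parameters rebuilds it per cell; otherwise share one
    shared_connectome = None
    if not (name1.startswith("connectome") or name2.startswith("connectome")):
        from .config import _build_connectome

        shared_connectome = _build_connectome(base_config.get("connectome", {}))

    grids = {name: np.empty((values1.size, values2.size)) for name in fns}
    for i, v1 in enumerate(values1):
        for j, v2 in enumerate(values2):
            cell = run_cell(
                base_config, {name1: v1, name2: v2}, seed, fns,
                connectome=shared_connectome,
            )
            for name, value in cell.items():
                grids[name][i, j] = value
    return SweepResult(
        axis1_name=name1,
        axis1_values=values1,
        axis2_name=name2,
        axis2_values=values2,
        metrics=grids,
        seeds=None if seed is None else np.full((values1.size, values2.size), seed),
        metadata={"simulation_length": base_config.get("simulation_length", 1000.0)},
    )
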