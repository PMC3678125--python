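"""Single-node phase-plane sampling: vector fields, example trajectories
(RK4) and nullclines for two designated state variables, with all other
state variables clamped.  Coupling input is zero (isolated node)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrators import RungeKutta4
from .models import Model

__all__ = ["PhasePlane", "phase_plane_sample"]


@dataclass
class PhasePlane:
    x_grid: np.ndarray          # (nx,)
    y_grid: np.ndarray          # (ny,)
    u: np.ndarray               # (ny, nx) derivative of the x-variable
    v: np.ndarray               # (ny, nx) derivative of the y-variable
    trajectories: list[np.ndarray] = field(default_factory=list)  # (steps, 2)
    nullclines: dict[str, np.ndarray] = field(default_factory=dict)
    svar_x: int = 0
    svar_y: int = 1


def _dfun_point(model: Model, xy: np.ndarray, svar_x: int, svar_y: int,
                fixed: np.ndarray, mode: int) -> np.ndarray:
    """Planar derivative at one (x, y) point, other svars clamped."""
    state = np.tile(fixed[None, :, None], (1, 1, model.n_modes))
    state[0, svar_x, :] = xy[0]
    state[0, svar_y, :] = xy[1]
    coupling = np.zeros((1, model.n_cvar, model.n_modes))
    d = model.dfun(state, coupling)
    return np.array([d[0, svar_x, mode], d[0, svar_y, mode]])


def phase_plane_sample(
    model: Model,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
    n_grid: int = 24,
    svar_x: int = 0,
    svar_y: int = 1,
    fixed_state: np.ndarray | None = None,
    trajectories: list[tuple[float, float]] | None = None,
    trajectory_length: float = 100.0,
    dt: float = 0.05,
    mode: int = 0,
) -> PhasePlane:
    """Sample the vector field on a grid, integrate RK4 trajectories from
    the given starts, and locate nullcline crossings by sign change plus
    bisection along grid lines."""
    if x_range[1] <= x_range[0] or y_range[1] <= y_range[0]:
        raise ValueError("degenerate grid box")
    if model.n_nodes is None:
        model.configure(1)
    fixed = (
        np.asarray(fixed_state, dtype=float)
        if fixed_state is not None
        else np.array([(lo + hi) / 2.0 for lo, hi in model.state_ranges])
    )

    xs = np.linspace(*x_range, n_grid)
    ys = np.linspace(*y_range, n_grid)
    # vectorised field evaluation: one "node" per grid point
    X, Y = np.meshgrid(xs, ys)
    npts = X.size
    state = np.tile(fixed[None, :, None], (npts, 1, model.n_modes))
    state[:, svar_x, :] = X.ravel()[:, None]
    state[:, svar_y, :] = Y.ravel()[:, None]
    model.configure(npts)
    deriv = model.dfun(state, np.zeros((npts, model.n_cvar, model.n_modes)))
    u = deriv[:, svar_x, mode].reshape(X.shape)
    v = deriv[:, svar_y, mode].reshape(X.shape)
    model.configure(1)

    trajs = []
    if trajectories:
        rk4 = RungeKutta4(dt)
        n_steps = int(round(trajectory_length / dt))
        for x0, y0 in trajectories:
            path = np.empty((n_steps + 1, 2))
            path[0] = (x0, y0)
            xy = np.array([x0, y0], dtype=float)
            f = lambda z: _dfun_point(model, z, svar_x, svar_y, fixed, mode)
            for k in range(n_steps):
                xy = rk4.step(xy, f)
                path[k + 1] = xy
            trajs.append(path)

    nullclines = {
        "x": _nullcline_points(model, xs, ys, 0, svar_x, svar_y, fixed, mode),
        "y": _nullcline_points(model, xs, ys, 1, svar_x, svar_y, fixed, mode),
    }
    return PhasePlane(
        x_grid=xs, y_grid=ys, u=u, v=v, trajectories=trajs,
        nullclines=nullclines, svar_x=svar_x, svar_y=svar_y,
    )


def _nullcline_points(model, xs, ys, component, svar_x, svar_y, fixed, mode,
                      n_bisect: int = 40) -> np.ndarray:
    """Zero crossings of one derivative component along horizontal grid
    lines, refined by bisection."""
    points = []
    for y in ys:
        vals = np.array(
            [_dfun_point(model, np.array([x, y]), svar_x, svar_y, fixed, mode)[component]
             for x in xs]
        )
        sign_change = np.where(np.diff(np.sign(vals)) != 0)[0]
        for k in sign_change:
            a, b = xs[k], xs[k + 1]
            fa = vals[k]
            for _ in range(n_bisect):
                mid = (a + b) / 2.0
                fm = _dfun_point(model, np.array([mid, y]), svar_x, svar_y,
                                 fixed, mode)[component]
                if fa * fm <= 0:
                    b = mid
                else:
                    a, fa = mid, fm
            points.append(((a + b) / 2.0, y))
    return np.array(points) if points else np.empty((0, 2))
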