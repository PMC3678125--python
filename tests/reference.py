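"""Independent naive reference implementations used as test oracles.

Everything here is written with plain Python loops and scalar arithmetic,
deliberately sharing no code with the package's vectorised simulation
path: the reference re-derives the plane-oscillator equations, the linear
coupling, the delay bookkeeping and the Heun scheme from their
definitions.
"""

from __future__ import annotations

import numpy as np


def naive_generic2d_heun(
    weights,
    delay_steps,
    params: dict,
    init_history,
    dt: float,
    n_steps: int,
    coupling_a: float,
    coupling_b: float = 0.0,
    stimulus=None,
):
    """Loop-based deterministic Heun simulation of the plane oscillator.

    ``init_history``: [horizon, n_nodes, 2] with the most recent state last
    (time step 0).  ``stimulus``: optional callable t -> per-node drive on v.
    Returns the trajectory [n_steps, n_nodes, 2] for steps 1..n_steps.
    """
    weights = np.asarray(weights, dtype=float)
    delay_steps = np.asarray(delay_steps, dtype=int)
    n = weights.shape[0]
    horizon = int(delay_steps.max()) + 1
    assert init_history.shape == (horizon, n, 2)

    p = params
    tau, d_rate = p["tau"], p["d"]

    def deriv(v, w, c_in):
        total = p["I_ext"] + c_in
        dv = d_rate * tau * (
            p["alpha"] * w - p["f"] * v**3 + p["e"] * v**2 + p["g"] * v
            + p["gamma"] * total
        )
        dw = d_rate * (p["a"] + p["b"] * v + p["c"] * v**2 - p["beta"] * w) / tau
        return dv, dw

    # history of the coupling variable v, keyed by absolute step number
    v_hist = {}
    for k in range(horizon):
        step = -(horizon - 1) + k
        for j in range(n):
            v_hist[(step, j)] = init_history[k, j, 0]
    state = [(init_history[-1, j, 0], init_history[-1, j, 1]) for j in range(n)]

    out = np.empty((n_steps, n, 2))
    for step in range(n_steps):
        s = step  # current step index; new state is step s+1
        c_in = []
        for i in range(n):
            agg = 0.0
            for j in range(n):
                agg += weights[i, j] * v_hist[(s - delay_steps[i, j], j)]
            c_in.append(coupling_a * agg + coupling_b)
        drive = [0.0] * n
        if stimulus is not None:
            amp = stimulus(s * dt)
            for i in range(n):
                drive[i] = amp[i]
        new_state = []
        for i in range(n):
            v, w = state[i]
            dv1, dw1 = deriv(v, w, c_in[i])
            k1v, k1w = dv1 + drive[i], dw1
            vi, wi = v + dt * k1v, w + dt * k1w
            dv2, dw2 = deriv(vi, wi, c_in[i])
            v_new = v + dt / 2.0 * (k1v + dv2 + drive[i])
            w_new = w + dt / 2.0 * (k1w + dw2)
            new_state.append((v_new, w_new))
        state = new_state
        for j in range(n):
            v_hist[(s + 1, j)] = state[j][0]
            out[step, j, 0] = state[j][0]
            out[step, j, 1] = state[j][1]
    return out


def naive_node_coupling(buffer, step, weights, delay_steps, a=1.0, b=0.0):
    """Triple-loop delayed coupling on a raw ring buffer
    [horizon, n_nodes, n_cvar, n_modes]; linear transform a*x + b."""
    horizon, n, n_cvar, n_modes = buffer.shape
    out = np.zeros((n, n_cvar, n_modes))
    for i in range(n):
        for c in range(n_cvar):
            for m in range(n_modes):
                agg = 0.0
                for j in range(n):
                    slot = (step - delay_steps[i, j]) % horizon
                    agg += weights[i, j] * buffer[slot, j, c, m]
                out[i, c, m] = a * agg + b
    return out
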