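"""Convert a burst of neural activity into a BOLD signal with the
balloon-windkessel hemodynamic model.

A one-second square pulse of activity drives the hemodynamic cascade
(vasodilatory signal -> inflow -> venous volume and deoxyhemoglobin);
the read-out shows the classic shape: a positive peak a few seconds
after the stimulus, an undershoot, and a slow return to baseline.
"""

import numpy as np

from brainsim import BoldMonitor, Generic2dOscillator

dt_ms = 1.0
monitor = BoldMonitor(period=500.0)       # sample every 0.5 s
monitor.configure(dt_ms, Generic2dOscillator(), n_nodes=1)

t_on, t_off, t_total = 1000.0, 2000.0, 25_000.0
for step in range(1, int(t_total / dt_ms) + 1):
    t = (step - 1) * dt_ms
    state = np.zeros((1, 2, 1))
    state[0, 0, 0] = 1.0 if t_on <= t < t_off else 0.0   # neural drive
    monitor.record(step, state)

ts = monitor.drain()
y = ts.data[:, 0, 0, 0]
t_s = ts.time / 1000.0
print(f"BOLD sampled every {ts.sample_period} ms, {y.size} samples over "
      f"{t_total / 1000:.0f} s")
print(f"peak  {y.max():+.6f} at t = {t_s[np.argmax(y)]:.1f} s "
      "(a few seconds after the 1-2 s stimulus)")
print(f"undershoot {y.min():+.6f} at t = {t_s[np.argmin(y)]:.1f} s")
print(f"final value {y[-1]:+.2e} (back near baseline)")
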