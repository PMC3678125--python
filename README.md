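# brainsim

Neural-mass simulation of whole-brain network dynamics: population models
on the nodes of a weighted connectome, coupled through connections with
conduction delays, integrated deterministically or stochastically, driven
by spatiotemporal stimuli and observed through raw and biophysical
(EEG/MEG/sEEG/BOLD) monitors.

`brainsim` is aimed at computational neuroscientists who want to script
brain network models: study how coupling strength, transmission speed and
noise shape collective dynamics; prototype stimulation protocols; or
generate synthetic sensor-level data from a structural connectome.

## The model

A brain network model couples `n` regions. Region `i` carries a neural-mass
model — a small ODE system `dx_i/dt = f(x_i, c_i)` for its mean activity
(plane oscillator, Wilson–Cowan, Jansen–Rit, reduced Wong–Wang, or a
three-mode FitzHugh–Nagumo mean field). The long-range input is the
delayed, weighted sum of afferent activity passed through a coupling
function `S` (linear or sigmoidal):

    c_i(t) = S( Σ_j  w_ij · x_j(t − L_ij / v) )

where `w_ij` is the connection strength into `i` from `j`, `L_ij` the
tract length (mm) and `v` the transmission speed (mm/ms). Delays are
discretised to integration steps and served from a ring buffer whose
depth is the maximum delay plus one (the *horizon*). Time stepping is
Euler or Heun (deterministic or stochastic, with additive/multiplicative
white or Ornstein–Uhlenbeck noise); classical RK4 is available for
deterministic phase-plane trajectories. Monitors observe the state stream
online: raw/sub-sampled/averaged time series with axes
`[time, state_variables, space, modes]`, lead-field projections to sensors
`[time, 1, sensors, 1]`, a point-dipole gain for depth electrodes and a
balloon–windkessel BOLD forward model. Two scalar metrics — the Global
Variance and the Variance of the node Variances — plus multiscale entropy
summarise simulations for parameter-space exploration.

## Worked example

```python
from brainsim import (Simulator, Generic2dOscillator, GENERIC_2D_DEMO_PARAMS,
                      HeunDeterministic, LinearCoupling, TemporalAverageMonitor,
                      generate_synthetic_connectome, global_variance)

conn = generate_synthetic_connectome(n_regions=74, weight_levels=4, seed=42)
sim = Simulator(conn,
                Generic2dOscillator(**GENERIC_2D_DEMO_PARAMS),  # ~40 Hz node rhythm
                HeunDeterministic(dt=0.0625),                    # ms
                LinearCoupling(a=0.015),
                [TemporalAverageMonitor(period=1.0)],
                seed=1).configure()
(ts,) = sim.run(1000.0)     # one second of activity
print(ts.data.shape, global_variance(ts))
```

Running `python examples/run_region_simulation.py` prints:

```
connectome: 74 regions, max tract length 131.7 mm, speed 4.0 mm/ms
delay horizon: 528 steps (max delay 527 steps of 0.0625 ms)
output shape [time, svar, space, modes] = (1000, 1, 74, 1), sampled every 1.0 ms
Global Variance:            0.1828
Variance of node variances: 0.001246
```

The horizon line says how much delayed history the network must keep
(527 past steps at this dt and speed); the Global Variance is the scalar
summary used to map collective dynamics across parameters — here a
weakly-coupled oscillatory regime. The other scripts in `examples/`
demonstrate the stimulation protocol with EEG read-out, the coupling ×
speed parameter sweep, the BOLD forward model and the phase-plane /
multiscale-entropy tools, one capability each.

A thin CLI wraps the same functions:

```bash
brainsim simulate --config cfg.json --out results/
brainsim sweep --config cfg.json --axis1 coupling.a=0,0.02,0.05 --axis2 connectome.speed=2,4,8
brainsim analyze --metric global_variance --in results/timeseries.h5
brainsim phase-plane --model generic2d
```

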