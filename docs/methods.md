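# Methods

This note documents the models, numerical choices and design decisions
behind `brainsim`, and what the synthetic data used by the tests does and
does not establish about real connectomes.

## Network model and delay handling

The state of a simulation is a rank-3 array `[n_nodes, n_svar, n_modes]`.
Each node runs a neural-mass model; nodes interact through the connectome
weights with conduction delays `L_ij / v` (tract length over transmission
speed), discretised to whole integration steps by rounding
half-away-from-zero. Sub-step delays round to zero (instantaneous); no
one-step floor is imposed. The horizon — the ring-buffer depth for past
coupling-variable states — is the maximum delay in steps plus one slot
for the current state, so an 80 mm tract at 4 mm/ms and dt = 2⁻⁴ ms
requires 320 stored past states.

The update loop uses the explicit convention: the state at step `s+1` is
computed from delayed coupling read at step `s` (a zero-step delay reads
the current state). Within a Heun step the delayed input is frozen; for
delays ≥ 1 step this is exact, for 0-step delays it is the standard
explicit approximation. The history stores only the coupling variables,
not the full state. A consequence tested step-exactly: in a feed-forward
pair, the target's *input* lags the source state by exactly the delay,
and the target's *state* by one further step (the explicit-update
latency).

The coupling transform (linear `a·x + b`, or a saturating sigmoid) is
applied to the weighted sum of delayed afferents, i.e. after aggregation;
the weights matrix is row = target. Applying the transform per afferent
before summation differs for the sigmoid, so couplings carry an
`apply_before_sum` switch; post-summation is the default because the
update loop is then a plain matrix–vector product.

`weights` and `tract_lengths` need not be symmetric; only
non-negativity, squareness and a zero tract-length diagonal are enforced.
Demonstration weights are not normalised — the linear coupling slope `a`
plays the role of the global coupling strength.

## Population models

The node models are taken in their canonical published forms, with every
constant exposed as a parameter that may be a scalar (applied to all
nodes) or a per-node array:

* **Generic2dOscillator** — plane oscillator with cubic nullcline,
  `dv/dt = d·τ·(αw − fv³ + ev² + gv + γI)`,
  `dw/dt = d·(a + bv + cv² − βw)/τ`. FitzHugh–Nagumo is the special case
  `f = 1/3, g = 1, e = c = 0`. The rate constant `d` (1/ms) scales the
  whole vector field and hence the frequency. `GENERIC_2D_DEMO_PARAMS`
  fixes `d = 0.375` so that an isolated node's spectral peak sits at
  40 Hz (gamma band), calibrated once on a 2 s deterministic run at
  dt = 2⁻⁴ ms and frozen.
* **WilsonCowan** — excitatory/inhibitory firing rates with logistic
  responses shifted so `S(0) = 0`; the origin is then a true rest state
  when the external drives vanish, which the stimulation protocol
  exploits.
* **JansenRit** — three-population cortical column as six first-order
  equations; rate constants are per ms (a = 0.1/ms), sigmoid
  `Sigm(v) = 2e₀/(1+exp(r(v₀−v)))`. Long-range input is the afferent
  pyramidal potential, i.e. the difference of the delayed `y1` and `y2`
  aggregates (the model's two coupling variables).
* **ReducedWongWang** — two NMDA gating variables with self-excitation
  and cross-inhibition; the input–output function
  `H(x) = (ax−b)/(1−exp(−d(ax−b)))` has its removable singularity filled
  by the series value `1/d + u/2` near `ax = b`.
* **StefanescuJirsa2D** — three-mode mean field of excitatory/inhibitory
  FitzHugh–Nagumo populations with a Gaussian-dispersed input current
  (N = 4 state variables × M = 3 modes). The mode reduction used here
  partitions the Gaussian into three intervals of equal probability mass
  (boundaries at the 1/3 and 2/3 quantiles); each mode is driven by the
  conditional mean current of its interval, computed by trapezoidal
  quadrature of `x·pdf(x)` on a 2·10⁵-point grid (tails clipped at 10σ,
  agreeing with the closed-form truncated-normal mean to better than
  1e-8), and modes interact through the population mean with weights
  1/3. Zero dispersion makes the three modes identical.

Coupling input enters each model through one documented additive term
(the oscillator's input current, the Wilson–Cowan excitatory drive, the
Jansen–Rit pyramidal drive `p`, the Wong–Wang `x₁` current, the
mean-field ξ input). Stimulation is a separate additive drive applied by
the integrator to each model's designated stimulus variable.

## Integration and noise

Fixed-step Euler and Heun, deterministic and stochastic; classical RK4
for deterministic problems only (used by the phase-plane sampler).
Stochastic Heun reuses the same Wiener increment in predictor and
corrector (Stratonovich-consistent), so zero noise intensity reproduces
the deterministic scheme bit-for-bit — this degeneracy is tested
exactly. Empirical convergence orders on `dy/dt = −y` are ≈ 1 (Euler),
≈ 2 (Heun), ≈ 4 (RK4).

White noise contributes increments of variance `2·D·dt` per step and
state variable. Colored noise is an Ornstein–Uhlenbeck process with
correlation time `τ_c` and stationary variance `D/τ_c`, advanced by its
exact update `η' = ρη + sqrt((D/τ_c)(1−ρ²))ξ`, `ρ = exp(−dt/τ_c)` — no
Euler discretisation of the noise itself, so its statistics do not
depend on dt. Multiplicative noise scales the increment by a
user-supplied function of the pre-step state (default `g(x) = x`).
Random numbers come from independently seedable PCG64 streams whose
state can be saved and restored; initial conditions, when not supplied,
are drawn uniformly within each state variable's declared range and fill
the whole history. User initial conditions shorter than the horizon
occupy the most recent slots, with random padding in the older ones (a
dialect choice; the alternative orientation would only relabel the
pre-`t=0` history).

Typical step sizes are dt ∈ {2⁻², …, 2⁻⁶} ms. A divergence guard aborts
with the offending step and node when any state magnitude exceeds 10⁶
times the widest state range.

## Monitors and forward models

Raw-family monitors emit `[time, state_variables, space, modes]`: raw
(every step, all state variables), sub-sample, temporal average
(window mean), spatial average (over node masks, e.g. hemispheres).
Periods must be integer multiples of dt. Biophysical monitors emit
`[time, 1, sensors, 1]`; their per-node source signal is the sum
(switchable to mean) over the model's variables of interest and modes.
EEG/MEG gain matrices are consumed, not computed (delimited text with an
optional label header); the depth-electrode gain uses the point dipole
in an infinite homogeneous medium,
`g = q̂·(r_k−r_i) / (4πσ|r_k−r_i|³)`, with σ defaulting to 1 S/m.

The BOLD monitor integrates the balloon–windkessel system per node
(vasodilatory signal, inflow, volume, deoxyhemoglobin; constants
κ = 0.65 s⁻¹, γ = 0.41 s⁻¹, τ = 0.98 s, α = 0.32, ρ = 0.34, V₀ = 0.02,
k₁ = 7ρ, k₂ = 2, k₃ = 2ρ−0.2, all overridable) with one RK4 sub-step per
neural step and the neural drive held piecewise constant; the read-out
`y = V₀(k₁(1−q) + k₂(1−q/v) + k₃(1−v))` is zero at the resting point
(0, 1, 1, 1). Against an adaptive-step reference solution of the same
piecewise-constant problem the monitor agrees to 1e-6.

## Surface mode and stimulation

Surface simulations (toy scale, ≤ ~10³ vertices) put one node per mesh
vertex plus one node per non-cortical region. Vertices inherit their
region's afferent weights normalised by the source region's vertex count
and the region-pair delay; local coupling is a sparse distance kernel
with finite cutoff applied instantaneously (short distances). Distances
are Euclidean — adequate for the near-flat toy meshes used here;
geodesic distance would matter on folded cortices and is noted as an
extension.

Stimuli factorise exactly into spatial weights × temporal profile.
Region-level patterns take an explicit per-node weighting (a region node
has no spatial extent); surface patterns evaluate a finite-support
profile (e.g. Gaussian with cutoff) of the distance to one or more focal
vertices, combined across focal points by maximum (switchable to sum —
maximum avoids double-counting overlapping kernels). Pulse windows are
half-open `[onset, onset+width)` so step sampling is unambiguous.

## Continuation

A simulation can be stopped, modified and resumed: model parameters,
coupling constants and the stimulus may change; dt, transmission speed
and the spatial support may not (they define the spatiotemporal domain).
The history buffer, random-stream state, colored-noise state and monitor
window/hemodynamic state all persist, so an unmodified continued run
equals an uninterrupted one bit-exactly — deterministically and
stochastically.

## Metrics and sweeps

Global Variance zero-centres every individual time series and takes the
variance over all points of the 4-D array; the Variance of the node
Variances takes, per node, the variance of its concatenated
per-(state-variable, mode) zero-centred series, then the variance of
those numbers across nodes. Both use population variance (divide by the
count) — the convention is documented because either choice is defensible
and the difference vanishes at realistic sample counts.

Multiscale entropy coarse-grains by non-overlapping window means and
computes sample entropy per scale with m = 2 and tolerance r = 0.15
times the standard deviation of the original scale-1 series, held fixed
across scales (the usual convention). Both template lengths range over
the same `N − m` starting indices, so a constant series scores exactly
zero at every scale.

The sweep driver runs one simulation per cell of a two-axis grid
(dotted parameter paths such as `coupling.a` × `connectome.speed`), each
cell a pure function of the base configuration, the two values and the
seed — ready for any external parallel scheduler; nothing is
parallelised internally.

## Synthetic data, problem sizes and what the tests show

The synthetic connectome generator emulates the structure of a
two-hemisphere demonstration dataset: 74 cortical regions (37 per
hemisphere), integer connection weights drawn uniformly from 0–3, and
symmetric tract lengths equal to Euclidean distances between region
centres placed on a 65 mm-radius sphere, with a default speed of
4 mm/ms. It reproduces the *format* and coarse statistics of a real
connectome, not its topology: no distance-dependent connection
probability, no hemispheric asymmetries, no log-normal weight tails.
Tests passing on it validate the simulation machinery (delays, coupling,
integration, monitors, metrics), not any empirical claim about brain
dynamics.

Problem sizes were chosen to keep the full suite and the acceptance
script fast while still exercising every code path at meaningful scale:
oracle-equivalence runs use 5 nodes × 100 ms at 1e-12; the sweep uses
the 74-node connectome, an 8×8 grid and 500 ms per cell at dt = 0.25 ms
(the map's qualitative features — a flat decoupled row, strong
speed-dependence under strong coupling — are stable across seeds);
noise statistics use 10⁶ draws (1% tolerance); BOLD runs 25 s of
hemodynamics at 1 ms resolution.

## Known limitations

* Delays are whole integration steps; no interpolation between history
  samples (halving dt is the way to refine delay resolution).
* Published sweep maps for comparable platforms cannot be reproduced
  number-for-number: the demonstration dataset's exact weights and the
  oscillator demo parameters behind such figures are not available, so
  the sweep here is validated qualitatively
  and the 40 Hz node rhythm is a calibrated property of this package's
  demo parameter set.
* No BEM/FEM lead-field computation — gain matrices are inputs.
* Surface mode is a toy-scale reference implementation (dense vertex
  gather, O(n²) memory); large meshes need a sparse delay-aware
  implementation.
* Spatially correlated noise across nodes is out of scope.
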