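# Methods

This note documents the model, the numerical choices, and the design
decisions behind `dbsloop`, in the spirit of the methods sections that
accompany simulation packages: what is computed, under which assumptions,
and what the shipped defaults do and do not represent.

## The plant: a cortex–basal-ganglia–thalamus network

Eight populations of ten single-compartment neurons are simulated:
subthalamic nucleus (STN), external and internal globus pallidus (GPe,
GPi), thalamus (TH), direct- and indirect-pathway striatum (dSTR, idSTR),
and excitatory/inhibitory cortex (eCTX, iCTX).

STN, GP, TH and STR follow Hodgkin–Huxley-type membrane equations
(C = 1 μF/cm²) with the ionic currents and gating kinetics of the
Rubin–Terman-derived rat model lineage: Na, K and leak everywhere; T-type
and L-type calcium, A-type, M-type, calcium-activated and
after-hyperpolarization potassium currents where the respective nucleus
has them; GP carries an explicit calcium pool
dCA/dt = 10⁻⁴(−I_Ca − I_T − 15·CA).  Gates relax either as
dX/dt = λ_X(X∞ − X)/τ_X(v) with Boltzmann steady states
X∞ = 1/(1+exp(−(v+w_X)/σ_X)), or (striatum) in α/β rate form.  Cortical
neurons are Izhikevich units (dv/dt = 0.04v² + 5v + 140 − u − I_syn,
du/dt = a(0.2v − u); reset to −65 mV with u ← u + d on crossing +30 mV;
a = 0.02, d = 8 for eCTX, a = 0.1, d = 2 for iCTX).

Projections are delayed alpha synapses: each presynaptic spike, after a
transmission delay t_d, contributes S(t) = ((t−t_d)/τ)e^{−(t−t_d)/τ} with
τ = 5 ms, and the synaptic current is I = g·(v_post − E_syn)·S.  By
default E_syn is 0 mV for excitatory and −85 mV for inhibitory
projections; a literal mode (`paper_literal_esyn`) forces −85 mV
everywhere, reproducing a published parameterization in which the
reversal is stated as uniform.  That uniform value is non-physiological
for excitatory projections, so the split default is shipped and the
switch documents the discrepancy rather than hiding it.

The topology comprises the direct (eCTX→dSTR→GPi→TH→eCTX), indirect
(eCTX→idSTR→GPe→GPi→TH→eCTX) and hyper-direct (eCTX→STN→GPi→TH→eCTX)
pathways, the reciprocal STN↔GPe loop, GPe→GPe collaterals, and
reciprocal eCTX↔iCTX coupling.

### The parkinsonism variable

A scalar `pd ∈ [0, 1]` interpolates three conductances between healthy
(pd = 0) and fully Parkinsonian (pd = 1) states:

* striatal M-current: g_m = 2.6 − 0.9·pd mS/cm²
* cortico-striatal coupling: g_CTX,STR = 0.07 − 0.044·pd mS/cm²
* GPe collaterals: g_GPe,GPe = 0.0125 + 0.0375·pd mS/cm²

`apply_parkinsonism` recomputes these from the closed forms, so repeated
application never compounds.

### Editorial parameters and what they were calibrated to

Neuron-level wiring, per-connection conductances and delays, bias
currents, and background-noise amplitudes are not fixed by the model
lineage at the level of detail needed to run; they are all explicit
`NetworkConfig` fields.  The shipped defaults were chosen **once** so
that the plant expresses the established pathophysiology of the
dopamine-depleted state:

* firing rates rise in STN and GPi and fall in GPe at pd = 1;
* spike synchrony χ rises in STN, GPe and GPi at pd = 1;
* the pd = 1 GPi LFP carries an exaggerated beta-band (13–30 Hz)
  rhythm, absent at pd = 0;
* high-frequency GPi stimulation (>50 Hz) progressively suppresses that
  rhythm.

The mechanism realized by the defaults: lowering g_m makes
indirect-pathway striatal neurons intrinsically excitable, shifting them
from sparse cortex-paced firing (~5 Hz, healthy) to regular intrinsic
~24 Hz firing — i.e. the striatal M-current reduction itself sets a
beta-rate clock, as in striatal-origin accounts of Parkinsonian beta.
One indirect-pathway neuron is wired divergently: it receives no direct
cortical contact (its drive is purely intrinsic, so the g_m threshold
gates it crisply) and innervates every GPe and GPi cell, standing in for
the aggregate divergent striato-pallidal innervation that a ten-neuron
sample underrepresents.  In the Parkinsonian state this cell imposes a
coherent ~24 Hz inhibitory rhythm on the whole pallidum — raising beta
power and synchrony together — while in the healthy state it is silent.
The two pallido-subthalamic contacts per STN cell carry dispersed
conduction delays (8 and 15 ms), which keeps the healthy STN out of a
spurious entrained mode.  Small Gaussian background currents (0.3–3
μA/cm² depending on nucleus, redrawn every 0.1 ms from a counter-based
generator) stand for afferents outside the model; they make trials
statistically independent while remaining bit-reproducible and resumable
for a given seed.

These direction and contrast properties were verified on eight seeds
(5 s runs each) and hold on every seed.

### What the defaults do not reproduce

Because the beta generator is strictly upstream of GPi
(striatum→GPe→GPi is feedforward, and the pd = 1 cortico-striatal
conductance of 0.026 mS/cm² essentially severs the only feedback route
through thalamus and cortex), GPi pulse trains cannot excite the
generator.  Low-frequency (<50 Hz) stimulation therefore does **not**
increase measured beta power in this plant: the stimulus-locked spectral
line it adds (~1 mV²) is smaller than the endogenous modulation it masks
by overriding pallidal firing pauses.  Reports of a low-frequency beta
increase require a plant in which the stimulated nucleus feeds the
oscillator; the corresponding check in the acceptance suite documents
this limitation by failing.  High-frequency suppression, the property
the controller relies on, is unaffected.

## Integration

Fixed-step explicit RK4, default dt = 0.025 ms, in a numba-compiled
kernel.  At this step the integrator-order consistency check (halving dt
on a 200 ms coupled, noise-free run) shifts no spike time by more than
0.5 ms — spiking networks are timing-sensitive, so spike-time shift, not
pointwise voltage difference, is the meaningful convergence metric; the
shipped tolerance is 0.5 ms.  Runs at finer steps (e.g. 0.01 ms) are a
config change away and were used to validate the default.

Alpha synapses are not evaluated by spike-list summation during
integration.  Each connection carries the equivalent linear system
ds/dt = (z − s)/τ, dz/dt = −z/τ, with z incremented by one per delayed
spike arrival; this reproduces the alpha kernel's impulse response
exactly (verified against an independent `solve_ivp` oracle) at O(1)
cost per step.  Delays are rounded to the integration grid and arrivals
are queued in a ring buffer, so the state (including in-flight spikes)
is resumable across simulation segments — which the closed loop relies
on.

Spikes in HH-type nuclei are upward crossings of −20 mV with a 1 ms
refractory lockout (the threshold is part of the model; the lockout is a
debouncing choice).  Cortical spikes are the Izhikevich peak events.

Initial conditions: v(0) ~ U[−70, −50] mV per neuron (seeded), gates at
their steady state for v(0), CA(0) = 0.1, u(0) = 0.2·v(0).

## Biomarker

The LFP of a population is the arithmetic mean of its membrane
potentials, analysed at 1 kHz.  Beta power is estimated per sliding
window (1 s length, 0.1 s step) by a multitaper spectrum with
time-bandwidth product 3 and 5 unit-energy DPSS tapers; windows are
demeaned; band power is the one-sided PSD integrated over 13–30 Hz (bins
× bin width, units mV²).  The dB scale is
10·log₁₀(P / 1 mV²) + 120 dB: the fixed +120 dB calibration offset
places the healthy-state setpoint of the shipped network at the ~120 dB
display level customary for this biomarker.  The offset is pure display
convention — it cancels from every error, gain, and RMSE computed on the
dB scale — and is a `SpectralConfig` field.

Synchrony is the Golomb measure χ = σ²_V / (n⁻¹Σᵢ σ²_{vᵢ}) over the full
analysed interval; note that for n independent neurons χ floors near 1/n
rather than 0, which matters when comparing small populations.  The
band-pass view of the LFP uses a 4th-order zero-phase Butterworth.

## Controllers

The tracking error is defined as e = y − y_d, the *excess* of measured
beta power over the reference.  With the plant's monotone decreasing
beta-vs-frequency relationship above 50 Hz, this orientation makes
positive gains raise the stimulation frequency when beta is exaggerated;
it is equivalent to the textbook e = y_d − y law with negated gains, and
it is the orientation under which the published gain settings (kp = 0.1
etc.) actually close the loop stably.

* **P**: u_p = kp·e.  **PI**: u_p = kp·e + ki·∫e dt, with the integral
  clamped to ±200/ki by default (anti-windup; an unbounded integral
  combined with the output clamp stalls recovery).  The derivative term
  is omitted throughout — beta power is a noisy measurement and
  differentiation amplifies that noise.
* **RBF supervisory branch**: a 1–m–1 Gaussian radial-basis network,
  h_j = exp(−‖x−c_j‖²/2b_j²), u_rbf = Σ w_j h_j.  Default m = 11 with
  centers spaced over [−2, 2] and widths 5; a 5-node preset
  (c = [−2,−1,0,1,2], b = 5) is selectable.  Weights start uniform on
  [0, 1] (seeded).  The network input is the reference beta power
  mapped affinely onto [−2, 2] (a feedforward inverse-model input);
  feeding the error instead is a config option.
* **Learning**: gradient descent on E = ½(u_rbf − u)² with η = 0.30 and
  momentum α = 0.05, where u is the *clamped* command the plant actually
  received.  Since u = clamp(u_p + u_rbf), away from the clamp the error
  gradient equals −u_p: the RBF branch integrates the feedback branch
  away, and at convergence u_p → 0 with the RBF carrying the whole
  command.  The momentum term is the standard difference
  α·(θ(t−1) − θ(t−2)) for all three parameter families (a sum-form
  momentum grows without bound and cannot be what an operational
  implementation uses).  The width gradient is the true derivative of
  the Gaussian (‖x−c_j‖²/b_j³ factor), verified against central
  differences to 10⁻⁶ relative error; widths are floored at 0.1.
* The total command is clamped to [5, 200] Hz; commands below 5 Hz are
  raised to the 5 Hz floor (stimulation never switches fully off, and
  control starts from 5 Hz).

## Closed loop

DBS is a train of monophasic rectangular pulses (300 μA/cm², 0.3 ms)
injected into every GPi membrane equation; the pulse period is
1000/u(t) ms.  After a 1 s unstimulated warm-up (the spectral window
requirement), each cycle simulates one stimulation period at the current
command, appends the GPi voltages to the running LFP, re-estimates beta
power on the trailing 1 s window (end-anchored, 1 kHz), and performs one
controller step; during the first second of control the trailing window
necessarily includes warm-up data.  The parkinsonism level and the
reference may follow schedules (piecewise-constant random pd with 1 s
dwells; 1 Hz square-wave reference).

The default reference is self-calibrated: the measured healthy-state
(pd = 0) beta power of the same network build, because the absolute dB
level is convention-dependent; a fixed-dB mode exists.  Performance is
the RMSE between the post-hoc sliding beta-power series (0.1 s grid) and
the reference over the final 4 s of a 6 s control run (N = 40 samples).
Settling time is the time from control onset until the sliding-window
beta power enters and stays within ±10 % of the reference.

## Problem sizes

Shipped experiment scales, chosen as desk-scale defaults: 5 s
characterization runs with 3 seeds; 3 s per cell of the frequency sweep
with 5 trials over 8 frequencies; 6 s of control (plus 1 s warm-up) per
closed-loop condition with 3 seeds; 10-neuron populations throughout
(the population size of the underlying model).

## Known limitations

* Single-compartment neurons and intracellular stimulus current — no
  extracellular field model, no charge-balanced biphasic pulses.
* The LFP is a population-mean potential, not a volume-conducted field.
* The low-frequency stimulation limb of the frequency–beta curve is not
  reproduced (see above).
* χ is reported on 10-neuron populations and inherits the 1/n floor.
* No synaptic plasticity; the STN is not a stimulation target.
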