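# Methods

`ifatsim` is a desk-scale software emulator of an integrate-and-fire array
transceiver (IFAT): a neuromorphic array of 65,536 two-compartment
conductance-based integrate-and-fire neurons organized as 4 quadrants x
8 cores x 2,048 neurons (64 rows x 32 columns per core), wired virtually
through address events and an external synaptic routing table.  This note
records the model, the numerical choices, what the synthetic experiments
emulate, and the limits of what they show.

## Neuron model

Each neuron has a *distal* and a *proximal* compartment, each a leaky RC
membrane with two first-order conductance synapses, coupled by a
conductance `G_comp`:

    C0 dV0/dt = G_syn,0 (E_rev,0 - V0) + G_syn,1 (E_rev,1 - V0)
                + G_leak,0 (E_leak,0 - V0) + G_comp (V1 - V0)
    C1 dV1/dt = G_syn,2 (E_rev,2 - V1) + G_syn,3 (E_rev,3 - V1)
                + G_leak,1 (E_leak,1 - V1) + G_comp (V0 - V1)

A spike is emitted when the proximal voltage `V1` crosses `V_thresh`; `V1`
is reset to `V_reset` and the neuron is locked out for `t_refr`.  The
axon-hillock positive feedback of the physical circuit is abstracted by
this threshold-reset mechanism; no explicit feedback current is modelled.
The distal compartment and the synaptic conductances are untouched by the
reset.

Synaptic strength is an 8-bit PWAM (pulse-width and amplitude modulation)
code: the four LSBs are a linear pulse-width mantissa `W`, the four MSBs a
binary amplitude exponent `A`.  One input event steps the addressed
synapse's conductance instantaneously by

    dG = g0 (1 + W/16) 2^A,

which is strictly increasing over all 256 codes and spans
log10(1.9375 * 2^15) = 4.8 decades.  The within-pulse conductance ramp is
not simulated; the code law already integrates the pulse.  Between events
each conductance decays exponentially with its `tau_syn`.

### Default parameters

The hardware's absolute electrical values are not published, so defaults
are chosen for biological plausibility and are fully configurable
(`mV`/`nS`/`ms`-suffixed values in the YAML config):

| parameter | default | rationale |
|---|---|---|
| C_mem | 1 pF | with G_leak gives tau_mem = 20 ms |
| G_leak | 50 pS | ditto |
| E_leak | 0 V | reference/rest |
| E_rev (excitatory) | 1 V | unit drive above rest |
| E_rev (inhibitory) | 0 V | shunting: reversal at rest |
| G_comp | 0.5 nS | coupling strong enough for distal drive to fire the cell |
| tau_syn | 5 ms | typical fast synapse |
| V_thresh / V_reset | 0.5 V / 0 V | mid-scale threshold |
| t_refr | 100 us | axon-hillock reset dead time; caps firing at 10 kHz |
| g0 | 1 pS | conductance-step quantum at code 0 |

`t_refr = 100 us` is load-bearing: at maximal synaptic strength it makes
the neuron emit exactly one spike per input event up to 10 kHz, which is
the regime where the measured response gain saturates at one.  With zero
refractory time, a code-255 event leaves a high-conductance tail that
free-runs the integrator far above the input rate and no gain-1 plateau
exists.

## Numerics

The engine is event-driven: external and routed events sit in a priority
queue; an active neuron advances in substeps no longer than `dt`
(default 10 us).  Within a substep:

1. conductances are evaluated at the substep midpoint (second-order
   accurate for exponential decay) and frozen;
2. the resulting 2x2 linear compartment system is propagated by its
   closed-form solution (real non-positive eigenvalues; decoupled,
   coupled and repeated-eigenvalue branches);
3. the proximal threshold crossing is located exactly within the scheme —
   closed form for a single exponential, monotone-segment bisection for
   the two-exponential case — and a neuron held above threshold by the
   refractory lockout fires exactly at lockout expiry.

Exact crossing times matter: with crossings quantized to substep
boundaries, every reset inherits the detection lateness and spike trains
drift by O(dt) per spike, which defeats any spike-time comparison over
hundreds of spikes.  With the closed-form propagator the engine agrees
with an independent dense fixed-step oracle (step dt/16, linear crossing
interpolation) to well within one `dt` per spike on recurrent networks
over hundreds of spikes.  The simpler textbook update (exponential Euler
per compartment with start-of-step conductances) is kept as the public
`integrate_step` operation and converges to the same trajectories as the
step shrinks.

Simultaneous events at one synapse add their conductance steps in stream
order.  Probe traces are sampled on a fixed grid (default 0.1 ms) to
bound output size.  Rate measurements discard a 100 ms onset transient.
Runs are bit-deterministic for fixed inputs and seeds; all randomness
flows through seeded `numpy` generators.

## Pipeline timing model

The two-tier micro-pipeline of one core is modelled as a serial front end
plus per-row pulse circuits.  An event's handshake starts when the front
end is idle *and* its target row's pulse circuit is free (an
unacknowledged event blocks everything behind it — in-order,
non-preemptive); the handshake lasts `T_latency`, then the pulse occupies
the row for `dt_pulse_base (1 + W/16)`.  Under a saturated single-row
workload the service period is exactly `T_latency + pulse width`
(throughput = 1/(T_latency + T_wait)); interleaving rows hides pulse
occupancy behind handshakes and throughput rises toward `1/T_latency`.
`T_latency = 50 ns` and `dt_pulse_base = 10 us` are free parameters —
absolute hardware throughput figures are not calibration targets, only
the shape (monotone in interleaving, non-increasing in pulse width) and
the closed-form limits are.

## Mismatch model and calibration

Fabrication mismatch is modelled per neuron as (i) a digital-weight
*offset* of the response curve, Normal(0, 8 codes) by default — the
histogram of offsets is described only qualitatively in the source
measurements, so the spread is configurable — and (ii) a *slope* of
log10(output rate) per weight code, Normal(0.0185, 0.0068).  Slopes are
rejection-sampled into `[max(mu - 3 sigma, 0.002), mu + 3 sigma]`: the
plain 3-sigma window would admit non-positive slopes at the default
parameters, and the 0.002 decades/code floor (about a tenth of the ideal
PWAM law, log10(2)/16 = 0.0188) keeps every neuron's log-linear regime
inside the 0-255 sweep so every synthesized neuron is estimable.  The
truncation changes the recovered mean by about +0.0001 and the recovered
standard deviation by about -0.0002, both inside the recovery tolerances.

The weight-sweep measurement is synthesized by the mean-rate shortcut:
the mean response crosses `0.1 x input rate` at code `80 + offset`, rises
`slope` decades per code, saturates at gain one, and the measured rate is
a Poisson spike count over the measurement duration.  The offset
estimator interpolates the 0.1-gain crossing in (code, log10 rate); the
slope estimator fits rates between twice the criterion rate and half the
input rate (2-5 kHz at 10 kHz input) — a window chosen to sit above the
threshold knee and below saturation.  Single-point calibration stores
integer corrections `round(mean(offsets) - offset_i)` externally and
removes them from routed strengths; re-calibrating a calibrated core
yields corrections of 0 +- 1 code when the measurement noise is kept
below one code (long per-code integration).

In the event-driven path, mismatch enters by replacing the code law with
its smooth log-linear envelope `dG(w) = g0 10^(slope (w - offset))`,
which for the ideal slope and zero offset reduces to `g0 2^(w/16)`.

## Rate model and vision demos

On mean-rate time scales the neuron implements a rectified-linear map of
the weight-normalized effective drive
`f_eff = sum_n f_n w_n / w_nom` (nominal weight `w_nom = 80`):
`f_out = [G_wnom (f_ext_eff - f_inh_eff)]+` with a single fitted gain
`G_wnom`.  The nominal-weight normalization is folded into the gain, and
the model is fit per neuron by least squares through the origin with
gain-one saturation points excluded.

The vision demos project 15x15 stimulus patches through 15x15 signed
Gabor kernels onto one neuron.  Stimulus intensities map to 6-bit rate
codes (0-63) at 31.25 Hz per code, so the brightest pixel drives ~2 kHz —
the top of the modelled input-frequency range.  Kernel magnitudes map
linearly to signed weights with peak 2 x w_nom; because the physical code
law is exponential while the projection model is linear in the weights,
the event-driven path transmits `byte = w_nom + 16 log2(w / w_nom)`, the
code that realizes a conductance step proportional to the linear weight.
Gabor kernels are DC-subtracted, with stripes running along their stated
orientation (a bar at angle theta drives the theta kernel maximally);
default wavelength 10 px, sigma 4 px, even phase, bar width 3 px — all
unpublished in the source and configurable here.

The demo projection neuron is programmed into the current-driven regime
where the ReLU reduction is faithful: threshold 0.01 V far below the
+-1 V symmetric reversal potentials (so g(E - V) ~ gE and excitatory and
inhibitory unit drives are equal and opposite), leak 2 pS, distal
compartment decoupled, refractory 10 us, conductance quantum 3.3 fS to
keep the 225-pixel summed drive linear, and tau_syn = 2 ms.  The residual
rectification threshold of this configuration is a few hundred Hz of
effective drive — below the trial-to-trial Poisson noise of the tuning
measurements.  At exactly orthogonal stimulus angles the event-driven
mean sits slightly *above* the rectified-linear prediction because
conductance fluctuations smooth the rectifier knee, the same
noise-smoothing visible in measured activation functions; this is the one
systematic, physically expected deviation from the fitted ReLU.

Boundary detection slides the 15x15 window at stride 1 over the valid
region (a 113x75 image yields 99x61 maps) with a single image-wide
intensity-to-rate mapping, and projects each patch through four kernels
at 0/45/90/135 degrees in either mode.  A synthetic scene generator (a
bright rectangle plus a diagonal stripe) stands in for the unpublished
photographic input.

## What the synthetic experiments do and do not show

The generators emulate the *study conditions*: Poisson/regular trains at
stated rates, 2,048-neuron cores with the stated slope distribution,
15x15 bar stimuli swept 0-180 degrees in 5-degree steps, 30 x 1 s
measurements.  Passing tests show the implementation is internally
consistent (engine vs independent oracles, model vs engine, estimator vs
generator ground truth) and reproduces the published *relative* behaviour
(gain saturation at one, threshold-linear vs noise-smoothed activation,
shunting-inhibition vetoes, throughput shape, slope statistics).  They do
not validate absolute hardware quantities — transistor-level effects,
absolute throughput and energy, temperature drift, or per-synapse (rather
than per-neuron) mismatch are out of scope.

## Problem sizes in the shipped tests

The test suite scales some experiments to keep the default run short
while preserving the measured property: the engine-vs-oracle comparison
uses 5 neurons for 0.2 s at dt = 20 us; tuning curves use a 15-degree
angle grid with 6 trials of 0.25 s; boundary-map agreement uses a 24x24
synthetic scene at 80 ms per patch.  The library defaults remain at the
full study conditions (5-degree grid, 30 x 1 s trials, full-size images),
and the mismatch-recovery experiment always runs the full 2,048-neuron
core with the complete 0-255 sweep.
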