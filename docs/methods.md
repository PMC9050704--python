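# Methods

## Model overview

`scmotormap` simulates a one-dimensional strip of the Superior Colliculus
(SC) motor map as a two-layer spiking network.  A cortical **input layer**
converts an externally applied current profile into spike trains; its spikes
drive an **SC output layer** through topography-preserving one-to-one
synapses; SC neurons interact all-to-all through conductance-based
excitatory–inhibitory lateral synapses; and a linear ensemble decoder turns
SC spike trains into an eye trajectory.  Both layers contain 200 neurons
uniformly spaced on 0–5 mm (neuron n at u = 0.025·n mm), and the whole
system is deterministic: there is no noise source anywhere, so identical
configurations yield bit-identical spike trains.

### Afferent/efferent mapping

Target eccentricity T (deg) maps to the anatomical image point
u_T = B_u·ln((T + A)/A) with A = 3 deg and B_u = 1.4 mm; the efferent map is
the exact inverse R(u) = A·(exp(u/B_u) − 1).  These constants put T = 15 deg
at u = 2.5 mm (the map's midpoint anchor) and keep targets up to ~50 deg on
the 5 mm map.  Both are config-exposed (`map.A_deg`, `map.B_u_mm`).

### External input current

I_ext(u_n, t) = I0 · exp(−‖u_n − u_T‖²/2σ_pop²) · g(t), with the gamma
profile g(t) = (t^γ e^{−βt}) / ((γ/β)^γ e^{−γ}).  Two reading choices:

* **Time units.**  t is in ms and β in 1/ms.  β = 0.03 with γ = 1.8 then
  puts the input peak at t = γ/β = 60 ms and gives burst durations of order
  150 ms (≈300 ms at β = 0.019); an s⁻¹ reading would put the peak at 60 s,
  inconsistent with any saccadic time scale.
* **Peak normalization.**  g(t) is normalized to unit peak so that I0 is the
  maximum current anywhere in space and time (in pA), as its name implies;
  the raw gamma function would otherwise scale the peak by an arbitrary
  β- and γ-dependent factor.

The **spatial sweep** varies σ_pop over {0.05 … 1.0} mm (12 values) with I0
ramped linearly from 2.0 pA at 0.05 mm to 3.0 pA at 0.5 mm and held at
3.0 pA above (the ramp's linearity in σ_pop is an assumption; only its range
is constrained).  The **temporal sweeps** vary β over 0.019–0.030 /ms at
fixed σ_pop = 0.5 mm and re-calibrate I0 per β by bisection (40 iterations
max, 1% tolerance on spike counts) so that either the SC-layer total
("fixed_output_spikes", I0 ∈ [0.2, 3.0] pA) or the input-layer total
("fixed_input_spikes", I0 ∈ [1.2, 3.0] pA) matches the default condition.
Calibration failures are flagged in the returned records, never clipped.

### Neuron model

All neurons follow the AdEx equations with conductance synapses

    C dV/dt = −g_L(V−E_L) + g_L Δ_T exp((V−V_T)/Δ_T) − q
              + g_exc(E_exc−V) + g_inh(E_inh−V) + I_ext
    τ_q dq/dt = a(V−E_L) − q

with a spike at V ≥ V_cut, reset to V_reset, adaptation increment q += b and
a refractory clamp of t_ref.  Integration is forward Euler for (V, q) and
exponential Euler for the conductances at dt = 0.05 ms; the exponential
argument is clamped at +10 slope factors; spikes are stamped at the
beginning of the step in which V crossed V_cut; synaptic events are
delivered within the same step (zero axonal delay).  The first-order scheme
converges to ~0.1 ms spike-time accuracy over burst-length windows when dt
is halved; phase error accumulates (~0.07 ms per ISI) over long tonic
trains, which none of the model's analyses depend on.

### Layer parameters

The biophysical constants of the two layers are not uniquely determined by
the published network description, so they are model design choices, fixed
once and shipped as defaults (all config-exposed):

* **Input layer** (C = 0.193 pF, g_L = 5.31 pS, t_ref = 2.5 ms, no
  adaptation): a low rheobase (~0.1 pA) makes the recruited input population
  track the Gaussian current's extent — about 10 neurons at σ_pop = 0.05 mm
  and the whole map at 1.0 mm — while the small capacitance keeps the f-I
  curve steep across the 2–3 pA sweep range (peak rate ≈190 spk/s at 2 pA,
  ≈260 spk/s at 3 pA).  The external drive passes through the saturating
  sigmoid I_sat·tanh(I/I_sat) with I_sat = 15 pA (identity within 2% up to
  the default 3 pA); together with t_ref = 2.5 ms this makes 400 spk/s a
  hard upper bound on input-layer firing.  We deliberately operate the layer
  *below* the cap: an operating point at the cap would flatten the f-I curve
  over the sweep range and erase the input-rate differentiation that the
  spatial sweep is supposed to produce.
* **SC layer** (C = 20.9 pF, g_L = 2.09 nS, Δ_T = 2 mV, V_T = −50 mV,
  V_reset = −51 mV, t_ref = 0.7 ms, a = 5 nS, b = 30 pA, τ_syn_exc = 2.5 ms,
  τ_syn_inh = 45 ms, E_exc = 0 mV, E_inh = −70.5 mV): the layer operates in
  a *trigger regime* — the feedforward drive alone is barely suprathreshold
  and the burst is carried by recurrent lateral excitation, which is what
  makes the central cell's spike count sensitive to the recruited population
  size.  Spike-triggered adaptation (b) terminates the burst after ~19
  spikes at the map center; subthreshold adaptation (a·(V−E_L)) suppresses
  re-ignition by the long input tail; the slow, near-shunting inhibition
  (τ_syn_inh = 45 ms, E_inh just below E_L) acts as a sustained divisive
  brake that confines the active population to ~0.5–0.6 mm regardless of the
  input extent.  τ_q is overridden per neuron by the rostral–caudal gradient.

### Tuned gradients and lateral kernel

The location dependence of the SC layer is carried by three fixed gradients:
τ_q(u) = 60 − 12·u ms, w^FS(u) = 10 − 1.2·u nS, S(u) = 1 − 0.04·u², and by
the Mexican-hat kernel w_exc = S_src·0.16·exp(−d²/2·0.2²),
w_inh = S_src·(1 − 1.15·exp(−d²/2·0.7²)) nS (no self-connections).  The site
gain S is taken from the **source** neuron (outgoing scaling; a config flag
switches to target-side scaling for sensitivity tests).  At short range
w_inh is negative (net disinhibition, −0.15 nS at the rostral pole); those
negative values are folded into the excitatory conductance increment so that
conductances stay non-negative while the net drive w_exc − w_inh is
preserved — at the 15-deg site the net central effect is
0.75·(0.16 − 1 + 1.15) = +0.2325 nS.  S(u) is implemented literally, so the
caudal-most neurons have (almost) no lateral output; populations evoked
beyond u ≈ 3.9 mm interact with this degenerate edge (see Limitations).

### Calibration

Only two kinds of free scale remain and `calibrate_model` resolves them
from the stock config, in order:

1. a joint multiplier on the input layer's (C, g_L) — this scales current
   sensitivity without touching any time constant — set by bisection so the
   central input neuron's peak spike-density rate for the default stimulus
   is 260 spk/s (below the 400 spk/s cap, on the steep part of the f-I
   curve);
2. the same multiplier for the SC layer, set so the central SC cell's peak
   rate is 550 spk/s;
3. the decoder gain ζ, set so the default T = 15 deg run decodes to exactly
   15 deg (ζ enters linearly, so this is a one-shot rescale).

The shipped defaults are pre-calibrated: re-running the calibration changes
no constant by more than 0.1%.

### Decoding and metrics

S(t) = Σ_n m_n·N_n(t) binned at 1 ms, with m_n = ζ·R(u_n)/N_ref and
N_ref = 500 (the population spike budget of a saccade).  The final amplitude
equals Σ_n m_n·N_n exactly — every SC spike counts; there is no omnipause
gate.  Velocity is the Savitzky–Golay first derivative (order 3).  The
**window is 31 samples**: the recurrently synchronized SC population fires
in volleys ~25–30 ms apart, and the window must span that period for the
velocity trace to reflect the burst envelope; a shorter window resolves
individual volleys and the threshold criterion then brackets a single
volley.  Saccade onset/offset are the 5%-of-peak crossings scanned outward
from the velocity peak (robust for slow near-threshold movements, where any
fixed deg/s threshold fails); note that on an exact triangular profile this
criterion yields V_peak·D/R ≈ 1.9 rather than the geometric 2.0, because 5%
of the duration is shaved off each end.  Spike densities use a Gaussian
kernel, σ = 4 ms (standard for collicular burst analysis); the central cell
of a population is the one with the maximal spike count, ties broken toward
the image point.  The main sequence V_peak = V0(1 − e^{−αR}) is fitted by
bounded least squares (V0 ≤ 10⁷, so saturation-free data converges to the
degenerate linear limit instead of diverging); V_peak·D = k·R by
zero-intercept least squares.  The ten default stimulation sites are
T ∈ {2, 5, 8, 11, 15, 19, 24, 30, 35, 40} deg — spanning the map while
keeping the recruited populations clear of the degenerate caudal edge.

## What the model reproduces, and what it does not

With the shipped calibration the model reproduces (deterministically):

* the analytic connectivity constants (net central lateral weight +0.23 nS
  at the 15-deg site; S(0) = 1, S(5) = 0; τ_q(2.5) = 30 ms);
* the default operating point at T = 15 deg: 19 central-cell spikes, 412
  total SC spikes, 545 spk/s central peak rate, a 15.0-deg decoded saccade;
* the spatial robustness: amplitude, velocity, spike counts and the
  recruited population width (~0.6 mm) are invariant within 10% for
  σ_pop ∈ [0.5, 1.0] mm and decline monotonically below, with 12 central
  spikes at σ_pop = 0.1 mm; input-layer rates never exceed 400 spk/s;
* the temporal scenarios: per-β current calibration holds the constrained
  layer's spike count within ~1–4%; with the SC budget fixed, peak eye
  velocity increases with β (shorter, stronger inputs yield faster
  movements), and with the input budget fixed, SC output grows with β;
* slow sub-default saccades that fall below the default amplitude–velocity
  relation, and a pooled kinematic slope k = 1.88 ≈ 2 across all ten sites.

Two reference behaviors are *not* reproduced, for structural reasons worth
recording:

* **Absolute main-sequence saturation.**  The fixed gradients weaken caudal
  drive faster than caudal adaptation, so site total spike counts decline
  from ~550 (T = 2 deg) to ~230 (T = 40 deg) instead of staying near the
  500-spike budget; decoded amplitudes consequently saturate near 21 deg for
  T ≥ 24 deg, the amplitude–velocity relation shows no saturating bend over
  the attainable amplitude range, and the exponential fit degenerates (V0
  at its bound, α → 0).  A search over the SC layer's free constants did not
  find a regime that restores caudal spike budgets without breaking the
  central operating point.
* **Windowed amplitude invariance across β.**  In the fixed-SC-budget
  scenario the *total* decoded displacement is invariant to ~1% (it is
  proportional to the spike budget), but the 5%-crossing windowed amplitude
  drops by up to ~29% at β = 0.019 because the stretched burst places a
  larger displacement share outside the onset–offset window.

## Limitations

One-dimensional map only (no direction coding); no intrinsic noise, so no
trial-to-trial variability; no omnipause gating or saccade-offset trigger —
amplitude control is purely input calibration plus intrinsic normalization;
no prelude or post-saccadic activity; the literal S(u) = 1 − 0.04u² makes
the caudal-most ~1 mm of the map progressively lateral-free, so sites beyond
T ≈ 40 deg should not be used.  The synchronized-volley fine structure of
the population burst is a consequence of the deterministic, zero-delay,
homogeneous network; real SC bursts are smoother, which is why the velocity
filter window matters more here than it would on physiological data.
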