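# scmotormap

A spiking neural-network model of the midbrain Superior Colliculus (SC) motor
map and of the saccadic eye movements it encodes.

The SC deep layers hold a topographic motor map: *where* a neural population
is active determines the amplitude of the upcoming saccade, while the
population's firing rates shape its velocity profile.  Microstimulation
experiments show that this machinery is remarkably robust — above a certain
input strength, evoked saccades keep their site-specific amplitude and
kinematics no matter how strongly or how long the map is driven, while weak
inputs evoke smaller *and* slower movements.  `scmotormap` implements a
one-dimensional, two-layer network of adaptive exponential integrate-and-fire
(AdEx) neurons that reproduces this robustness mechanistically, together with
the stimulation-sweep experiments and kinematic analyses used to characterize
it.  It is aimed at computational and systems neuroscientists studying
population coding in the oculomotor system.

## Model

* **Geometry.**  200 neurons per layer on 0–5 mm of the motor map, with the
  logarithmic afferent magnification `u(T) = B_u ln((T + A)/A)`
  (A = 3 deg, B_u = 1.4 mm), so a 15-deg target maps to u = 2.5 mm.
* **Input current.**  A separable Gaussian × gamma profile
  `I_ext(u,t) = I0 exp(−(u−u_T)²/2σ_pop²) · g(t)`, `g(t) ∝ t^γ e^{−βt}`
  normalized to unit peak (default I0 = 3 pA, σ_pop = 0.5 mm, β = 0.03 /ms,
  γ = 1.8).  A saturating sigmoid on the drive plus a 2.5 ms refractory
  period cap input-layer firing at 400 spikes/s.
* **Network.**  One-to-one feedforward projections with strength
  `w^FS(u) = 10 − 1.2·u` nS; all-to-all Mexican-hat lateral connectivity
  `w_exc = S(u)·0.16·G(σ=0.2 mm)`, `w_inh = S(u)·(1 − 1.15·G(σ=0.7 mm))`
  acting as a soft winner-take-all; site gain `S(u) = 1 − 0.04 u²` and
  adaptation gradient `τ_q(u) = 60 − 12·u` ms make the burst repertoire vary
  from rostral (small, fast saccades; high-rate short bursts) to caudal.
* **Decoder.**  Each spike of the neuron at u moves the eye by its fixed
  *spike vector* `m(u) = ζ·R(u)/N_ref` deg, where `R(u)` is the efferent map;
  the eye displacement S(t) is the cumulative sum of all spike vectors.  Eye
  velocity is the Savitzky–Golay derivative of S(t); the main sequence
  `V_peak = V0 (1 − e^{−αR})` and the amplitude–duration law
  `V_peak·D = k·R` are fitted over saccades decoded at ten sites.

The anatomical gradients and lateral weights are fixed model constants; the
only free scales — the current sensitivity of each layer and the decoder gain
ζ — are resolved by a documented calibration (`scmotormap calibrate`) against
the model's operating point: input-layer rates below the 400 spk/s cap, a
central SC burst rate of ≈550 spk/s, and a 15-deg decoded saccade for the
default input at the 15-deg site.  The shipped configuration is
pre-calibrated, and every simulation is fully deterministic.

## Worked example

```bash
$ scmotormap simulate -T 15
T=15.0 deg: amplitude 15.00 deg, V_peak 946 deg/s, duration 30 ms, 412 SC spikes

$ scmotormap simulate -T 15 --sigma-pop 0.1 --I0 2.111
T=15.0 deg: amplitude 5.91 deg, V_peak 287 deg/s, duration 37 ms, 132 SC spikes
```

The first command drives the input layer with the default current centred on
the 15-deg site: the recruited SC population (~0.6 mm wide, central cell
19 spikes at a ~550 spk/s peak rate) decodes to a 15.0-deg saccade.  The
second command shrinks the input population to σ_pop = 0.1 mm (with the
correspondingly swept amplitude): the evoked saccade becomes both smaller
(5.9 deg) and slower (287 deg/s) than a normal saccade of that site — the
near-threshold behavior seen in microstimulation.  Above the default input
size, amplitude and velocity stay within 10% of the site-specific values
(`scmotormap sweep-spatial`).  Pooling the default saccades from ten sites
(`scmotormap main-sequence`) gives the dimensionless amplitude–duration slope
k = 1.88, close to the triangular-profile value of 2 that real saccades obey.

Other subcommands: `sweep-temporal` (burst-duration sweeps that hold either
the input-layer or the SC-layer total spike count fixed), `decode` (apply the
spike-vector decoder to an externally supplied spike file), `calibrate`.
All outputs are plain CSV; every run is reproducible from its config file.

## Limitations

The model is one-dimensional (horizontal saccades only), noise-free, and has
no brainstem omnipause gating: every SC spike contributes to the movement,
so amplitude control rests entirely on input calibration and intrinsic
normalization.  See `docs/methods.md` for the full model description, the
calibration procedure, numerical choices, and known limitations (including
which reference behaviors the tuned network does and does not reproduce).
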