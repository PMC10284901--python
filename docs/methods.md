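# Methods

This note records the models implemented in `memspike`, the parameter
choices that matter, the numerical decisions, and what the synthetic-data
studies do and do not demonstrate.

## Device model

The volatile threshold switch is modeled behaviorally, not physically: no
electrothermal filament dynamics, no temperature dependence.  Three pieces:

1. **Comparator latch.**  A binary state flips ON the instant the terminal
   voltage magnitude reaches `v_th` (3.4 V default) and OFF the instant it
   falls to `v_hold` (1.45 V default), identically for both polarities.
   The latch responds to the *instantaneous* voltage.  This matters: if the
   branch selection instead followed the filtered state variable, a device
   behind a series load would find a stable partial-ON operating point — as
   the device starts conducting, the divider pulls its terminal voltage
   back below threshold and the switch stalls.  Relaxation oscillation
   requires the latch.

2. **Smooth drive + RC.**  A `tanh` comparator (steepness 10⁴ V⁻¹) produces
   a drive in [0, 1] toward the latched branch's target; an internal RC
   (`r0·c0` = 50 ns default, consistent with sub-70 ns switching) low-passes
   it into the state variable `v_c ∈ [0, 1]`, giving the resistance its
   finite switching time.  The update is exponential-Euler: exact for
   piecewise-constant drive, unconditionally stable.

3. **Resistance mixing.**  `1/R = (1−v_c)/r_off + v_c/r_on` with defaults
   `r_off` = 100 kΩ, `r_on` = 1 kΩ.  The ON/OFF values, like `r0·c0`, are
   order-of-magnitude configuration values, not measured constants.

In the transient circuit kernels the *latch-ON* test uses the nominal HRS
divider (device at `r_off`).  The soft comparator's subthreshold tail
otherwise leaks a little conductance into the divider and pins the device
voltage a hair below threshold whenever the approach is slow — an artifact
of the behavioral softness, not of the physics the model is meant to
capture.

## Neuron circuits

**LIF oscillator** — memristor (plus 50 Ω readout resistor) parallel to
`c_mem` (1 nF default), driven through `r_load` (18 kΩ default).  Integrated
with fixed-step exponential Euler at `dt = min(r0·c0, τ_c)/50`.  Spikes are
read from the readout-resistor voltage (rising-edge crossing of half the
peak, floored at half the minimum physical spike amplitude
`v_hold·r_read/r_on` so a spikeless trace yields no events).

The closed-form oscillation period used as the test oracle is the two-phase
RC expression: charge time `τ_c·ln((V∞−V_hold,eff)/(V∞−V_th,eff))` with
`τ_c = c_mem·(r_load ∥ (r_off+r_read))`, plus the analogous LRS discharge
term.  It neglects the device switching time, so simulation and closed form
agree to the stated 2% only when the period is long against `r0·c0`; the
comparison is run at `c_mem` = 10 nF (period ≈ 59 µs vs. 0.25 µs of
switching overhead, observed error ≈ 0.5–1%).

**ALIF** — the same core plus `r1` = 500 Ω in the firing path, an
adaptation store `c2` = 20 nF charged by `i_adapt` = 0.5 mA during each
output spike and drained through `r3` = 100 kΩ (`τ_a` = 2 ms ≫
`τ_m` ≈ 0.1 ms, enforced at construction), and a threshold-linear leak
transistor: `i_leak = g_leak·max(0, v_g − 0.7 V)` with `g_leak` =
0.28 mA/V, active only while the membrane is above ground (the transistor
cannot source current into the capacitor).  With these values the firing
cutoff sits near `v_g ≈ 1.65 V` and a 0.3 mA step input produces the
canonical adaptation transient: constant initial ISI ≈ 5 µs, monotone
growth, saturation near 25 µs.  ISI monotonicity is asserted with a 2%
tolerance: spike times are quantized to the integration grid and the
saturated regime breathes around its limit cycle.

The LIF simulation is the ALIF kernel with the feedback disabled, so
"feedback off ⇒ identical to LIF" holds bitwise by construction (and is
still asserted).

## Delta encoder

The behavioral encoder tracks a reference starting at `signal[0]`; a
sample with `signal − ref ≥ δ` emits UP and advances the reference by δ
(symmetrically DOWN), at most one event per channel per sample — a jump of
kδ spreads over the next k samples, modeling the finite reset time.  Event
times are the sample instants.  Exact-threshold ties fire; the comparison
carries a 10⁻⁶ relative slack because the accumulated reference makes an
exact `≥` knife-edged in floating point.

The circuit-level encoder simulates the loop with the device model in it:
the differentiator node accumulates input changes, the amplified node
voltage drives the memristor through `r3`, an HRS→LRS transition emits the
event, and an idealized feedback reset removes exactly one δ charge packet
within the sample (op-amps, diodes and reset transistors are ideal; the
gain is chosen to invert `δ = V_th/(α·R_off/(R_off+R_3))` exactly).  Under
these idealizations its event train equals the behavioral encoder's on
smooth signals — asserted exactly in the tests.

Threshold fluctuations are modeled by re-drawing the pending threshold as
`δ(1 + cv·z)`, `z` standard normal (non-positive draws rejected), after
every event; reconstruction still assumes the nominal δ, so the mean
reconstruction MSE grows with `cv` (the study direction asserted over 100
seeds at cv ∈ {0, 0.05, 0.15}).

## Recurrent spiking network

Dynamics exactly as in the README equations, with hard threshold at
`v_th_eff` (3.4017 V: threshold through the HRS + readout divider), reset
to `v_hold_eff` (1.5225 V), per-unit constants `a = exp(−Δt/(R_eff C₁))`
(τ_m = 20 ms at Δt = 1 ms) and `b = exp(−Δt/(R₃C₂))` (τ_a = 600 ms, on the
scale of a full input sequence).  The first `n_alif` hidden units are
adaptive.  Integer synaptic delays are drawn uniformly from {0..5} per
input and recurrent connection; the readout is undelayed so the decision
timestep is not shifted.  Recurrent self-connections are structurally zero.

Choices worth flagging:

* **Adaptation increment.**  One spike moves `v_g` by `(1−b)·R₃·I_a` ≈
  0.6 V (default `i_a` = 60 µA).  The leak gate opens only above 0.7 V, so
  the increment must let a burst of a few spikes reach the gate — with
  much smaller increments the gate never opens and the gradient through the
  adaptation pathway is identically zero, removing the network's memory
  mechanism.

* **Readout trace.**  Hidden spikes feed `f ← κf + z`, κ = exp(−1/τ) with
  τ = 20 steps by default (300 for the EEG study, where the decision must
  integrate evidence over most of the clip).  The trace is deliberately
  *not* normalized to unit DC gain: with sparse spikes a normalized trace
  is O(0.01) and the readout weights would need to grow two orders of
  magnitude beyond their initialization before the logits move — outside
  what a few hundred optimizer steps deliver.  Same filter, saner feature
  scale.

* **Initialization.**  Weights are Gaussian with 1/√fan-in scale;
  input weights are multiplied by `input_gain` = 8 because the inputs are
  sparse binary events and the units must start within the surrogate's
  support to receive any gradient; the CUE channel's input weights start
  positive so the hidden layer is tonically active during the output
  window — the readout can only see which units adaptation has silenced if
  units are otherwise firing then.

* **Loss.**  Cross-entropy of the last-timestep softmax plus
  `(λ_f/N)·Σ(f̄_n − f₀)²` with `f̄_n` the per-unit rate averaged over batch
  and time and divided by Δt (so in Hz).  At Δt = 1 ms and `f₀` = 10 Hz the
  rate term is numerically large; the default `λ_f` = 10⁻⁴ balances the two
  terms.  Training is Adam (defaults lr 10⁻³, batch 32), fully
  deterministic given the seed.

* **Gradients.**  BPTT propagates through the reset and the adaptation
  recursion; the spike derivative is `γ·max(0, 1−|x|)/v_th_eff` with
  `x = (v − v_th_eff)/v_th_eff`, γ = 0.3.  The backward pass is validated
  against central finite differences on a twin network whose activation is
  the exact antiderivative of the surrogate (continuous, so finite
  differences are meaningful); agreement is ~10⁻⁶ relative on a 3×5×2 net.

## Synthetic data

Heartbeats are sums of Gaussian bumps (P, Q, R, S, T) with class-specific
centers/widths/amplitudes and seeded jitter, normalized to 0–0.6 V, 1000
samples at 1800 Hz; the four classes follow standard clinical morphology
descriptions (ventricular beats wide with discordant T and no P; early
supraventricular beats with abnormal P; fusion intermediate).  EEG clips
are 1/f background noise per channel (std 30 mV around 0.3 V); seizure
clips add a 3–12 Hz oscillatory burst with cross-channel correlation 0.7
and ±0.22 V envelope; 18 channels × 1000 samples at 800 Hz.  Test-sequence
normal clips additionally carry brief non-rhythmic movement artifacts with
probability 0.12 — artifacts the *training* clips lack.  That train/test
domain shift is deliberate: real seizure classifiers trained on limited
data emit scattered false positives on artifact-laden recordings, and the
post-processing stage exists to remove exactly those; a synthetic test set
on which the classifier is perfect would leave it nothing to do.

None of this claims clinical realism.  What the passing tests show is that
the pipeline — encoding, network, training, post-processing — behaves as
designed on signals carrying the same *kinds* of structure (morphology
differences, rhythmic high-amplitude bursts, sparse contiguous positives);
accuracy numbers on these generators say nothing quantitative about real
recordings.

## Study sizes and benchmarks

Chosen for single-CPU runs:

* Burst discrimination: 240 samples (192/48 split), T = 100 + 25 cue
  steps, 3×20×2 network with 8 adaptive units, ≤ 50 epochs.
* Cue-gap memory: burst at steps 10–30 on channel 0 or 1, silent gap to
  step 200, 40 cue steps — the gap is ~9 membrane time constants, so a
  LIF-only network stays near chance while the mixed network solves the
  task through its adaptation variable.
* Seizure study: 300 balanced training clips, 25 epochs; test sequence of
  2878 contiguous clips with one 31-clip seizure run; per-clip decision at
  P(seizure) ≥ 0.2 — a sensitivity-first operating point, as appropriate
  for a screening task where the post-processor absorbs false alarms;
  post-processing window 9, threshold 0.8.

## Post-processing

Centered moving average of odd width (edges use the window that fits),
then strict `average > threshold`.  Two properties worth stating because
they are easy to assume wrongly: the operation is *not* idempotent at
threshold 0.8 (each application needs 8-of-9 positives, so it trims ~3 more
clips off each edge of a solid run — repeated application keeps shrinking
it), and it therefore reduces the sensitivity of even a perfect classifier
at the run edges while leaving the run interior and the specificity intact.
Metrics with empty denominators are reported as undefined, never as zero.

## Known limitations

* The device model has no temperature or history dependence and no
  device-to-device variability beyond the encoder's threshold-noise hook.
* Transistors in the ALIF feedback are reduced to a per-spike charge packet
  and a threshold-linear leak; no SPICE-netlist compatibility.
* The LSNN trains small networks on a CPU; there is no GPU path and no
  quantization or crossbar mapping.
* Real-record ingestion is a plain CSV reader; annotated clinical databases
  are out of scope.
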