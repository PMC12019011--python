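# Methods

This note records the models the toolkit implements, the defaults it
ships, the numerical choices behind the pipelines, and what the
synthetic-data validation does and does not establish.

## Stimulus model

The stimulation command is a ramp–hold–ramp profile parameterized by
amplitude `A` (mA), ramp length `S` (ms) and hold length `D` (ms):

```
f(t) = A·sin(π/2 · t/S)               0 ≤ t < S
       A                              S ≤ t < S+D
       A·sin(π/2 − π/2·(t−S−D)/S)     S+D ≤ t ≤ 2S+D
```

The quarter-sine ramps make the onset/offset smooth (no tingling from
abrupt steps) and the waveform is continuous at both junctions and
symmetric about `t = S + D/2`. `S = 0` degenerates to a step and is
accepted with a logged warning. The API works in milliamps and
milliseconds, matching how stimulation protocols are written; sampled
traces carry seconds and Hz.

An n-bit DAC code maps linearly onto `[−N, +N]` mA via
`I = 2N/(2ⁿ−1)·Dₙ − N`; the inverse rounds to the nearest code with
ties away from zero, so round-trip error is at most half an LSB
(`N/(2ⁿ−1)`, ≈ 0.98 µA at n = 12, N = 4). The DAC-voltage law is
`I = N·V_DAC/V_ref − N` with `V_ref = 2.65 V` (half the maximum DAC
output, giving symmetric bipolar control).

Band-limited noise (for noisy-GVS work, up to 640 Hz at ≤ 1 mA) is
synthesized in the frequency domain — unit magnitude and uniform random
phase on every bin up to the requested bandwidth, zero above — then
mean-removed and peak-rescaled. This gives exact band-limiting and an
exactly zero mean, at the cost of a Gaussian-ish (not strictly bounded)
crest profile before rescaling; reproducibility is per-seed.

The safety limit defaults to 4 mA (the accepted bound for low-intensity
transcranial electrical stimulation) and is enforced at waveform
construction and by `enforce_current_limit` (raise by default, clip as
an opt-in policy). The manual-search increment for perception testing
is exposed as a parameter rather than fixed.

## Circuit model

The enhanced Howland current source is modelled at three levels:

1. **Balanced closed form.** With bridge ratios `R1/R2 = R3/R4 = k`,
   the load current is `i_L = (u⁺ − u⁻)/(k·R₀)`, independent of load.
2. **Exact nodal analysis** of the unbalanced bridge (ideal op-amps,
   buffered sense resistor): a 3×3 linear solve for the shared op-amp
   input voltage, stage output and load node. It reduces to the closed
   form exactly on balanced ratios (property-tested to 1e−9 relative)
   and exposes the load-dependence and zero-input offset that resistor
   mismatch causes on real boards.
3. **Device simulation**: command voltage → current → differential load
   voltage, split symmetrically across the two electrodes around
   mid-supply (channel A in phase with the command, channel B in
   anti-phase), plus white measurement noise, optional narrowband
   boost-ripple, and hard clipping `swing_margin` (3 V) from the rails.

Defaults: `k = 4.99` (49.9 kΩ over 10 kΩ, per the bill of materials)
and `R₀ = V_ref/(k·N) ≈ 132.8 Ω`, chosen so the transconductance equals
`N/V_ref` exactly and the DAC law above holds; the BOM's 100 + 30 Ω
sense pair is consistent with this to ≈ 2 %. The exact build values are
not unambiguous from the published BOM, so these defaults are an
assumption, and every quantity derived from them is configurable.

The compliance budget is `V_required = I_max(R_max + R_sense) +
V_headroom` (4 mA across 0–5 kΩ plus a 100 Ω sense resistor → 20.4 V
minimum), and the boost converter supplies `V_out = 0.6·(1 +
(R₉+R₁₁)/R₁₂)` = 24.6 V with the BOM divider. Saturation under the
symmetric-drive convention begins at `|I| = (V_supply/2 −
margin)/(R/2)`; note that at the full 5 kΩ corner this is 3.72 mA at
24.6 V/3 V margin, i.e. the supply sized by the budget leaves the last
~0.3 mA of range to headroom better than the worst-case 3 V swing spec.

Two reference voltages coexist deliberately: `vref_V = 2.65` (the
control law) and `vref_fra_V = 2.6` (the offset constant the
frequency-response gain convention uses). They differ in the source
material and are carried as separate configuration keys rather than
reconciled; the ≈ 0.165 dB gain difference between the conventions is
real and visible when comparing simulated sweeps against the analytic
expectation.

Resistor-tolerance Monte Carlo perturbs R1–R4 and R₀ independently and
uniformly within ±tolerance (a tolerance is a guaranteed bound, not a
standard deviation) and records the zero-command output current from
the nodal solve with both inputs at 2.65 V. With 1 % parts the 95th
percentile of |offset| lands at the few-hundredths-of-a-milliamp scale,
matching what a multimeter shows on an uncalibrated board; calibration
subtracts a measured offset and is exactly invertible.

## Characterization pipelines

**Precision & stability.** Recordings (50 kS/s default) are low-pass
filtered with an order-5 Butterworth at 10 kHz, applied forward and
backward (`sosfiltfilt`) so the net phase is zero and the effective
magnitude is the squared single-pass response
`|H| = 1/√(1 + (ω_d/ω_c)^{2N})`. The digital design uses the bilinear
transform with pre-warping, so the half-power point lands exactly at
the cutoff. Holding-state segmentation estimates the plateau as the
median of `|v_diff|` over samples above half its maximum, keeps maximal
runs above 0.9× that plateau, trims 5 % per edge and drops runs under
50 ms — the threshold technique named in the source procedure with
concrete values chosen here (all configurable). Metrics are computed on
the differential voltage (A − B), with per-channel SDs also reported
because published figures are ambiguous about which was tabulated;
`σ_I = SD/R` and `error = 100·σ_I/|I_set|` are recomputable from the
returned fields by construction.

**Frequency response.** Per-channel medians over an initial window are
subtracted (median, not mean, so a partial cycle in the window does not
bias the estimate; synthetic sweeps include a 1 s idle lead-in for this
purpose). Signals are decimated by 10 with a 31-tap Hamming
windowed-sinc FIR at 0.8× the new Nyquist, applied forward-backward so
no group-delay compensation is needed; passband tones survive within
1 %. Each nominal sweep frequency is measured at the command spectrum's
dominant bin within ±0.5 Hz; gain is the bin-magnitude ratio in dB and
phase the wrapped bin-phase difference. Sweep segments are analyzed
individually (each holds an integer number of cycles, so the tone lands
on/near a single bin); command bins below 1e−3 of the spectrum maximum
are flagged unresolved rather than reported. Optional moving-average
smoothing uses a window of `max(1, round(0.5 Hz/Δf))` points — the
frequency-resolution-based choice, with the 0.5 Hz constant ours.

The analytic expectation for a single electrode is
`G = 20·log₁₀((N/V_ref,fra)/2 · R)`: 1.13, 6.23 and 9.43 dB at 1481,
2663 and 3850 Ω. These sit within 0.03 dB of the published
circuit-simulator references (1.152/6.251/9.455 dB); the residual is
attributed to op-amp non-idealities present in the SPICE model but not
in the ideal small-signal form. Pairwise gain differences obey
`20·log₁₀(R_a/R_b)` exactly — the model's load-only dependence.

## Staircase psychophysics

The 3-down-1-up rule starts at 1.6 mA with 0.1 mA steps: three
consecutive correct left/right judgements step down, any incorrect
steps up, the correct-streak resets after every step and every
incorrect response, and the session ends at six reversals. A reversal
is logged at the pre-step level (the local extreme); this convention is
documented because the source protocol is silent. Levels clamp to
[0.1, 1.8] mA, mirroring the observed stimulus range; clamped steps
count as reversals only via their direction. The rule's equilibrium is
the level answered correctly with probability `0.5^(1/3) ≈ 0.7937`.

The default JND estimator is the mean of all recorded reversal levels,
with "last n reversals" selectable. The simulated observer is a
cumulative Gaussian with 2AFC guess rate 0.5 and default lapse rate
0.02; its analytic 79.37 %-correct point is
`θ + s·Φ⁻¹((0.7937 − 0.5)/(0.5 − λ))`.

Validation facts the test-suite establishes, and one bias worth
knowing: the track itself is unbiased — late-reversal means over long
tracks sit within ~0.01 mA of the analytic point — but the short
six-reversal protocol started at 1.6 mA reads high (≈ +0.1–0.2 mA for a
0.7 mA-threshold observer) because the first reversals occur during the
initial descent, often triggered by lapses well above threshold.
Parameter-recovery validation therefore runs 12 reversals and averages
the last 8, the standard practice of discarding pre-asymptotic
reversals; the transient bias of the short protocol is itself asserted
in the suite rather than hidden. Consequences for real use: a
six-reversal JND is a protocol-defined quantity, comparable across
participants measured the same way, but not an unbiased estimate of the
79.4 % point when the start level is far above threshold.

Group summaries use the sample SD (n−1); between-group comparison is
Welch's unequal-variance t-test with Welch–Satterthwaite fractional
degrees of freedom (matching the reporting style `t(9.47) = 0.82`).

## Synthetic data: what it does and does not show

The fixture generator (`interfaces.synth_recording`) emulates a current
source driving a resistive load through two mid-supply electrodes:
exact Ohm's-law differential voltages, independent white measurement
noise per channel, optional narrowband ripple, a constant DC offset
error, rail clipping, and per-seed reproducibility. Problem sizes used
in the default suite: ~0.6–2 s recordings at 50 kS/s, 1–20 Hz sweeps
with 3 repeats, 200–500 staircase sessions, 1000-sequence rule
equivalence checks, 2000-draw tolerance Monte Carlos.

What passing on this data shows: the pipelines are numerically correct
(filters, segmentation, spectral extraction, rule bookkeeping, and the
algebra tying them together) and recover known ground truth under the
stated noise model. What it does not show: behaviour under real
electrode drift, electromagnetic pickup, boost-converter switching
artefacts beyond a single sinusoidal ripple tone, non-resistive
(capacitive, time-varying) tissue impedance, op-amp bandwidth/slew
limits, or human response biases beyond a stationary psychometric
function. Conclusions about a physical board still require its own
recordings.

## Degenerate inputs and tie-breaks

* `S = 0` ramps → step waveform, warning logged.
* DAC mid-scale current 0 mA → code 2048 (ties round away from zero).
* Zero-variance groups with equal means → `t = 0, p = 1`.
* `i_set = 0` → error rate reported absent rather than infinite.
* Recordings shorter than the filter warm-up, empty offset windows,
  non-monotone or jittered (> 1 ppm relative) time axes, commands
  outside `[0, 2·V_ref]`, and currents beyond full scale all raise
  typed errors rather than propagating garbage.
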