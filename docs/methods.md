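# Methods

This note documents the models, the calibration and its rationale, the
numerical choices, and the limits of what the synthetic experiments show.

## Device model

The VO₂ threshold switch is a volatile two-state resistor with voltage
hysteresis. State HRS (insulating, `r_off`, default 20 kΩ) switches to LRS
(metallic, `r_on`, 300 Ω) when the device voltage reaches the effective
threshold `v_th`; LRS releases to HRS at `v_hold`. Because `v_hold < v_th`
the switch is bistable over a voltage window, which converts RC charging
into relaxation oscillation. Defaults `v_th = 4.0 V`, `v_hold = 1.7 V` are
round nominal values inside the measured device-to-device spans
(3.55–4.10 V and 1.52–1.96 V over 40 devices); both spans are available to
the device sampler.

Two stochastic layers, both seeded:

- **Cycle-to-cycle jitter** — at every transition the effective thresholds
  are redrawn as `v·(1 + σ·N(0,1))` with relative σ of 2.1·10⁻⁴ (`v_th`)
  and 1.3·10⁻⁴ (`v_hold`). The measured deviations are printed without
  units; we interpret them as relative standard deviations (they are tiny
  either way). Ordering violations are redrawn up to 100 times, then error.
- **Device-to-device spread** — `sample_devices` draws `v_th`, `v_hold`
  independently and uniformly from configurable intervals.

Finite switching times (saturated values 115 ns / 90 ns are shipped as
constants) are modelled as a pure dead time: the resistance holds its
pre-transition value for `t_sw`, then switches instantaneously. The default
is zero dead time, which keeps the closed-form period oracle exact; with
dead time enabled the capacitor overshoots the thresholds during the dead
interval, so the period exceeds the naive `T + t_sw_on + t_sw_off` (the
tests assert exactly this behavior). No transition waveform shape is
claimed beyond that.

## Oscillator network

One node is `v_dd — r_load — (c_parallel ∥ device)`. Feasibility
(`check_oscillates`): the HRS divider level `v_dd·r_off/(r_load+r_off)`
must exceed `v_th` and the LRS level must fall below `v_hold`; otherwise
the node sticks. The uncoupled period is the exact two-phase RC solution
(see README); for the printed circuit values (10 V, 8.2 kΩ, 10 nF) it is
35.22 µs. A validator warns above the device's measured 2.6 MHz limit.

Coupling capacitors add `C_ij·d(V_j−V_i)/dt` terms. Collecting derivatives
gives `M·dV/dt = b(V)` with `M[i,i] = c_i + Σ_j C_ij`, `M[i,j] = −C_ij`:
symmetric, strictly diagonally dominant, inverted once per run.

**Integration.** Fixed-step explicit midpoint (RK2) with the device states
frozen within a step; default `dt = min-RC/200` where min-RC is the
smallest `(r_load ∥ r_on)·c_parallel` (the discharge phase is stiffest).
After a step that crosses a threshold, the crossing is located by bisection
on the step length to `dt/100` before the state switches — uncontrolled
event timing would bias the period. Simultaneous crossings switch in
config node order. The inner loop is compiled with numba; the recorded
time base is re-anchored to the exact grid each step. Single-oscillator
period error against the closed form is ~2·10⁻⁴ at the default step.

**Start-up.** The hardware uses a divider start-up stage so that the phase
mode reached after coupling is reproducible. We emulate the mechanism, not
the (unpublished) component values: node i of N starts at
`v_hold + i/(N+1)·(v_th−v_hold)` — deterministic, pairwise distinct,
sub-threshold. A seeded randomized mode (uniform in `[0, v_hold]`) serves
the attractor-basin experiments.

**Collective states** (all verified by the test suite): identical pairs
lock anti-phase (the coupling capacitor's plates accumulate opposite
charge, a mutually inhibitory interaction); identical all-to-all triples
lock in the 120° splay state; detuned oscillators lock within a finite
range with a detuning-dependent phase, and the locking range grows with
coupling capacitance (22 → 47 → 100 pF). At a coupling ratio
`C_c/C_s ≳ 0.25` the pair attractor flips to in-phase; the default
calibration stays below that.

## Waveform analysis

Phases are measured the way the hardware measurements define them: from
spike peak times, not analytic signals. Peaks are prominence-filtered local
maxima (default prominence 10% of peak-to-peak) refined by 3-point
parabolic interpolation; in phase analysis a minimum peak spacing of 0.6
periods suppresses noise-induced secondary maxima. The dominant frequency
is the largest non-DC FFT bin with quadratic interpolation, plus a
subharmonic correction: coupling kinks can push a harmonic above the
fundamental for relaxation waveforms, so the estimator steps down to k/2 or
k/3 when that bin holds ≥ 50% of the peak magnitude.

Synchronization: per-channel dominant frequencies over the post-transient
window agree within `rel_tol` (default 1%; the hardware papers report
consistency but no tolerance, so this is an engineering choice). Default
transient cut: max(20 µs, 3 reference periods). Phase pattern: T = median
reference inter-peak interval; per channel, the circular median of matched
peak offsets `(t_i − t_ref) mod T`, expressed in degrees in [0, 360) with
the reference at 0. Circular statistics avoid wrap bias at 0/360; a
circular spread above 20° raises `unstable-phase`.

## Sensor calibration — why the shipped numbers

Capacitive sensors increase capacitance with stimulus (pressure compresses
the gap; stretch sensors are proportional to elongation):
`C = c_base·(1+ε)·(1+gain·s)` with per-trial jitter ε. The hardware's
sensor capacitance ranges are unpublished, so the calibration is a
documented stand-in (`src/oscsense/data/default_calibration.json`), chosen
around two measured facts of the simulator:

1. **The locking budget.** At the printed 100 pF coupling, the pairwise
   locking range is ≈ 0.4·(C_c/C_s) in relative capacitance mismatch, and
   the anti-phase/splay regime requires C_c/C_s ≲ 0.2. The shipped
   `c_base ≈ 500 pF` (rest frequency ≈ 410 kHz, safely under the 2.6 MHz
   device limit) sits at that optimum, giving ≈ 8% of usable mismatch
   budget. A calibration with rest frequencies near 100 kHz (C_s ≈ 3 nF)
   would leave a < 2% budget, within which no gesture or mixed mode could
   both detune and stay locked — so the frequency scale, not the relative
   structure, is where this model departs from the hardware's published
   anecdotes.
2. **Symmetry breaking.** Scaling all sensing capacitances uniformly is
   (up to the fixed coupling capacitors) a pure time rescaling, which
   leaves relative phase patterns unchanged — identical sensors could
   never separate all-rest from all-pressed. The three stretch sensors are
   therefore deliberately heterogeneous: `c_base` 500/503/506 pF and
   `gain` 3.0/4.5/6.0%, which places all 8 binary modes inside the locking
   budget (worst-case pairwise mismatch 7.3%) at 8 distinct phase-locked
   states (minimum inter-mode distance ≈ 24° against ≈ 5° intra-mode
   spread at the default 0.1% sensor jitter and 30 dB measurement SNR).
   The touch task uses a 575 pF reference and a pressure gain of 15%, so
   the untouched sensor sits far outside the locking range and the touched
   sensor lands on the reference.

Stimulus conventions: bent/pressed = 1.0, extended/rest = 0.0; bit strings
map 1 → bent, fingers ordered (thumb, forefinger, middle); rock bends all
three, paper none, scissor only the thumb. "Rock" consequently has the
lowest synchronized frequency, as in the hardware.

## Readout and decision network

**Features.** Relaxation waveforms are time-rescale invariant, so the time
averages of raw (or delayed) voltages are the same for every stimulus —
no affine readout of instantaneous voltages can fit distinct constant
targets, however it is trained. Phase must enter through second order: the
feature vector is the per-channel standardized voltages, their delayed
copies, and all lagged pairwise products (a mixer / phase-detector front
end; the product means are lagged cross-correlations, i.e. the phase
pattern). Three taps at one-third-period spacing make the longest lag one
full period, whose autocorrelation doubles as a sharp frequency
discriminator. A boxcar over ~one period low-passes the features
(post-mixer filter), removing ripple-induced least-squares shrinkage. The
tap delay is frozen into the trained weights so training and evaluation
use identical features.

**Training.** FORCE = recursive least squares with `P₀ = I/λ`; processing
a finite stream at update stride 1 is algebraically identical to
ridge-regularized batch least squares (asserted to 10⁻⁶). Targets are +1
for the correct class, −1 elsewhere. Training windows are the trailing
40 µs of each trace (fully locked), repeated twice; test windows start at
seeded random offsets just after the transient, disjoint from training.
`λ = 100` is deliberately strong: with a handful of training trials the
smoothed, highly collinear features otherwise let the fit lean on
trial-specific noise directions and generalization collapses (validated on
held-out trials during calibration).

**Decision network.** The reduced mean-field model's published parameter
tables are not available, so the shipped constants are a validated working
point of the same family: α=0.3, β=0.7, γ=0.641, θ=1, τ_s=100 (DM clock
units, Euler step τ_s/200 — halving it moves final activities < 10⁻³),
J_E=2.0, J_M=−1.0. With unit-scale feedforward drive this is a clean
winner-take-all: at a 10% input margin the winner ends at r ≈ 5.9 and the
loser at ≈ 2% of it. The decision threshold `r_dec = 2.5` sits between the
suppressed branch (r ≲ 1.5), the symmetric-deadlock plateau (r ≈ 2.3), and
the winning branch (r ≳ 3.5). Exact final ties report "undecided" rather
than an arbitrary winner, and undecided trials count as errors. The DM
clock is decoupled from circuit time; waveform samples map one-to-one onto
DM steps via linear interpolation.

## What the synthetic data does and does not show

The generator reproduces: hysteretic relaxation oscillation with the
printed device constants, capacitive-coupling synchronization and its
locking ranges, phase-difference encoding of capacitive stimuli,
measurement noise (30 dB SNR), sensor jitter, cycle-to-cycle and
device-to-device variability, and deterministic start-up. It does not
model: the Mott transition's electro-thermal microphysics, temperature or
optical sensitivity, parasitics or instrument loading, the unpublished
start-up divider values, or the physical characteristics of the commercial
sensors. Passing tests therefore validate the dynamical and algorithmic
claims at desk scale, not hardware-numeric agreement; hardware-measured
figures (2.6 MHz, 45 kHz rock frequency, the measured gesture phase
triples, energy-delay products) appear only as representation or
serialization checks, never as simulation targets.

## Known limitations

- **Variation tolerance is bounded by the locking budget.** The three-node
  network at 100 pF absorbs ≈ 8% natural-frequency spread. Thresholds
  drawn from the measured device-to-device intervals at *half*-width
  produce 7–13% spreads, so synchronization survives only for favorable
  draws; at *quarter*-width the bare network locks reliably, and the full
  8-mode task (which adds up to 7% stimulus detuning on top) holds ≥ 7/8
  accuracy at *eighth*-width draws. This ordering — stimulus budget plus
  variation budget must fit inside one locking range — is a property of
  the model, and the acceptance script reports all three scales.
- The anti-phase/splay regime constrains the coupling ratio from above
  (≲ 0.2), so coupling cannot simply be strengthened to widen tolerance.
- The phase convention folds offsets into [0, 360); a splay state is
  reported as e.g. (0°, 240°, 120°) depending on which neighbor leads.
- CSV is the only waveform container; runs at the shipped durations are a
  few MB at most.
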