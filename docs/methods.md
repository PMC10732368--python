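# Methods

This note documents the models implemented in `bimanual_adapt`, the
assumptions behind the synthetic-experiment generator, and the numerical
and design choices that were genuinely open.

## Task design

The condition grid crosses three speed classes per hand — 15 cm @ 45 cm/s,
20 cm @ 60 cm/s, 25 cm @ 75 cm/s, each with a ±10% peak-speed compliance
band and a nominal 700 ms movement time — into 9 bimanual conditions
(`b_<left><right>`), plus 3 unimanual conditions (`u_s/m/f`, left hand
only). The schedule has three phases of 48-trial blocks:

* **baseline** (6 blocks, 288 trials): blocks 1–5 present every condition
  3× in the null field plus 1 error clamp; block 6 previews the trained
  mixture (14 null + 2 clamp per trained condition).
* **exposure** (20 blocks, 960 trials): 14 force-field + 2 clamp trials per
  trained condition per block.
* **generalization** (20 blocks, 960 trials): 12 force-field trials per
  trained condition plus one clamp trial for each of the 12 conditions.

Within-block order is a uniform shuffle from a splittable seeded generator
(the design only requires randomization within blocks). No constraint
prevents consecutive clamp trials; none is claimed by the design, and block
composition is asserted exactly in tests. The block-6 baseline recipe is
applied identically to both groups using each group's trained conditions.

## Synthetic kinematics

Reaches are minimum-jerk along +y: `v(τ) = (d/T)(30τ² − 60τ³ + 30τ⁴)`,
peak `1.875·d/T` at mid-movement. Because a fixed 700 ms duration would
put the long reach's peak (~67 cm/s) outside its compliance band, the
**duration is rescaled so the peak speed equals the class target**
(T = 1.875·d/v_peak = 625 ms for all three classes — peak speed, not
duration, is the experimentally controlled quantity). Trial-to-trial
variability multiplies the peak speed by a normal draw centred on 1 with
cv = 0.05, chosen so ~95% of draws land inside the ±10% band, matching the
compliance observed in practice; the travelled distance is preserved.
The right hand leads the left by 20 ms in bimanual trials (a small
dominant-hand lead is reported qualitatively but without a magnitude; the
value is a package default, configurable in `KinematicsConfig`). Trials are
recorded at 1 kHz with 300 ms pre-movement and 200 ms post-movement rest.

This temporal lead matters scientifically: within any single condition the
two hands' speed profiles are proportional (equal durations), so the
encoding weight is identifiable only across conditions with distinct
speed ratios — or, for the matched-speed (ambiguous) regime, through the
lead and the independent per-hand speed noise. The generator reproduces
exactly this structure.

## Field, channel and learner

Force-field trials apply `F_left = [[0,−B],[B,0]]·v_right` with
B = 13 N·s/m; for forward reaches the field pushes the left hand leftward,
and perfect compensation is `+B·v_y,right`. Clamp trials record the
commanded (wall-pressed) lateral force; a constant per-trial force offset
(sd 0.1 N, emulating posture-dependent transducer drift) and white
execution noise (sd 0.3 N) are added.

The simulated participant is a single-rate state-space learner: its
compensation gain updates on force-field trials as
`α ← a·α + b·(1−α)` (retention a = 0.99, learning rate b = 0.04,
asymptote b/(1−a+b) = 0.8, rising within the first exposure block) and is
held on clamp/null trials, where movement error is (near) zero; a
`clamp_update` flag enables the alternative. The predictive lateral force
is `α·B·(ω·v_R + (1−ω)·v_L)` with the ground-truth weight ω fixed per
participant (defaults: 0.9 evident, 0.4 ambiguous — the encodings the two
training regimes are expected to produce). The generator does not model
within-trial feedback control, biomechanics, or the learning process that
*produces* ω; ω is an input, which is precisely what makes the fitting
pipeline testable against ground truth.

An optional lateral point-mass plant (`m·x'' = F_field + F_cmd − c·x'`,
m = 1.5 kg, c = 60 N·s/m, off by default) yields leftward path errors early
in exposure that shrink with adaptation, for exercising the
maximum-perpendicular-error metric; it is a crude impedance stand-in and
its absolute MPE values are not calibrated to human data.

## Preprocessing

Forces are filtered with a 5th-order zero-phase Butterworth low-pass at
40 Hz (`scipy.signal.sosfiltfilt`). Clamp-trial drift is removed by
subtracting the mean lateral force 200–150 ms before movement onset; onset
is the first sample exceeding 5% of the trial's peak speed (the criterion
is not specified by the original method; the threshold is configurable).
Clamp forces are clipped to ±400 ms around the reference hand's peak speed
(right hand in bimanual, left in unimanual trials; ties broken by the
earliest sample). Windows that exceed the recording are padded with the
boundary rest value and flagged; all downstream fits exclude padded
samples. "A window of 20 ms around peak velocity" for peak forces is read
as total width 20 ms (±10 ms); the ±20 ms reading is available via a
parameter.

## Metrics

MPE is the signed extremum of the perpendicular distance from the left-hand
path to the start→target line, positive leftward of the line for a forward
reach (the direction the field pushes; the sign convention is the
package's, as the original only states "signed"). Force compensation is
100× the **through-origin** regression slope of measured on perfect force
— drift is already removed, so an intercept would only absorb noise; a
with-intercept variant sits behind a flag. FC is computed on the lateral
force only and is undefined for unimanual trials (no field is ever applied
there; unimanual transfer is summarised by peak forces instead).

## Encoding models and comparison

The four parametric models (right / left / average / weighted) are fit by
least squares to concatenated clamp-trial profiles; the default granularity
is one condition-averaged profile per condition (matching how force
profiles are conventionally summarised), with per-trial concatenation as an
option. Single-gain models are linear and solved by exact projection. The
weighted model is fit with `scipy.optimize.least_squares`
(Levenberg–Marquardt, α₀ = 1, ω₀ = 0.5, tolerances 1e−10; both parameters
unrestricted). Although the model is bilinear and could be solved by a
two-regressor linear solve, the iterative fit preserves the stated
initialisation semantics; the linear solve serves as an independent test
oracle instead.

When the two hands' velocity profiles are (near-)identical the objective is
flat in ω; the fit measures the SSE excursion over ω ∈ [0,1] relative to
the total signal power and flags the fit (plus an
`OmegaIdentifiabilityWarning`) when it falls below 1e−6 — the
matched-speed group's situation in the absence of motor variability.

BIC assumes i.i.d. Gaussian residuals: `n·ln(SSE/n) + k·ln(n)` with k = 1
for single-gain models, 2 for weighted, 0 for the fixed-gain reference
(the formula is not stated by the original method; this is the standard
least-squares form). Results are reported as BIC improvement over the
reference (positive = better). The reference gain is the mean fitted α
pooled across the four models and all participants of both groups (the
published constant 0.822 for the original cohort is available as an
override); the reference encodes the environment's true right-hand mapping
and is evaluated, never re-fit. R² (1 − SSE/TSS about the mean) is computed
per participant and averaged, not pooled.

Generalization predictions apply the trained-condition fit's (α, ω) to each
condition's velocity profiles; predicted FC is the through-origin slope of
predicted on perfect force. Prediction MSE over FC excludes the trained
conditions by default (in-sample error would flatter every model), with
all-bimanual and unimanual subsets available. The encoding-weight
trajectory re-fits the weighted model on consecutive 96-trial windows
through exposure and generalization (per-trial concatenation; windows
without clamp trials yield flagged missing values). Note the first window
mixes the learner's rapid early gain change, which biases its ω estimate;
steady-state windows recover ω to ~0.01 under default noise.

## Degenerate inputs and numerical notes

Zero reference profiles (FC), zero-length start→target lines (MPE),
all-zero speed (onset), too-short series (filtering) and SSE = 0 (BIC)
raise descriptive errors; noise-free fits record BIC as NaN rather than
failing. Datasets round-trip losslessly through CSV (`%.17g` on write,
round-trip float parsing on read).

## Problem sizes and what the tests show

The test suite validates each stage against analytic oracles (closed-form
learner recursion, min-jerk root-finding, ramp-mean drift, grid-search and
two-regressor fits) and runs a two-group cohort of 8+8 simulated
participants (full 2208-trial experiments) to confirm that group-mean ω is
recovered within 0.05 and that the weighted model wins the BIC comparison
in both groups. Passing these tests shows the pipeline is self-consistent
and unbiased under the generator's assumptions (straight reaches, additive
Gaussian noise, constant ω, single-rate learning); it does not validate
those assumptions against human behaviour, where feedback corrections,
non-stationary encoding and richer noise structure apply.
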