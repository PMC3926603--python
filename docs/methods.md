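# Methods

`insolekit` implements the complete data-processing chain of a 64-cell
optoelectronic pressure-sensitive insole — from raw per-cell voltages to
temporal gait parameters — together with a synthetic gait generator that
stands in for the hardware. This note documents the models, the defaults
and why they were chosen, the numerical choices, and what the synthetic
tests do and do not establish about real recordings.

## Transduction and calibration model

Each sensing cell is an optoelectronic force-to-voltage transducer: a
silicone bulk occludes a light path as it compresses, so the de-offset
output voltage `v` goes negative under load. The voltage-to-force law is a
sum of two exponentials with a noise threshold:

    F(v) = 0                                   if v > v0
    F(v) = A1·e^(c1·v) + A2·e^(c2·v)           if v <= v0

with signs A1 > 0, c1 > 0, A2 < 0, c2 < 0 and v0 = −0.02 V. Forces are
signed throughout (compression negative); reporting layers may show |νGRF|.
Under that sign pattern dF/dv > 0 everywhere, so the loaded branch is
strictly increasing and invertible (`voltage_from_force`, bracketed root
finding to <1e−9; a table-initialised Newton variant handles arrays).

The shipped shared ("aggregate") model carries A1 = 21.386 N,
c1 = 4.834 /V, A2 = −22.30 N, c2 = −0.401 /V. Because the two-exponential
law does not pass through the origin, zeroing above v0 creates a jump of
|F(v0)| ≈ 3.06 N at the threshold. Two closed-form worst-case bounds
follow and are exposed by `worst_case_errors`: 64 cells loaded just below
the threshold force contribute up to 64 × 3.06 ≈ 195.8 N of unseen νGRF,
and a shared-model RMSE of ~5 % of the 50 N per-cell full scale
(500 kPa × 1 cm²) accumulates to 64 × 2.5 N = 160 N at full load.

`fit_calibration` fits the law by bounded nonlinear least squares
(`scipy.optimize.least_squares`) with multi-start initialisation: a coarse
grid over the rates (c1, c2) with amplitudes solved linearly at each
start, then refinement of the best candidates. The bounds A1 > 0 > A2,
c1 > 0 > c2 break the label-swap degeneracy of the two-exponential
family; the procedure is deterministic. The aggregate model is fitted on
the **pooled** samples of all cells rather than by averaging per-cell
coefficients: a pooled fit is what a single firmware curve actually
minimises, and coefficient averaging is not even well-defined under the
fit's degeneracy. On heterogeneous cells the pooled RMSE therefore
exceeds the mean per-cell RMSE, which is the expected signature.

## Signal conditioning

Raw streams are 64 channels at 1200 Hz. Processing per channel:

1. **De-offset** — subtract the mean over an operator-chosen unloaded
   window (default: first 0.5 s), mirroring the device's de-offset
   command. The baseline is recorded for reproducibility.
2. **Low-pass** — causal Butterworth, cutoff 40 Hz, order 2 by default
   (real-time capable, like an on-board implementation); order and
   zero-phase (forward–backward) filtering are configurable for offline
   work. A 2nd-order filter attenuates 55 Hz to ~0.47 of passband gain;
   users needing the <0.2 stop-band figure should raise the order (6
   suffices) — the tests verify both the order-2 response against the
   analytic frequency response and the order-6 stop-band figure.
3. **Decimate** — keep every 12th sample (1200 → 100 Hz), output length
   floor(n/12). The 40 Hz cutoff sits below the 50 Hz output Nyquist, so
   the chain is anti-aliasing by construction.

## νGRF, CoP and the −20 N rule

Per-cell forces come from the calibration model (one shared model by
default, matching the firmware; per-cell models are supported). Then

    νGRF  = Σ F_i
    CoP_x = Σ F_i·x_i / νGRF,   CoP_y = Σ F_i·y_i / νGRF

in insole coordinates (x medial-lateral; y antero-posterior, 0 = toe,
250 mm = heel). When νGRF > −20 N (total load magnitude under 20 N) the
foot is treated as unloaded: νGRF is reported as 0 and CoP as NaN — a
typed "undefined", never silently 0. The centroid is computed from the
raw sum before the rule is applied; equality at exactly −20 N counts as
loaded. Pressure maps interpolate |F_i|/area (10 kPa per N at 1 cm²)
linearly over the Delaunay mesh of the cell nodes, with no smoothing and
no outlier removal.

The default 64-cell layout is a deterministic foot-shaped arrangement on
a 1 cm grid (denser under heel and forefoot, sparse along the arch,
covering y = 15–245 mm). Actual cell coordinates are a hardware property,
so the layout is a convention and always overridable from a JSON file.

## Gait segmentation and temporal parameters

Each 100 Hz sample is classified by thresholds (simplified Perry–Davids
grouping): swing (SW) when CoP is undefined; Stance 1 (ST1) when
νGRF ≤ −20 N and CoP_y > 125 mm; Stance 2 (ST2) when νGRF ≤ −20 N and
CoP_y ≤ 125 mm. Classification is total and causal. Heel strike is the
SW→stance transition and toe off the stance→SW transition, timed at the
first sample of the new phase (≤10 ms quantisation at 100 Hz). A direct
SW→ST2 transition (forefoot-first contact) still emits a heel-strike
event but is flagged atypical. No debouncing is applied by default — the
−20 N threshold is what suppresses noise-induced false positives — but an
optional minimum-phase-duration filter (30 ms when enabled) exists for
noisy inputs.

A step is the interval between consecutive heel strikes of one foot;
stance runs heel strike → toe off, swing toe off → next heel strike,
cadence = 1/(stance + swing). The first and last two steps of a trial are
trimmed (configurable) to keep steady-state gait. Double support is the
interval where one foot is in ST1 while the other is in ST2; DS_L
(left ST1, right ST2) precedes a left single support, symmetrically DS_R.
Trial summaries report mean ± sd (sample sd, n−1 denominator, as in all
sd computations in the package) of stance, swing and double support in
seconds and percent of stride, plus cadence per side.

## Comparison metrics

Stance-phase νGRF segments are linearly resampled to 100 points (stance
only, not full stride; configurable) and averaged pointwise. Against a
time-aligned reference trace the package reports, per paired step,
NRMSE = RMSE/(max−min of the *insole* profile), the sample Pearson
correlation, and the mean absolute error of stance durations, where the
reference stance is measured with the same −20 N rule and the same
"stance ends at the first unloaded sample" convention. Profiles are
compared on the signed νGRF; being range-normalised, NRMSE as implemented
is dimensionless and O(1) for similar waveforms.

## Synthetic gait generator

The generator produces raw voltage streams by pushing a known gait
pattern backwards through the transduction chain, so every stage of the
pipeline is testable against ground truth.

- **νGRF profile**: a valley-level plateau with raised-cosine edge ramps
  (zero at both stance boundaries) plus two raised-cosine lobes. Defaults
  put the weight-acceptance peak at 20 % and the push-off peak at 75 % of
  stance — inside the physiological 15–25 % and 70–80 % windows — with
  magnitudes scaled to body weight (1.10 / 1.05 BW peaks, 0.75 BW
  valley, 75 kg subject). Raised cosines are smooth, compactly supported
  and give analytically controllable peak times.
- **Timing**: stance 0.80 s, swing 0.45 s (cadence 0.8 Hz — a
  self-selected slow walk of a healthy young adult), double support 14 %
  of stride. Feet alternate with a right-foot delay of
  stance − DS duration; infeasible combinations (double support not
  shorter than stance) are rejected.
- **CoP**: advances linearly from y = 240 mm (heel) to 20 mm (toe),
  crossing the 125 mm ST1/ST2 boundary exactly once; the linear
  progression places the push-off peak under the forefoot rows and
  reaches the toe region only as the load vanishes. A small
  medial-lateral sway (5 mm) fades out near contact and lift-off.
- **Pressure distribution**: the total force is spread over a compact,
  near-uniform contact patch (super-Gaussian footprint, 45 mm radius)
  and the weights are exponentially tilted — a 2-D Newton iteration whose
  Jacobian is the weighted coordinate covariance — until the
  force-weighted centroid matches the requested CoP to <1e−6 mm while
  the forces sum exactly to the νGRF. The patch size keeps per-cell
  loads near the 0–500 kPa working range at body-weight loads, as a real
  foot contact does; a much tighter footprint would drive single 50 N
  cells far beyond full scale and make the shared-model decode meaningless.
- **Per-cell variability**: cells are drawn with coefficient dispersions
  matching the reported fleet statistics, truncated at ±2 sd with the
  sign pattern enforced. Because two-exponential fits are ill-conditioned,
  wide coefficient scatter is compatible with — and in real cells cast
  from a single mold, accompanied by — very similar curves; draws are
  therefore rejected unless the cell's curve stays within 4 N RMS of the
  aggregate curve over the 0–50 N working range (the same order as the
  pooled aggregate fit RMSE). Voltages are generated with the per-cell
  models while the pipeline decodes with the shared model, reproducing
  the device's main error mechanism.
- **Noise and offsets**: static per-channel offsets (1.3 ± 0.05 V) plus
  Gaussian noise, default sd 0.005 V so that unloaded channels cross the
  −0.02 V threshold only in the 4σ tail. Forces below a cell's threshold
  force are emitted as 0 V (the hardware dead zone): the thresholded law
  cannot represent them, and emitting v0 instead would read as the full
  ~3 N jump. All randomness flows from a single seed; trials are
  reproducible bit-for-bit.

**What the simulator does not emulate** — shear loads, ADC quantisation,
Bluetooth transport, soft-tissue dynamics, stride-to-stride timing and
waveform variability, or drift. Passing recovery tests therefore shows
that the *algorithms* are correct and self-consistent under physiological
signal shapes and realistic sensor noise; it does not certify accuracy on
real recordings, where contact mechanics and cell behaviour are richer.

## Numerical choices and degenerate inputs

- Fits: xtol/ftol/gtol 1e−15; noise-free forward-model data recovers
  coefficients to better than 1e−4 relative. Constant-voltage input is a
  fit error; non-convergence raises, never silently falls back.
- Inversion: forces outside the representable range (including magnitudes
  below the threshold force) raise a domain error.
- Segmentation boundaries: CoP_y exactly 125 mm is ST2; νGRF exactly
  −20 N is loaded.
- Streams starting mid-stance contribute no step (first event is a toe
  off); fewer than 2·trim+1 steps yield an empty, warned result.
- Degenerate scenario with peak = valley produces a plateau profile, not
  an error.
- Test problem sizes: the end-to-end recovery checks use 24 simulated
  steps per foot at 1200 Hz (~32 s of gait), enough for ≥20 steady-state
  steps after trimming; unit tests use 5–7 steps.

## Known limitations

- The recovered event times carry the causal filter delay plus one-sample
  quantisation; recovery tolerances (±40 ms on durations, ±0.02 Hz on
  cadence) account for both.
- The aggregate-decode error on simulated trials (~5–10 % νGRF
  overestimation with default variability) depends on the rejection
  threshold in the cell sampler; it is a plausible, not a calibrated,
  emulation of device error.
- `nrmse` is dimensionless by construction; comparisons with conventions
  that normalise differently (or not at all) require rescaling by the
  insole profile range.
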