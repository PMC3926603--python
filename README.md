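# insolekit

Processing and gait analysis for 64-cell optoelectronic pressure-sensitive
insoles: calibration modelling, signal conditioning, vertical ground
reaction force (νGRF) and centre-of-pressure (CoP) computation,
threshold-based gait segmentation, temporal gait parameters, validation
metrics, and a synthetic gait simulator with known ground truth.

It is written for biomechanics and wearable-sensor researchers who work
with plantar-pressure insoles (or want to prototype algorithms for one
without hardware): the whole device chain is reproduced in software and
every stage is testable against simulated walking.

## The model

Each of the 64 sensing cells (1 cm², working range 0–500 kPa) acts as a
force-to-voltage transducer. After de-offsetting, voltage-to-force
conversion uses a thresholded sum of two exponentials

    F(v) = 0                                   if v > v0 = −0.02 V
    F(v) = A1·e^(c1·v) + A2·e^(c2·v)           if v ≤ v0

with the shared (aggregate) coefficients A1 = 21.386 N, c1 = 4.834 /V,
A2 = −22.30 N, c2 = −0.401 /V (compression negative). Per frame,

    νGRF = Σᵢ Fᵢ,   CoP_x = Σᵢ Fᵢxᵢ / νGRF,   CoP_y = Σᵢ Fᵢyᵢ / νGRF

with νGRF set to 0 and CoP to NaN whenever νGRF > −20 N. Each 100 Hz
sample is then classified into gait phases

    CoP undefined                →  SW   (swing)
    νGRF ≤ −20 N, CoP_y > 125 mm →  ST1  (initial contact + mid-stance)
    νGRF ≤ −20 N, CoP_y ≤ 125 mm →  ST2  (terminal stance + pre-swing)

from which heel-strike/toe-off events, stance/swing/double-support
durations and cadence follow. See `docs/methods.md` for the full account.

## Worked example

```python
from insolekit import GaitScenario, generate_trial, process_trial

left, right, truth = generate_trial(GaitScenario(n_steps=10, seed=7))
result = process_trial(left, right)
s = result.summary["left"]
print(f"stance {s['dt_stance_s']['mean']:.3f} s, "
      f"swing {s['dt_swing_s']['mean']:.3f} s, "
      f"cadence {s['cadence_hz']['mean']:.3f} Hz, "
      f"double support {s['dt_ds_s']['mean']:.3f} s")
print(f"truth: stance {truth.dt_stance_s} s, swing {truth.dt_swing_s} s, "
      f"cadence {truth.cadence_hz:.3f} Hz")
```

prints

```
stance 0.800 s, swing 0.450 s, cadence 0.800 Hz, double support 0.170 s
truth: stance 0.8 s, swing 0.45 s, cadence 0.800 Hz
```

i.e. the pipeline recovers the simulated temporal parameters to within
the 10 ms sample period (the double-support truth is 0.175 s). The
`examples/` directory has one short script per capability — calibration
modelling, simulation + segmentation, νGRF profiles and comparison
statistics, pressure maps — each printing the numbers it computes and
what they mean.

A thin CLI wraps the same chain:

```
insolekit simulate scenario.json --out-dir trial/
insolekit process trial/raw_left.csv trial/raw_right.csv --out-dir out/
insolekit calibrate characterization.csv calibration.json
insolekit compare trial/raw_left.csv trial/raw_right.csv reference.csv
insolekit report out/steps_left.csv out/steps_right.csv
```

CSV dialects are fixed (comma, `.` decimal, `NaN` sentinel) so outputs
round-trip bit-stably; streams are `time_s,ch00..ch63`, biomech traces
`time_s,vgrf_N,cop_x_mm,cop_y_mm`.

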