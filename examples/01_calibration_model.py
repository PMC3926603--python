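"""Evaluate, invert and refit the voltage-to-force calibration model.

Prints the threshold-force jump, the worst-case vGRF error bounds implied
by the thresholded transduction law, and a parameter-recovery check of the
two-exponential fitter on forward-generated data.
"""

import numpy as np

from insolekit import (
    AGGREGATE_MODEL,
    fit_calibration,
    force_from_voltage,
    threshold_force,
    voltage_from_force,
    worst_case_errors,
)

# The loaded branch of the model: F = A1 e^{c1 v} + A2 e^{c2 v} for v <= -0.02 V
for v in (-0.02, -0.5, -1.0, -2.0):
    print(f"F({v:+.2f} V) = {force_from_voltage(v):8.2f} N")
# Below the -0.02 V noise threshold a cell reads exactly 0 N, so any load up
# to the ~3.06 N threshold force is invisible:
print(f"\nthreshold force |F(v0)| = {threshold_force():.2f} N")
wc = worst_case_errors()
print(f"worst-case vGRF threshold error (64 cells):   {wc['vgrf_threshold_error_N']:6.1f} N")
print(f"worst-case vGRF calibration error (5% f.s.r.): {wc['vgrf_calibration_error_N']:6.1f} N")

# The loaded branch is strictly increasing, hence invertible:
v = voltage_from_force(-25.0)
print(f"\nvoltage for a 25 N compressive load: {v:.4f} V")

# Refitting noise-free forward-model samples recovers the coefficients:
vgrid = np.linspace(-1.3, -0.05, 40)
report = fit_calibration(list(zip(vgrid, force_from_voltage(vgrid))))
m = report.model
print(
    f"\nrefit: A1={m.A1:.3f} c1={m.c1:.3f} A2={m.A2:.3f} c2={m.c2:.3f} "
    f"(rmse {report.rmse_N:.2e} N, R^2 {report.r2:.6f})"
)
print(f"true:  A1={AGGREGATE_MODEL.A1} c1={AGGREGATE_MODEL.c1} "
      f"A2={AGGREGATE_MODEL.A2} c2={AGGREGATE_MODEL.c2}")
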