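"""Simulate a walking trial and run the full analysis pipeline on it.

Generates raw 64-channel voltage streams for both feet (1200 Hz), runs
de-offset -> 40 Hz low-pass -> 100 Hz decimation -> voltage-to-force ->
vGRF/CoP -> SW/ST1/ST2 segmentation -> step extraction, and compares the
recovered temporal gait parameters with the simulator's ground truth.
"""

from insolekit import GaitScenario, generate_trial, process_trial

scenario = GaitScenario(n_steps=10, seed=7)
left, right, truth = generate_trial(scenario)
print(f"simulated {scenario.n_steps} steps/foot at {scenario.fs_hz:g} Hz "
      f"({left.n_samples} samples, {left.n_samples/scenario.fs_hz:.1f} s)")

result = process_trial(left, right)

print(f"\nsteady-state steps kept (first/last 2 trimmed): "
      f"{len(result.left.steps)} left, {len(result.right.steps)} right")
print(f"{'':>8}{'stance [s]':>12}{'swing [s]':>12}{'cadence [Hz]':>14}")
for side in ("left", "right"):
    s = result.summary[side]
    print(
        f"{side:>8}"
        f"{s['dt_stance_s']['mean']:>9.3f} ±{s['dt_stance_s']['sd']:.3f}"
        f"{s['dt_swing_s']['mean']:>9.3f} ±{s['dt_swing_s']['sd']:.3f}"
        f"{s['cadence_hz']['mean']:>10.3f} ±{s['cadence_hz']['sd']:.3f}"
    )
    print(f"{'':>8}  double support {s['dt_ds_s']['mean']:.3f} ± {s['dt_ds_s']['sd']:.3f} s")
print(
    f"\nground truth: stance {truth.dt_stance_s} s, swing {truth.dt_swing_s} s, "
    f"cadence {truth.cadence_hz:.3f} Hz, double support {truth.dt_double_support_s:.3f} s"
)
print("recovered values agree to within the 10 ms sample period plus the "
      "few-sample detection delay of the -20 N threshold.")
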