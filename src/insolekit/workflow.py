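"""End-to-end processing: raw voltages to step reports, plus comparison.

Mirrors the device chain: de-offset -> 40 Hz low-pass -> down-sample to
100 Hz -> voltage-to-force -> vGRF/CoP with the -20 N rule -> phase
segmentation -> event detection -> step extraction (steady-state trim) ->
trial summary.  Every stage appends a structured record to a run log, so a
processed trial documents its own parameters and counts (samples zeroed by
the -20 N rule, steps discarded by the trim, atypical contacts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import biomechanics, gait, metrics
from .io import PipelineConfig
from .sensor_model import AGGREGATE_MODEL, CalibrationModel, SensorLayout, default_layout
from .signal_pipeline import RawVoltageStream, deoffset, lowpass_decimate

__all__ = ["RunLog", "FootResult", "TrialResult", "process_trial", "compare_with_reference"]

logger = logging.getLogger("insolekit")


@dataclass
class RunLog:
    """Structured per-stage records of one pipeline run."""

    records: list[dict] = field(default_factory=list)

    def add(self, stage: str, **info) -> None:
        rec = {"stage": stage, **info}
        self.records.append(rec)
        logger.debug("%s: %s", stage, info)

    @property
    def warnings(self) -> list[dict]:
        return [r for r in self.records if r.get("warning")]


@dataclass
class FootResult:
    """All per-foot artifacts of one processed trial."""

    side: str
    biomech: pd.DataFrame
    phases: pd.DataFrame
    events: list[gait.GaitEvent]
    steps: list[gait.StepRecord]


@dataclass
class TrialResult:
    left: FootResult
    right: FootResult
    ds_records: list[gait.DoubleSupportRecord]
    summary: dict
    log: RunLog


def _process_foot(
    raw: RawVoltageStream,
    side: str,
    layout: SensorLayout,
    model: CalibrationModel | Sequence[CalibrationModel],
    config: PipelineConfig,
    log: RunLog,
) -> FootResult:
    stream, baseline = deoffset(raw, (raw.t0, raw.t0 + config.baseline_window_s))
    log.add("deoffset", side=side, window_s=config.baseline_window_s,
            baseline_mean_V=float(np.mean(baseline)))

    proc = lowpass_decimate(
        stream,
        cutoff_hz=config.cutoff_hz,
        out_fs_hz=config.fs_out_hz,
        order=config.filter_order,
        zero_phase=config.zero_phase,
        baseline=baseline,
    )
    log.add("lowpass_decimate", side=side, cutoff_hz=config.cutoff_hz,
            order=config.filter_order, n_in=raw.n_samples, n_out=proc.n_samples)

    if isinstance(model, CalibrationModel):
        forces = biomechanics.force_from_voltage(proc.data, model)
    else:
        forces = np.column_stack(
            [biomechanics.force_from_voltage(proc.data[:, i], m) for i, m in enumerate(model)]
        )
    biomech = biomechanics.process_frames(
        forces, layout, proc.times, vgrf_threshold=config.vgrf_threshold_N
    )
    n_zeroed = int(((forces.sum(axis=1) < 0) & (biomech["vgrf_N"] == 0)).sum())
    log.add("vgrf_cop", side=side, n_samples=len(biomech),
            n_zeroed_by_threshold=n_zeroed, vgrf_threshold_N=config.vgrf_threshold_N)

    phases = gait.segment_stream(
        biomech,
        copy_threshold_mm=config.copy_threshold_mm,
        vgrf_threshold=config.vgrf_threshold_N,
        min_phase_s=config.min_phase_s,
        fs_hz=config.fs_out_hz,
    )
    events = gait.detect_events(phases)
    n_atypical = sum(1 for e in events if e.atypical)
    if n_atypical:
        log.add("detect_events", side=side, n_events=len(events),
                n_atypical_contacts=n_atypical, warning=True)
    else:
        log.add("detect_events", side=side, n_events=len(events))

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        steps = gait.extract_steps(events, side=side, trim=config.trim_steps)
    n_total = max(len([e for e in events if e.kind == "heel_strike"]) - 1, 0)
    log.add("extract_steps", side=side, n_steps_total=n_total,
            n_steps_kept=len(steps), n_discarded=n_total - len(steps),
            trim=config.trim_steps)
    return FootResult(side=side, biomech=biomech, phases=phases, events=events, steps=steps)


def process_trial(
    raw_left: RawVoltageStream,
    raw_right: RawVoltageStream,
    config: PipelineConfig | None = None,
    layout: SensorLayout | None = None,
    model: CalibrationModel | Sequence[CalibrationModel] = AGGREGATE_MODEL,
) -> TrialResult:
    """Run the full chain on a left/right pair of raw voltage streams."""
    config = config or PipelineConfig()
    layout = layout or default_layout()
    log = RunLog()
    left = _process_foot(raw_left, "left", layout, model, config, log)
    right = _process_foot(raw_right, "right", layout, model, config, log)
    ds = gait.double_support(left.phases, right.phases, fs_hz=config.fs_out_hz)
    log.add("double_support", n_records=len(ds))
    summary = gait.trial_summary(left.steps, right.steps, ds)
    return TrialResult(left=left, right=right, ds_records=ds, summary=summary, log=log)


def stance_profiles(
    foot: FootResult,
    n: int = 100,
) -> tuple[list[np.ndarray], list[float]]:
    """100-point stance vGRF profiles and stance durations of kept steps."""
    t = foot.biomech["time_s"].to_numpy()
    v = foot.biomech["vgrf_N"].to_numpy()
    profiles, durations = [], []
    for s in foot.steps:
        mask = (t >= s.t_heel_strike) & (t < s.t_toe_off)
        if mask.sum() >= 2:
            profiles.append(metrics.resample_profile(v[mask], n))
            durations.append(s.dt_stance)
    return profiles, durations


def compare_with_reference(
    foot: FootResult,
    reference: pd.DataFrame,
    vgrf_threshold_N: float = -20.0,
    resample_n: int = 100,
) -> metrics.ComparisonReport:
    """Compare per-step insole vGRF profiles with a time-aligned reference.

    ``reference`` is a DataFrame with columns time_s, vgrf_N on the same
    time base as the trial.  Reference stance durations are measured with
    the same -20 N loading rule.  Steps without reference coverage are
    dropped; raises if none overlap.
    """
    rt = reference["time_s"].to_numpy(dtype=float)
    rv = reference["vgrf_N"].to_numpy(dtype=float)
    t = foot.biomech["time_s"].to_numpy()
    v = foot.biomech["vgrf_N"].to_numpy()

    ins_profiles, ref_profiles = [], []
    ins_stance, ref_stance = [], []
    for s in foot.steps:
        mask = (t >= s.t_heel_strike) & (t < s.t_toe_off)
        rmask = (rt >= s.t_heel_strike - 0.2) & (rt < s.t_next_heel_strike)
        if mask.sum() < 2 or rmask.sum() < 2:
            continue
        seg_t, seg_v = rt[rmask], rv[rmask]
        loaded = seg_v <= vgrf_threshold_N
        if loaded.sum() < 2:
            continue
        i0, i1 = np.flatnonzero(loaded)[[0, -1]]
        ins_profiles.append(metrics.resample_profile(v[mask], resample_n))
        ref_profiles.append(metrics.resample_profile(seg_v[i0 : i1 + 1], resample_n))
        ins_stance.append(s.dt_stance)
        # stance ends at the first unloaded sample, matching the event convention
        step_ref = float(np.median(np.diff(seg_t))) if len(seg_t) > 1 else 0.0
        ref_stance.append(float(seg_t[i1] - seg_t[i0]) + step_ref)
    if not ins_profiles:
        raise ValueError("no steps overlap the reference trace")
    return metrics.compare_step_profiles(ins_profiles, ref_profiles, ins_stance, ref_stance)
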