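"""Threshold-based gait segmentation and temporal gait parameters.

Each 100 Hz biomechanical sample (vGRF, CoP_y) is classified into one of
three phases, a simplified Perry–Davids grouping:

    CoP undefined (NaN)              -> SW   (swing)
    vGRF <= -20 N and CoP_y > 125 mm -> ST1  (initial contact + mid-stance)
    vGRF <= -20 N and CoP_y <= 125 mm-> ST2  (terminal stance + pre-swing)

Heel strike is the SW->stance transition, toe off the stance->SW
transition; both are timed at the first sample of the new phase, so the
detection is causal and quantised to the 10 ms sample period.  A step is
the interval between two consecutive heel strikes of the same foot; stance
duration runs heel strike -> toe off and swing toe off -> next heel
strike, with cadence 1/(stance + swing).  Double support is the interval
in which one foot is in ST1 while the other is in ST2.  Following the
steady-state (mid-gait) convention, the first and last two steps of a
trial are discarded by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .biomechanics import VGRF_THRESHOLD_N, BiomechSample

__all__ = [
    "SW",
    "ST1",
    "ST2",
    "COPY_THRESHOLD_MM",
    "GaitEvent",
    "StepRecord",
    "DoubleSupportRecord",
    "classify_sample",
    "segment_stream",
    "detect_events",
    "extract_steps",
    "double_support",
    "trial_summary",
]

SW = "SW"
ST1 = "ST1"
ST2 = "ST2"

#: CoP_y threshold separating ST1 (rear/mid foot) from ST2 (forefoot), mm.
COPY_THRESHOLD_MM = 125.0


def classify_sample(
    sample: BiomechSample,
    copy_threshold_mm: float = COPY_THRESHOLD_MM,
    vgrf_threshold: float = VGRF_THRESHOLD_N,
) -> str:
    """Classify one sample into SW / ST1 / ST2 (total: always one label)."""
    if not sample.cop_defined:
        return SW
    if sample.vgrf <= vgrf_threshold and sample.cop_y > copy_threshold_mm:
        return ST1
    if sample.vgrf <= vgrf_threshold:
        return ST2
    return SW


def segment_stream(
    biomech: pd.DataFrame,
    copy_threshold_mm: float = COPY_THRESHOLD_MM,
    vgrf_threshold: float = VGRF_THRESHOLD_N,
    min_phase_s: float = 0.0,
    fs_hz: float = 100.0,
) -> pd.DataFrame:
    """Per-sample phase labels for a vGRF/CoP DataFrame (causal, vectorised).

    ``biomech`` needs columns time_s, vgrf_N, cop_y_mm.  ``min_phase_s``
    optionally suppresses phase runs shorter than that duration (debounce,
    off by default: the -20 N threshold already rejects sensor noise).
    Returns a DataFrame with columns time_s, phase.
    """
    vgrf = biomech["vgrf_N"].to_numpy(dtype=float)
    cop_y = biomech["cop_y_mm"].to_numpy(dtype=float)
    defined = ~np.isnan(cop_y)
    labels = np.full(len(vgrf), SW, dtype=object)
    st = defined & (vgrf <= vgrf_threshold)
    labels[st & (cop_y > copy_threshold_mm)] = ST1
    labels[st & (cop_y <= copy_threshold_mm)] = ST2
    if min_phase_s > 0:
        labels = _debounce(labels, int(round(min_phase_s * fs_hz)))
    return pd.DataFrame({"time_s": biomech["time_s"].to_numpy(), "phase": labels})


def _debounce(labels: np.ndarray, min_len: int) -> np.ndarray:
    """Merge phase runs shorter than min_len into the preceding phase."""
    out = labels.copy()
    n = len(out)
    i = 0
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if 0 < i and (j - i) < min_len:
            out[i:j] = out[i - 1]
        i = j
    return out


@dataclass(frozen=True)
class GaitEvent:
    kind: str  # "heel_strike" | "toe_off"
    t: float
    index: int
    atypical: bool = False  # direct SW->ST2 contact (forefoot-first)


def detect_events(phases: pd.DataFrame) -> list[GaitEvent]:
    """Heel-strike / toe-off events from a phase stream.

    Heel strike at every SW->(ST1|ST2) transition, toe off at every
    (ST1|ST2)->SW transition; the event time is the time of the first
    sample of the new phase.  A direct SW->ST2 transition (forefoot-first
    contact) still counts as contact onset but is flagged atypical.
    """
    labels = phases["phase"].to_numpy()
    times = phases["time_s"].to_numpy(dtype=float)
    events: list[GaitEvent] = []
    for i in range(1, len(labels)):
        prev, cur = labels[i - 1], labels[i]
        if prev == SW and cur in (ST1, ST2):
            events.append(GaitEvent("heel_strike", float(times[i]), i, atypical=cur == ST2))
        elif prev in (ST1, ST2) and cur == SW:
            events.append(GaitEvent("toe_off", float(times[i]), i))
    return events


@dataclass(frozen=True)
class StepRecord:
    """One step (heel strike to next heel strike) of one foot."""

    side: str
    t_heel_strike: float
    t_toe_off: float
    t_next_heel_strike: float
    atypical: bool = False

    @property
    def dt_stance(self) -> float:
        return self.t_toe_off - self.t_heel_strike

    @property
    def dt_swing(self) -> float:
        return self.t_next_heel_strike - self.t_toe_off

    @property
    def duration(self) -> float:
        return self.t_next_heel_strike - self.t_heel_strike

    @property
    def stance_pct(self) -> float:
        return 100.0 * self.dt_stance / self.duration

    @property
    def swing_pct(self) -> float:
        return 100.0 * self.dt_swing / self.duration

    @property
    def cadence_hz(self) -> float:
        return 1.0 / self.duration


def extract_steps(
    events: Sequence[GaitEvent],
    side: str = "left",
    trim: int = 2,
) -> list[StepRecord]:
    """Build steps between consecutive heel strikes; drop warm-up/slow-down.

    A leading partial stance (stream starting mid-stance, first event a toe
    off) is ignored.  The first and last ``trim`` steps are discarded to
    keep only steady-state steps; if fewer than 2*trim+1 steps exist the
    result is empty (with a warning).
    """
    steps: list[StepRecord] = []
    hs: GaitEvent | None = None
    to: GaitEvent | None = None
    for ev in events:
        if ev.kind == "heel_strike":
            if hs is not None and to is not None:
                steps.append(
                    StepRecord(
                        side=side,
                        t_heel_strike=hs.t,
                        t_toe_off=to.t,
                        t_next_heel_strike=ev.t,
                        atypical=hs.atypical,
                    )
                )
            hs, to = ev, None
        elif ev.kind == "toe_off" and hs is not None:
            to = ev
    if trim > 0:
        if len(steps) < 2 * trim + 1:
            if steps:
                warnings.warn(
                    f"only {len(steps)} steps detected; trimming {trim} from each end leaves none",
                    stacklevel=2,
                )
            return []
        steps = steps[trim:-trim]
    return steps


@dataclass(frozen=True)
class DoubleSupportRecord:
    """A both-feet-on-ground interval.

    DS_L (left ST1 while right ST2) precedes a left single support; DS_R
    (left ST2 while right ST1) precedes a right single support.
    """

    kind: str  # "DS_L" | "DS_R"
    t_start: float
    dt: float


def double_support(
    left: pd.DataFrame,
    right: pd.DataFrame,
    fs_hz: float = 100.0,
) -> list[DoubleSupportRecord]:
    """Double-support intervals from two time-aligned phase streams."""
    if len(left) != len(right) or not np.allclose(
        left["time_s"].to_numpy(), right["time_s"].to_numpy()
    ):
        raise ValueError("left/right phase streams must be time-aligned and equal length")
    tl = left["time_s"].to_numpy(dtype=float)
    ll = left["phase"].to_numpy()
    rr = right["phase"].to_numpy()
    records: list[DoubleSupportRecord] = []
    for kind, mask in (
        ("DS_L", (ll == ST1) & (rr == ST2)),
        ("DS_R", (ll == ST2) & (rr == ST1)),
    ):
        for start, stop in _runs(mask):
            records.append(
                DoubleSupportRecord(kind=kind, t_start=float(tl[start]), dt=(stop - start) / fs_hz)
            )
    records.sort(key=lambda r: r.t_start)
    return records


def _runs(mask: np.ndarray) -> Iterable[tuple[int, int]]:
    """(start, stop) index pairs of contiguous True runs."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return zip(starts.tolist(), stops.tolist())


def _mean_sd(values: Sequence[float]) -> dict:
    a = np.asarray(values, dtype=float)
    if len(a) == 0:
        return {"mean": float("nan"), "sd": float("nan"), "n": 0}
    sd = float(a.std(ddof=1)) if len(a) > 1 else 0.0
    return {"mean": float(a.mean()), "sd": sd, "n": int(len(a))}


def trial_summary(
    left_steps: Sequence[StepRecord],
    right_steps: Sequence[StepRecord],
    ds_records: Sequence[DoubleSupportRecord] = (),
) -> dict:
    """Per-trial mean +/- sd of stance, swing, double support and cadence.

    Durations are reported in seconds and in percent of the stride; double
    support percentages are relative to the mean stride of the side whose
    single support the interval precedes.
    """
    out: dict = {}
    for side, steps in (("left", left_steps), ("right", right_steps)):
        if not steps:
            out[side] = {}
            continue
        stride = _mean_sd([s.duration for s in steps])
        out[side] = {
            "dt_stance_s": _mean_sd([s.dt_stance for s in steps]),
            "dt_swing_s": _mean_sd([s.dt_swing for s in steps]),
            "stance_pct": _mean_sd([s.stance_pct for s in steps]),
            "swing_pct": _mean_sd([s.swing_pct for s in steps]),
            "cadence_hz": _mean_sd([s.cadence_hz for s in steps]),
            "stride_s": stride,
            "n_steps": len(steps),
        }
    for kind, side in (("DS_L", "left"), ("DS_R", "right")):
        ds = [r.dt for r in ds_records if r.kind == kind]
        stats = _mean_sd(ds)
        out.setdefault(side, {})[f"dt_ds_s"] = stats
        stride_mean = out[side].get("stride_s", {}).get("mean")
        if ds and stride_mean:
            out[side]["ds_pct"] = _mean_sd([100.0 * d / stride_mean for d in ds])
    return out
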