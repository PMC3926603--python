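"""File formats and pipeline configuration.

Fixed dialects so round trips are bit-stable:

- stream CSV: header ``time_s,ch00,...,ch63``, one row per sample, '.'
  decimal separator, undefined values serialized as ``NaN``;
- biomech CSV: ``time_s,vgrf_N,cop_x_mm,cop_y_mm`` (NaN for undefined CoP);
- phase CSV: ``time_s,phase`` with phase in {SW, ST1, ST2};
- step CSV: one row per step record;
- layout / calibration / scenario / summary files: JSON (scenario also
  readable from YAML).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .gait import StepRecord
from .sensor_model import CalibrationModel, FitReport, SensorLayout
from .signal_pipeline import RawVoltageStream
from .synthetic import GaitScenario

__all__ = [
    "PipelineConfig",
    "read_stream_csv",
    "write_stream_csv",
    "read_layout_json",
    "write_layout_json",
    "read_calibration_json",
    "write_calibration_json",
    "read_biomech_csv",
    "write_biomech_csv",
    "read_phase_csv",
    "write_phase_csv",
    "write_steps_csv",
    "read_steps_csv",
    "read_scenario",
    "write_scenario",
]

_CHANNEL_COLS = [f"ch{i:02d}" for i in range(64)]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline settings, with the device's stock defaults.

    Thresholds: v0 = -0.02 V (per-cell noise threshold), -20 N on the total
    vGRF, 125 mm on CoP_y.  Rates: 1200 Hz in, 100 Hz out, 40 Hz cutoff.
    Steps: trim 2 from each end, 100-point stance resampling.
    """

    v0_V: float = -0.02
    vgrf_threshold_N: float = -20.0
    copy_threshold_mm: float = 125.0
    cutoff_hz: float = 40.0
    filter_order: int = 2
    zero_phase: bool = False
    fs_in_hz: float = 1200.0
    fs_out_hz: float = 100.0
    baseline_window_s: float = 0.5
    trim_steps: int = 2
    resample_n: int = 100
    min_phase_s: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def write_stream_csv(stream: RawVoltageStream, path: str | Path) -> None:
    df = pd.DataFrame(stream.data, columns=_CHANNEL_COLS)
    df.insert(0, "time_s", stream.times)
    df.to_csv(path, index=False, na_rep="NaN", float_format="%.9g")


def read_stream_csv(path: str | Path, fs_hz: float | None = None) -> RawVoltageStream:
    df = pd.read_csv(path)
    missing = [c for c in ["time_s", *_CHANNEL_COLS] if c not in df.columns]
    if missing:
        raise ValueError(f"stream CSV {path} lacks columns: {missing[:3]}...")
    t = df["time_s"].to_numpy(dtype=float)
    if fs_hz is None:
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from fewer than 2 samples")
        fs_hz = 1.0 / float(np.median(np.diff(t)))
        fs_hz = float(round(fs_hz))
    return RawVoltageStream(data=df[_CHANNEL_COLS].to_numpy(dtype=float), fs_hz=fs_hz, t0=float(t[0]))


def write_layout_json(layout: SensorLayout, path: str | Path) -> None:
    Path(path).write_text(json.dumps(layout.to_records(), indent=2) + "\n")


def read_layout_json(path: str | Path) -> SensorLayout:
    return SensorLayout.from_records(json.loads(Path(path).read_text()))


def write_calibration_json(
    path: str | Path,
    aggregate: FitReport | CalibrationModel,
    per_cell: Sequence[FitReport] | None = None,
) -> None:
    if isinstance(aggregate, CalibrationModel):
        data: dict = {**aggregate.to_dict()}
    else:
        data = {**aggregate.model.to_dict(), "fit_report": aggregate.to_dict()}
    if per_cell is not None:
        data["per_cell"] = [r.to_dict() for r in per_cell]
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def read_calibration_json(
    path: str | Path,
) -> tuple[CalibrationModel, list[CalibrationModel] | None]:
    data = json.loads(Path(path).read_text())
    model = CalibrationModel.from_dict(data)
    per_cell = None
    if "per_cell" in data:
        per_cell = [CalibrationModel.from_dict(r["model"]) for r in data["per_cell"]]
    return model, per_cell


def write_biomech_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep="NaN", float_format="%.9g")


def read_biomech_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"time_s", "vgrf_N", "cop_x_mm", "cop_y_mm"}
    if not need.issubset(df.columns):
        raise ValueError(f"biomech CSV {path} must have columns {sorted(need)}")
    return df


def write_phase_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_phase_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"time_s", "phase"}.issubset(df.columns):
        raise ValueError(f"phase CSV {path} must have columns time_s, phase")
    return df


def write_steps_csv(steps: Sequence[StepRecord], path: str | Path) -> None:
    rows = [
        {
            "side": s.side,
            "t_heel_strike_s": s.t_heel_strike,
            "t_toe_off_s": s.t_toe_off,
            "t_next_heel_strike_s": s.t_next_heel_strike,
            "dt_stance_s": s.dt_stance,
            "dt_swing_s": s.dt_swing,
            "stance_pct": s.stance_pct,
            "swing_pct": s.swing_pct,
            "cadence_hz": s.cadence_hz,
            "atypical": s.atypical,
        }
        for s in steps
    ]
    cols = [
        "side",
        "t_heel_strike_s",
        "t_toe_off_s",
        "t_next_heel_strike_s",
        "dt_stance_s",
        "dt_swing_s",
        "stance_pct",
        "swing_pct",
        "cadence_hz",
        "atypical",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.9g")


def read_steps_csv(path: str | Path) -> list[StepRecord]:
    df = pd.read_csv(path)
    return [
        StepRecord(
            side=row["side"],
            t_heel_strike=float(row["t_heel_strike_s"]),
            t_toe_off=float(row["t_toe_off_s"]),
            t_next_heel_strike=float(row["t_next_heel_strike_s"]),
            atypical=bool(row.get("atypical", False)),
        )
        for _, row in df.iterrows()
    ]


def write_scenario(scenario: GaitScenario, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(scenario), indent=2) + "\n")


def read_scenario(path: str | Path) -> GaitScenario:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(GaitScenario)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    return GaitScenario(**data)
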