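"""Per-cell forces, vertical ground reaction force (vGRF), CoP, pressure maps.

From the 64 de-offset voltages at one instant the pipeline computes the
per-cell forces F_i (via the calibration model), the total vertical ground
reaction force

    vGRF = sum_i F_i,

and the centre of pressure as the force-weighted centroid of the cell
coordinates

    CoP_x = sum_i F_i x_i / vGRF,     CoP_y = sum_i F_i y_i / vGRF.

Whenever vGRF > -20 N (i.e. the total load magnitude is below 20 N) the
device treats the foot as unloaded: vGRF is reported as 0 and the CoP is
undefined (NaN).  The centroid is computed from the raw force sum before
the rule is applied, so a defined CoP always reflects the actual load
distribution.  Forces are signed (compression negative); pressure maps are
reported as positive pressures in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import math

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator

from .sensor_model import AGGREGATE_MODEL, CalibrationModel, N_CELLS, SensorLayout, force_from_voltage

__all__ = [
    "VGRF_THRESHOLD_N",
    "BiomechSample",
    "PressureMap",
    "frame_forces",
    "compute_vgrf_cop",
    "process_frames",
    "pressure_map",
]

#: Loading threshold on the total force (N, signed): stance requires vGRF <= -20 N.
VGRF_THRESHOLD_N = -20.0


@dataclass(frozen=True)
class BiomechSample:
    """vGRF and CoP at one instant; CoP is NaN exactly when vGRF is 0."""

    t: float
    vgrf: float
    cop_x: float
    cop_y: float

    @property
    def cop_defined(self) -> bool:
        return not math.isnan(self.cop_x)


def frame_forces(
    voltages: Sequence[float],
    model: Union[CalibrationModel, Sequence[CalibrationModel]] = AGGREGATE_MODEL,
) -> np.ndarray:
    """Convert 64 de-offset voltages to 64 per-cell forces (N, <= 0).

    ``model`` is either one shared calibration model (the device's firmware
    behaviour) or a sequence of 64 per-cell models.
    """
    v = np.asarray(voltages, dtype=float)
    if v.shape != (N_CELLS,):
        raise ValueError(f"expected {N_CELLS} voltages, got shape {v.shape}")
    if isinstance(model, CalibrationModel):
        return force_from_voltage(v, model)
    models = list(model)
    if len(models) != N_CELLS:
        raise ValueError(f"expected {N_CELLS} per-cell models, got {len(models)}")
    return np.array([force_from_voltage(float(vi), m) for vi, m in zip(v, models)])


def compute_vgrf_cop(
    forces: Sequence[float],
    layout: SensorLayout,
    t: float = 0.0,
    vgrf_threshold: float = VGRF_THRESHOLD_N,
) -> BiomechSample:
    """Total vGRF and force-weighted CoP for one frame of per-cell forces.

    If the raw sum exceeds the threshold (|vGRF| < 20 N) the sample is
    treated as unloaded: vGRF = 0 and CoP = NaN.
    """
    f = np.asarray(forces, dtype=float)
    if f.shape != (N_CELLS,):
        raise ValueError(f"expected {N_CELLS} forces matching the layout, got {f.shape}")
    vgrf = float(f.sum())
    if vgrf > vgrf_threshold:
        return BiomechSample(t=t, vgrf=0.0, cop_x=float("nan"), cop_y=float("nan"))
    cop_x = float(f @ layout.x_mm / vgrf)
    cop_y = float(f @ layout.y_mm / vgrf)
    return BiomechSample(t=t, vgrf=vgrf, cop_x=cop_x, cop_y=cop_y)


def process_frames(
    forces: np.ndarray,
    layout: SensorLayout,
    times: np.ndarray,
    vgrf_threshold: float = VGRF_THRESHOLD_N,
) -> pd.DataFrame:
    """Vectorised vGRF/CoP over a (n, 64) force array.

    Returns a DataFrame with columns time_s, vgrf_N, cop_x_mm, cop_y_mm;
    CoP columns are NaN wherever the -20 N rule zeroes the sample.
    """
    f = np.asarray(forces, dtype=float)
    if f.ndim != 2 or f.shape[1] != N_CELLS:
        raise ValueError(f"expected force array of shape (n, {N_CELLS})")
    vgrf = f.sum(axis=1)
    loaded = vgrf <= vgrf_threshold
    with np.errstate(divide="ignore", invalid="ignore"):
        cop_x = np.where(loaded, f @ layout.x_mm / vgrf, np.nan)
        cop_y = np.where(loaded, f @ layout.y_mm / vgrf, np.nan)
    vgrf = np.where(loaded, vgrf, 0.0)
    return pd.DataFrame(
        {"time_s": np.asarray(times, dtype=float), "vgrf_N": vgrf, "cop_x_mm": cop_x, "cop_y_mm": cop_y}
    )


@dataclass(frozen=True)
class PressureMap:
    """Interpolated pressure field (kPa) over the layout plane."""

    x_mm: np.ndarray
    y_mm: np.ndarray
    pressure_kpa: np.ndarray  # shape (len(y_mm), len(x_mm))
    nodal_pressure_kpa: np.ndarray  # pressure at each cell node

    @property
    def max_kpa(self) -> float:
        return float(np.nanmax(self.pressure_kpa))


def pressure_map(
    forces: Sequence[float],
    layout: SensorLayout,
    grid_res_mm: float = 5.0,
) -> PressureMap:
    """Piecewise-linear pressure map over a mesh connecting the cell nodes.

    Nodal pressure is |F_i| / area (1 N over 1 cm^2 = 10 kPa); the surface
    linearly interpolates the nodes over their Delaunay triangulation with
    no smoothing and no outlier removal.  Points outside the sensed hull
    are NaN.
    """
    if grid_res_mm <= 0:
        raise ValueError("grid resolution must be positive")
    f = np.asarray(forces, dtype=float)
    if f.shape != (N_CELLS,):
        raise ValueError(f"expected {N_CELLS} forces")
    # 1 N / cm^2 = 10 kPa
    nodal = 10.0 * np.abs(f) / layout.area_cm2
    pts = np.column_stack([layout.x_mm, layout.y_mm])
    interp = LinearNDInterpolator(pts, nodal)
    xg = np.arange(layout.x_mm.min(), layout.x_mm.max() + grid_res_mm / 2, grid_res_mm)
    yg = np.arange(layout.y_mm.min(), layout.y_mm.max() + grid_res_mm / 2, grid_res_mm)
    xx, yy = np.meshgrid(xg, yg)
    zz = interp(xx, yy)
    return PressureMap(x_mm=xg, y_mm=yg, pressure_kpa=zz, nodal_pressure_kpa=nodal)
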