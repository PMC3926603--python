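"""Insole geometry and the voltage-to-force calibration model.

Each of the 64 optoelectronic cells behaves as a force-to-voltage
transducer.  After de-offsetting, the output voltage is zero when the cell
is unloaded and grows negative under compression.  The calibration model is
a sum of two exponentials

    F(v) = A1 * exp(c1 * v) + A2 * exp(c2 * v)        for v <= v0,
    F(v) = 0                                          for v >  v0,

with A1 > 0, c1 > 0, A2 < 0, c2 < 0 and a noise-threshold voltage v0
(default -0.02 V).  Under that sign pattern dF/dv > 0 everywhere, so the
loaded branch is strictly increasing and invertible.  Forces are signed:
negative means compression, matching the convention used throughout the
pipeline.  The firmware-style aggregate model (one curve for all 64 cells)
carries coefficients A1=21.386 N, c1=4.834 /V, A2=-22.30 N, c2=-0.401 /V.

Because the exponential model does not pass through the origin, zeroing the
force above v0 introduces a jump of |F(v0)| (about 3.06 N for the aggregate
model) at the threshold; ``threshold_force`` and ``worst_case_errors``
expose the resulting worst-case bounds on the total vertical ground
reaction force.
"""

from __future__ import annotations


import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "CalibrationModel",
    "SensorLayout",
    "FitReport",
    "AGGREGATE_MODEL",
    "FLEET_COEFF_MEAN",
    "FLEET_COEFF_SD",
    "F_FULL_SCALE_N",
    "N_CELLS",
    "default_layout",
    "force_from_voltage",
    "voltage_from_force",
    "threshold_force",
    "worst_case_errors",
    "fit_calibration",
    "aggregate_calibration",
    "summarize_models",
]

N_CELLS = 64

#: Full-scale force per cell: 500 kPa working range over a 1 cm^2 cell.
F_FULL_SCALE_N = 50.0


@dataclass(frozen=True)
class CalibrationModel:
    """Two-exponential voltage-to-force model with a noise threshold."""

    A1: float
    c1: float
    A2: float
    c2: float
    v0: float = -0.02

    def __post_init__(self) -> None:
        if not (self.A1 > 0 and self.c1 > 0 and self.A2 < 0 and self.c2 < 0):
            raise ValueError(
                "calibration coefficients must satisfy A1>0, c1>0, A2<0, c2<0; "
                f"got A1={self.A1}, c1={self.c1}, A2={self.A2}, c2={self.c2}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(A1=d["A1"], c1=d["c1"], A2=d["A2"], c2=d["c2"], v0=d.get("v0", -0.02))


#: Aggregate (shared, firmware-style) calibration model for all 64 cells.
AGGREGATE_MODEL = CalibrationModel(A1=21.386, c1=4.834, A2=-22.30, c2=-0.401)

#: Per-cell coefficient means and dispersions across the 64 fitted models,
#: used by the simulator to emulate cell-to-cell variability.
FLEET_COEFF_MEAN = {"A1": 19.366, "c1": 6.745, "A2": -20.458, "c2": -0.596}
FLEET_COEFF_SD = {"A1": 5.526, "c1": 3.704, "A2": 5.569, "c2": 0.214}


@dataclass(frozen=True)
class SensorLayout:
    """64 sensing cells with planar coordinates (mm) and contact area (cm^2).

    x is medial-lateral; y is antero-posterior with y=0 at the toe end and
    y=250 mm at the heel end.
    """

    cell_ids: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    area_cm2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("cell_ids", "x_mm", "y_mm", "area_cm2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        n = len(self.cell_ids)
        if n != N_CELLS:
            raise ValueError(f"layout must contain exactly {N_CELLS} cells, got {n}")
        if len(set(self.cell_ids.tolist())) != N_CELLS:
            raise ValueError("cell ids must be unique")
        if self.y_mm.min() < 0 or self.y_mm.max() > 250:
            raise ValueError("y coordinates must lie in [0, 250] mm")
        coords = set(zip(self.x_mm.tolist(), self.y_mm.tolist()))
        if len(coords) != N_CELLS:
            raise ValueError("no two cells may share identical (x, y) coordinates")

    def __eq__(self, other) -> bool:
        if not isinstance(other, SensorLayout):
            return NotImplemented
        return (
            np.array_equal(self.cell_ids, other.cell_ids)
            and np.array_equal(self.x_mm, other.x_mm)
            and np.array_equal(self.y_mm, other.y_mm)
            and np.array_equal(self.area_cm2, other.area_cm2)
        )

    def translated(self, dx_mm: float, dy_mm: float) -> "SensorLayout":
        return SensorLayout(self.cell_ids, self.x_mm + dx_mm, self.y_mm + dy_mm, self.area_cm2)

    def to_records(self) -> list[dict]:
        return [
            {
                "cell_id": int(i),
                "x_mm": float(x),
                "y_mm": float(y),
                "area_cm2": float(a),
            }
            for i, x, y, a in zip(self.cell_ids, self.x_mm, self.y_mm, self.area_cm2)
        ]

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "SensorLayout":
        records = sorted(records, key=lambda r: r["cell_id"])
        return cls(
            cell_ids=np.array([r["cell_id"] for r in records], dtype=int),
            x_mm=np.array([r["x_mm"] for r in records], dtype=float),
            y_mm=np.array([r["y_mm"] for r in records], dtype=float),
            area_cm2=np.array([r["area_cm2"] for r in records], dtype=float),
        )


# Foot-shaped arrangement on a 1 cm grid: (row-centre y in mm, cell x
# centres in mm).  Denser under the heel and forefoot, sparse along the arch
# and toes; 64 cells total spanning y in [15, 245] mm.
_DEFAULT_ROWS: tuple[tuple[int, tuple[int, ...]], ...] = (
    (245, (35, 45, 55)),
    (235, (30, 40, 50, 60)),
    (225, (30, 40, 50, 60)),
    (215, (30, 40, 50, 60)),
    (205, (35, 45, 55)),
    (195, (40, 50)),
    (185, (40, 50)),
    (175, (40, 50)),
    (165, (40, 50)),
    (155, (40, 50)),
    (145, (40, 50)),
    (135, (35, 45, 55)),
    (125, (35, 45, 55)),
    (115, (35, 45, 55)),
    (105, (30, 40, 50, 60)),
    (95, (30, 40, 50, 60)),
    (85, (30, 40, 50, 60)),
    (75, (35, 45, 55)),
    (65, (40, 50)),
    (55, (40, 50)),
    (45, (40, 50)),
    (35, (40, 50)),
    (25, (45,)),
    (15, (45,)),
)


def default_layout() -> SensorLayout:
    """Deterministic foot-shaped 64-cell layout on a 1 cm grid.

    The device's actual cell coordinates are a hardware property; this
    layout is a plausible convention (heel and forefoot denser than arch
    and toes) and is always overridable from a layout file.
    """
    xs, ys = [], []
    for y, row_xs in _DEFAULT_ROWS:
        for x in row_xs:
            xs.append(float(x))
            ys.append(float(y))
    ids = np.arange(N_CELLS)
    return SensorLayout(ids, np.array(xs), np.array(ys), np.ones(N_CELLS))


def force_from_voltage(v, model: CalibrationModel = AGGREGATE_MODEL):
    """Convert de-offset voltage(s) to force(s) in N.

    Returns 0 above the noise threshold v0, else the two-exponential model.
    Output forces are <= 0 under the sign conventions (compression is
    negative).  Accepts scalars or arrays.
    """
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("voltage input must be finite")
    loaded = arr <= model.v0
    f = np.zeros_like(arr)
    vl = arr[loaded] if arr.ndim else arr
    if arr.ndim == 0:
        if loaded:
            f = model.A1 * math.exp(model.c1 * float(arr)) + model.A2 * math.exp(
                model.c2 * float(arr)
            )
            return float(f)
        return 0.0
    f[loaded] = model.A1 * np.exp(model.c1 * vl) + model.A2 * np.exp(model.c2 * vl)
    return f


def threshold_force(model: CalibrationModel = AGGREGATE_MODEL) -> float:
    """Magnitude |F(v0)| of the jump at the noise threshold (N).

    Any cell loaded just below this magnitude reads exactly 0 N; for the
    aggregate model the value is about 3.06 N.
    """
    return abs(force_from_voltage(model.v0, model))


def worst_case_errors(model: CalibrationModel = AGGREGATE_MODEL) -> dict:
    """Closed-form worst-case error bounds on the total vertical force.

    - ``per_cell_threshold_N``: |F(v0)|, the largest force a single cell can
      read as zero.
    - ``vgrf_threshold_error_N``: 64 x per-cell threshold force — all cells
      loaded just under the threshold.
    - ``vgrf_calibration_error_N``: 64 x (5% of the 50 N full scale) — the
      shared-model RMSE (about 5% f.s.r.) summed over all cells at full
      load.
    """
    per_cell = threshold_force(model)
    return {
        "per_cell_threshold_N": per_cell,
        "vgrf_threshold_error_N": N_CELLS * per_cell,
        "vgrf_calibration_error_N": N_CELLS * 0.05 * F_FULL_SCALE_N,
    }


def voltage_from_force(F: float, model: CalibrationModel = AGGREGATE_MODEL) -> float:
    """Invert the loaded branch: find v <= v0 with F(v) = F.

    The loaded branch is strictly increasing with range (-inf, F(v0)], so
    any representable compressive force has a unique voltage.  Raises
    ``ValueError`` for forces outside that range (including magnitudes below
    the threshold force, which the thresholded model cannot produce).
    """
    if not math.isfinite(F):
        raise ValueError("force must be finite")
    f_at_v0 = force_from_voltage(model.v0, model)
    if F > f_at_v0:
        raise ValueError(
            f"force {F} N not representable: loaded branch covers (-inf, {f_at_v0:.4f}] N"
        )
    if F == f_at_v0:
        return model.v0
    lo = model.v0 - 0.1
    while force_from_voltage(lo, model) > F:
        lo = model.v0 + 2.0 * (lo - model.v0)
        if lo < model.v0 - 1e6:  # pragma: no cover - pathological model
            raise RuntimeError("failed to bracket the force")
    return float(
        optimize.brentq(
            lambda v: force_from_voltage(v, model) - F,
            lo,
            model.v0,
            xtol=1e-14,
            rtol=8.9e-16,
        )
    )


def voltage_from_force_batch(F, model: CalibrationModel = AGGREGATE_MODEL) -> np.ndarray:
    """Vectorised inverse of the loaded branch for arrays of forces.

    Monotone-table initialisation followed by Newton polishing; agrees with
    ``voltage_from_force`` to ~1e-12 V and is orders of magnitude faster on
    long arrays (the simulator inverts every loaded cell sample).
    """
    F = np.asarray(F, dtype=float)
    f_at_v0 = force_from_voltage(model.v0, model)
    if np.any(F > f_at_v0 + 1e-12):
        raise ValueError("force outside the representable compressive range")
    vgrid = np.linspace(model.v0 - 40.0, model.v0, 8001)
    fgrid = model.A1 * np.exp(model.c1 * vgrid) + model.A2 * np.exp(model.c2 * vgrid)
    v = np.interp(F, fgrid, vgrid)
    for _ in range(4):
        e1 = np.exp(model.c1 * v)
        e2 = np.exp(model.c2 * v)
        fv = model.A1 * e1 + model.A2 * e2
        dfv = model.A1 * model.c1 * e1 + model.A2 * model.c2 * e2
        v = v - (fv - F) / dfv
    return np.minimum(v, model.v0)


@dataclass(frozen=True)
class FitReport:
    """Fitted calibration model with goodness-of-fit figures."""

    model: CalibrationModel
    rmse_N: float
    r2: float
    rmse_pct_fsr: float = field(default=None)  # type: ignore[assignment]
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.rmse_pct_fsr is None:
            object.__setattr__(self, "rmse_pct_fsr", 100.0 * self.rmse_N / F_FULL_SCALE_N)

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "rmse_N": self.rmse_N,
            "r2": self.r2,
            "rmse_pct_fsr": self.rmse_pct_fsr,
            "n_samples": self.n_samples,
        }


def _linear_amplitudes(v: np.ndarray, F: np.ndarray, c1: float, c2: float):
    """Best (A1, A2) for fixed rates by linear least squares."""
    X = np.column_stack([np.exp(c1 * v), np.exp(c2 * v)])
    coef, *_ = np.linalg.lstsq(X, F, rcond=None)
    resid = F - X @ coef
    return coef, float(resid @ resid)


def fit_calibration(
    samples: Iterable[tuple[float, float]],
    v0: float = -0.02,
) -> FitReport:
    """Fit F = A1*exp(c1*v) + A2*exp(c2*v) to (voltage, force) samples.

    Multi-start: a coarse grid over the rates (c1, c2) with the amplitudes
    solved linearly at each start, followed by bounded nonlinear refinement
    of the best candidates.  The bounds A1 > 0 > A2, c1 > 0 > c2 break the
    label-swap degeneracy of the two-exponential family.  Deterministic.
    """
    pts = np.asarray(list(samples), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
        raise ValueError("need at least 8 (voltage, force) samples")
    v, F = pts[:, 0], pts[:, 1]
    if np.ptp(v) == 0:
        raise ValueError("degenerate input: all voltages identical")

    starts = []
    for c1 in (1.0, 2.5, 4.0, 5.5, 7.0, 9.0, 12.0):
        for c2 in (-1.2, -0.8, -0.5, -0.3, -0.15):
            (a1, a2), ss = _linear_amplitudes(v, F, c1, c2)
            starts.append((ss, a1, c1, a2, c2))
    starts.sort(key=lambda s: s[0])

    eps = 1e-9
    lb = [eps, eps, -np.inf, -np.inf]
    ub = [np.inf, np.inf, -eps, -eps]

    def residuals(p):
        a1, c1, a2, c2 = p
        return a1 * np.exp(c1 * v) + a2 * np.exp(c2 * v) - F

    best = None
    for ss, a1, c1, a2, c2 in starts[:4]:
        x0 = np.clip([max(a1, eps), c1, min(a2, -eps), c2], lb, ub)
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e6:
        raise RuntimeError("calibration fit failed to converge from any start")

    a1, c1, a2, c2 = best.x
    model = CalibrationModel(A1=float(a1), c1=float(c1), A2=float(a2), c2=float(c2), v0=v0)
    resid = residuals(best.x)
    sse = float(resid @ resid)
    rmse = math.sqrt(sse / len(F))
    tss = float(np.sum((F - F.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else (1.0 if sse == 0 else -np.inf)
    return FitReport(model=model, rmse_N=rmse, r2=r2, n_samples=len(F))


def aggregate_calibration(
    per_cell_samples: Sequence[Iterable[tuple[float, float]]],
    v0: float = -0.02,
) -> FitReport:
    """Fit one shared model to the pooled samples of all cells.

    Averaging the behaviour of all cells is realised as a pooled fit (not
    an average of per-cell coefficients): the pooled model minimises the
    residuals over every cell's data jointly, which is what a single
    firmware curve actually sees.
    """
    pooled: list[tuple[float, float]] = []
    for s in per_cell_samples:
        pooled.extend((float(a), float(b)) for a, b in s)
    return fit_calibration(pooled, v0=v0)


def summarize_models(reports: Sequence[FitReport]) -> dict:
    """Per-coefficient mean and sample sd across fitted per-cell models."""
    if not reports:
        raise ValueError("no reports to summarize")

    def stats(vals):
        a = np.asarray(vals, dtype=float)
        sd = float(a.std(ddof=1)) if len(a) > 1 else 0.0
        return {"mean": float(a.mean()), "sd": sd}

    out = {
        name: stats([getattr(r.model, name) for r in reports])
        for name in ("A1", "c1", "A2", "c2")
    }
    out["rmse_N"] = stats([r.rmse_N for r in reports])
    out["r2"] = stats([r.r2 for r in reports])
    out["rmse_pct_fsr"] = stats([r.rmse_pct_fsr for r in reports])
    out["n_models"] = len(reports)
    return out
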