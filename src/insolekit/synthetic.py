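"""Synthetic walking trials with known ground truth.

The simulator stands in for the hardware: it produces raw 64-channel
voltage streams at 1200 Hz for both feet, generated by pushing a
physiological gait pattern backwards through the transduction chain:

  1. a double-peak stance vGRF curve (weight-acceptance peak at 15–25 % of
     stance, push-off peak at 70–80 %, magnitudes scaled to body weight);
  2. a CoP trajectory progressing monotonically heel (y ~ 240 mm) to toe
     (y ~ 20 mm), crossing the 125 mm ST1/ST2 boundary exactly once;
  3. a compact contact patch (super-Gaussian footprint) that distributes
     the total force over nearby cells so that the per-cell forces
     reproduce the requested vGRF and CoP exactly (exponential tilting of
     the footprint weights);
  4. inversion of the per-cell voltage-to-force model, plus a static
     per-channel offset and Gaussian sensor noise.

Left and right feet alternate with a configurable double-support fraction
of the stride.  A ground-truth sidecar records every event time, per-step
temporal parameter, and the true vGRF/CoP series, so recovery by the
analysis pipeline can be checked sample by sample.

What the generator does not emulate: shear loads, ADC quantisation,
transmission losses, soft-tissue dynamics, or inter-step variability of
the vGRF shape beyond what the noise produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import sensor_model as sm
from .sensor_model import AGGREGATE_MODEL, CalibrationModel, N_CELLS, SensorLayout, default_layout
from .signal_pipeline import RawVoltageStream

__all__ = [
    "GaitScenario",
    "GroundTruth",
    "simulate_vgrf_profile",
    "simulate_cop_trajectory",
    "distribute_pressure",
    "forces_to_voltages",
    "sample_cell_models",
    "generate_trial",
]

#: gravitational acceleration, for body-weight scaling of force magnitudes
_G = 9.81


@dataclass(frozen=True)
class GaitScenario:
    """Parameters of one simulated walking trial.

    Timing defaults match self-selected slow walking of a healthy young
    adult: stance 0.80 s, swing 0.45 s (cadence 0.8 Hz), double support
    14 % of the stride.  Force magnitudes default to fractions of body
    weight (peaks ~1.1 and ~1.05 BW, mid-stance valley ~0.75 BW).  The
    noise sd of 0.005 V leaves unloaded channels below the 0.02 V noise
    threshold with 4-sigma margin.
    """

    n_steps: int = 10
    dt_stance_s: float = 0.80
    dt_swing_s: float = 0.45
    ds_fraction: float = 0.14
    subject_weight_kg: float = 75.0
    peak1_N: float | None = None
    peak2_N: float | None = None
    valley_N: float | None = None
    peak1_frac_of_stance: float = 0.20
    peak2_frac_of_stance: float = 0.75
    cop_y_start_mm: float = 240.0
    cop_y_end_mm: float = 20.0
    cop_x_center_mm: float = 45.0
    cop_x_sway_mm: float = 5.0
    footprint_radius_mm: float = 45.0
    noise_sd_V: float = 0.005
    offset_V: float = 1.3
    offset_spread_V: float = 0.05
    fs_hz: float = 1200.0
    lead_in_s: float = 1.0
    per_cell_variability: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        bw = self.subject_weight_kg * _G
        if self.peak1_N is None:
            object.__setattr__(self, "peak1_N", 1.10 * bw)
        if self.peak2_N is None:
            object.__setattr__(self, "peak2_N", 1.05 * bw)
        if self.valley_N is None:
            object.__setattr__(self, "valley_N", 0.75 * bw)
        if self.dt_stance_s <= 0 or self.dt_swing_s <= 0:
            raise ValueError("stance and swing durations must be positive")
        if not (self.valley_N <= min(self.peak1_N, self.peak2_N)):
            raise ValueError("peak magnitudes must be >= valley magnitude")
        if min(self.peak1_N, self.peak2_N, self.valley_N) < 0:
            raise ValueError("force magnitudes must be non-negative")
        if not 0 <= self.ds_fraction < self.stance_fraction:
            raise ValueError(
                f"ds_fraction {self.ds_fraction} infeasible: must be < stance fraction "
                f"{self.stance_fraction:.3f} of the stride"
            )
        if self.foot_offset_s <= 0 or self.foot_offset_s >= self.stride_s:
            raise ValueError("infeasible timing: left/right offset outside the stride")

    @property
    def stride_s(self) -> float:
        return self.dt_stance_s + self.dt_swing_s

    @property
    def stance_fraction(self) -> float:
        return self.dt_stance_s / self.stride_s

    @property
    def cadence_hz(self) -> float:
        return 1.0 / self.stride_s

    @property
    def dt_double_support_s(self) -> float:
        return self.ds_fraction * self.stride_s

    @property
    def foot_offset_s(self) -> float:
        """Delay of the right heel strike after the left one.

        Double support is the tail of one foot's stance overlapping the
        other foot's new stance, so offset = stance - ds duration.
        """
        return self.dt_stance_s - self.dt_double_support_s


def _raised_cosine(s: np.ndarray, center: float, radius: float) -> np.ndarray:
    """Smooth compactly-supported bump: 1 at center, 0 beyond +/- radius."""
    d = np.abs(s - center)
    out = np.zeros_like(s)
    inside = d < radius
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * d[inside] / radius))
    return out


def _edge_ramp(s: np.ndarray, ramp: float = 0.10) -> np.ndarray:
    """Smooth 0->1->0 envelope: raised-cosine ramps at both stance edges."""
    out = np.ones_like(s)
    lo = s < ramp
    hi = s > 1.0 - ramp
    out[lo] = 0.5 * (1.0 - np.cos(np.pi * s[lo] / ramp))
    out[hi] = 0.5 * (1.0 - np.cos(np.pi * (1.0 - s[hi]) / ramp))
    out[(s < 0) | (s > 1)] = 0.0
    return out


def simulate_vgrf_profile(scenario: GaitScenario, s: np.ndarray) -> np.ndarray:
    """Double-peak stance vGRF magnitude at normalised stance times s in [0, 1].

    The curve is a valley-level plateau (zero at both stance boundaries)
    plus two raised-cosine lobes centred at the weight-acceptance and
    push-off peak times.  Returns magnitudes (N, >= 0); the pipeline's sign
    convention (compression negative) is applied downstream.
    """
    s = np.asarray(s, dtype=float)
    base = scenario.valley_N * _edge_ramp(s)
    lobe_r = 0.16
    p1 = scenario.peak1_frac_of_stance
    p2 = scenario.peak2_frac_of_stance
    curve = (
        base
        + (scenario.peak1_N - scenario.valley_N) * _raised_cosine(s, p1, lobe_r)
        + (scenario.peak2_N - scenario.valley_N) * _raised_cosine(s, p2, lobe_r)
    )
    curve[(s <= 0) | (s >= 1)] = 0.0
    return curve


def simulate_cop_trajectory(scenario: GaitScenario, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CoP (x, y) in mm at normalised stance times s.

    cop_y decreases monotonically from ~heel to ~toe at a constant
    progression rate (placing the push-off peak under the forefoot and
    reaching the toe region only as the load vanishes), crossing the
    125 mm phase boundary exactly once; cop_x makes a small
    medial-lateral sway that vanishes near contact and lift-off (where
    few cells are loaded).
    """
    s = np.asarray(s, dtype=float)
    y = scenario.cop_y_start_mm + (scenario.cop_y_end_mm - scenario.cop_y_start_mm) * np.clip(
        s, 0.0, 1.0
    )
    sway_s = np.clip((s - 0.05) / 0.80, 0.0, 1.0)
    x = scenario.cop_x_center_mm + scenario.cop_x_sway_mm * np.sin(np.pi * sway_s) ** 2
    return x, y


def cop_boundary_crossing_s(scenario: GaitScenario, boundary_mm: float = 125.0) -> float:
    """Normalised stance time at which cop_y crosses the given boundary."""
    from scipy.optimize import brentq

    f = lambda s: simulate_cop_trajectory(scenario, np.array([s]))[1][0] - boundary_mm
    return float(brentq(f, 1e-9, 1 - 1e-9, xtol=1e-12))


def distribute_pressure(
    vgrf_N: float,
    cop: tuple[float, float],
    layout: SensorLayout,
    radius_mm: float = 45.0,
    _tilt0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Distribute a total force over cells near the CoP.

    Per-cell weights start from a compact, near-uniform contact patch
    (super-Gaussian footprint, hard cutoff at ``radius_mm``) centred at the
    CoP, emulating the finite contact area of the foot: at walking loads
    the patch keeps individual cells near their 0-500 kPa working range.
    The weights are exponentially tilted so that the force-weighted
    centroid matches the CoP to < 1e-6 mm while the forces stay
    non-positive and sum exactly to the requested vGRF.  Returns
    (forces, tilt) where ``tilt`` warm-starts the next solve.

    ``vgrf_N`` is signed (<= 0); vgrf = 0 yields all-zero forces.
    """
    forces = np.zeros(N_CELLS)
    if vgrf_N == 0:
        return forces, _tilt0
    if vgrf_N > 0:
        raise ValueError("vgrf must be <= 0 (compression is negative)")
    cx, cy = cop
    dx = layout.x_mm - cx
    dy = layout.y_mm - cy
    d2 = dx * dx + dy * dy
    sigma = 0.8 * radius_mm
    inside = d2 < radius_mm * radius_mm
    if not inside.any():
        raise ValueError(f"CoP ({cx:.1f}, {cy:.1f}) mm has no cells within {radius_mm} mm")
    idx = np.flatnonzero(inside)
    pts = np.column_stack([layout.x_mm[idx], layout.y_mm[idx]])
    logw = -((d2[idx] / (sigma * sigma)) ** 2)
    target = np.array([cx, cy])

    hull_lo = pts.min(axis=0) - 1e-9
    hull_hi = pts.max(axis=0) + 1e-9
    if np.any(target < hull_lo) or np.any(target > hull_hi):
        raise ValueError(f"CoP ({cx:.1f}, {cy:.1f}) mm outside the loaded-cell bounding box")

    tilt = np.zeros(2) if _tilt0 is None else _tilt0.copy()
    # Newton iteration on the exponential tilt: the Jacobian of the
    # weighted mean w.r.t. the tilt is the weighted covariance of the
    # cell coordinates.
    for _ in range(80):
        z = logw + pts @ tilt
        z -= z.max()
        p = np.exp(z)
        p /= p.sum()
        mu = p @ pts
        err = target - mu
        if np.abs(err).max() < 1e-9:
            break
        centred = pts - mu
        cov = centred.T @ (centred * p[:, None])
        cov[0, 0] += 1e-12
        cov[1, 1] += 1e-12
        try:
            step = np.linalg.solve(cov, err)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(cov, err, rcond=None)[0]
        step_norm = np.abs(step).max()
        if step_norm > 2.0:  # damp aggressive steps far from the solution
            step *= 2.0 / step_norm
        tilt = tilt + step
    else:
        raise RuntimeError(
            f"pressure distribution did not converge for CoP ({cx:.2f}, {cy:.2f}) mm"
        )
    forces[idx] = vgrf_N * p
    return forces, tilt


def sample_cell_models(
    rng: np.random.Generator,
    n: int = N_CELLS,
    spread_scale: float = 1.0,
    max_curve_rmse_N: float | None = 4.0,
) -> list[CalibrationModel]:
    """Draw per-cell calibration models around the fleet-average coefficients.

    Coefficients are drawn from normals centred on the averaged per-cell
    values with the reported dispersions (scaled by ``spread_scale``),
    truncated at +/- 2 sd and clipped to the sign pattern A1>0, c1>0,
    A2<0, c2<0 that guarantees a monotone loaded branch.

    Two-exponential fits are ill-conditioned: cells cast from one mold have
    very similar force-voltage *curves* even though their fitted
    *coefficients* scatter widely.  Independent coefficient draws ignore
    that coupling and can produce cells wildly inconsistent with the shared
    curve, so draws are rejected unless the cell's curve stays within
    ``max_curve_rmse_N`` (RMS over the 0-50 N working range, comparable to
    the shared model's pooled RMSE) of the aggregate curve.  Pass ``None``
    to disable the constraint.
    """
    mean = sm.FLEET_COEFF_MEAN
    sd = sm.FLEET_COEFF_SD
    f_grid = -np.linspace(8.0, 50.0, 22)
    models: list[CalibrationModel] = []
    tries = 0
    while len(models) < n:
        tries += 1
        if tries > 2000 * n:
            raise RuntimeError("cell-model sampling failed to find acceptable curves")
        coefs = {
            k: mean[k] + spread_scale * sd[k] * float(np.clip(rng.normal(), -2.0, 2.0))
            for k in ("A1", "c1", "A2", "c2")
        }
        coefs["A1"] = max(coefs["A1"], 1.0)
        coefs["c1"] = max(coefs["c1"], 0.5)
        coefs["A2"] = min(coefs["A2"], -1.0)
        coefs["c2"] = min(coefs["c2"], -0.05)
        m = CalibrationModel(**coefs)
        if max_curve_rmse_N is not None:
            try:
                v = sm.voltage_from_force_batch(f_grid, m)
            except ValueError:  # dead zone swallows part of the working range
                continue
            decoded = sm.force_from_voltage(v, AGGREGATE_MODEL)
            if math.sqrt(float(np.mean((decoded - f_grid) ** 2))) > max_curve_rmse_N:
                continue
        models.append(m)
    return models


def forces_to_voltages(
    forces: Sequence[float],
    model: CalibrationModel | Sequence[CalibrationModel] = AGGREGATE_MODEL,
    noise_sd_V: float = 0.0,
    rng: np.random.Generator | None = None,
    offsets_V: Sequence[float] | float = 0.0,
) -> np.ndarray:
    """Invert the calibration model per cell and re-add offset and noise.

    Forces of magnitude below the model's threshold force cannot be
    represented by the thresholded transduction law; those cells emit the
    unloaded de-offset voltage 0 V (the dead zone of the hardware).
    """
    f = np.asarray(forces, dtype=float)
    if f.shape != (N_CELLS,):
        raise ValueError(f"expected {N_CELLS} forces")
    models = [model] * N_CELLS if isinstance(model, CalibrationModel) else list(model)
    if len(models) != N_CELLS:
        raise ValueError(f"expected {N_CELLS} per-cell models")
    v = np.zeros(N_CELLS)
    for i, (fi, m) in enumerate(zip(f, models)):
        if fi > 0:
            raise ValueError("forces must be <= 0 (compression)")
        thr = sm.force_from_voltage(m.v0, m)
        if fi <= thr:
            v[i] = sm.voltage_from_force(float(fi), m)
    v = v + np.asarray(offsets_V, dtype=float)
    if noise_sd_V > 0:
        if rng is None:
            raise ValueError("noise requested but no random generator given")
        v = v + rng.normal(0.0, noise_sd_V, size=N_CELLS)
    return v


@dataclass(frozen=True)
class GroundTruth:
    """True events, per-step parameters and vGRF/CoP series of a trial."""

    scenario: GaitScenario
    heel_strikes: dict  # side -> list of times (s)
    toe_offs: dict  # side -> list of times (s)
    dt_stance_s: float
    dt_swing_s: float
    dt_double_support_s: float
    cadence_hz: float
    st1_st2_crossing_s: float  # stance time of the CoP 125 mm crossing
    true_vgrf: dict  # side -> ndarray at fs_hz (signed, N)
    true_cop_y: dict  # side -> ndarray at fs_hz (mm, NaN in swing)
    times: np.ndarray

    def to_dict(self) -> dict:
        return {
            "dt_stance_s": self.dt_stance_s,
            "dt_swing_s": self.dt_swing_s,
            "dt_double_support_s": self.dt_double_support_s,
            "cadence_hz": self.cadence_hz,
            "st1_st2_crossing_s": self.st1_st2_crossing_s,
            "heel_strikes": {k: list(map(float, v)) for k, v in self.heel_strikes.items()},
            "toe_offs": {k: list(map(float, v)) for k, v in self.toe_offs.items()},
        }


def _foot_stance_schedule(scenario: GaitScenario, side: str) -> np.ndarray:
    """Heel-strike times of one foot; n_steps+1 stances close n_steps steps."""
    first = scenario.lead_in_s if side == "left" else scenario.lead_in_s + scenario.foot_offset_s
    return first + scenario.stride_s * np.arange(scenario.n_steps + 1)


def generate_trial(
    scenario: GaitScenario,
    layout: SensorLayout | None = None,
) -> tuple[RawVoltageStream, RawVoltageStream, GroundTruth]:
    """Simulate one walking trial: left/right raw streams plus ground truth.

    Both feet share the layout and alternate with the scenario's
    double-support overlap.  Each foot performs n_steps+1 stance phases so
    that exactly n_steps complete steps (heel strike to heel strike) exist.
    """
    if layout is None:
        layout = default_layout()
    rng = np.random.default_rng(scenario.seed)

    hs = {side: _foot_stance_schedule(scenario, side) for side in ("left", "right")}
    to = {side: times + scenario.dt_stance_s for side, times in hs.items()}
    duration = float(to["right"][-1] + scenario.dt_swing_s + 0.5)
    n = int(round(duration * scenario.fs_hz))
    t = np.arange(n) / scenario.fs_hz

    if scenario.per_cell_variability:
        cell_models = sample_cell_models(rng)
    else:
        cell_models = [AGGREGATE_MODEL] * N_CELLS
    thresholds = np.array([sm.force_from_voltage(m.v0, m) for m in cell_models])

    streams = {}
    true_vgrf = {}
    true_cop_y = {}
    for side in ("left", "right"):
        offsets = scenario.offset_V + rng.normal(0.0, scenario.offset_spread_V, size=N_CELLS)
        volts = np.tile(offsets, (n, 1))
        vg = np.zeros(n)
        cy = np.full(n, np.nan)
        for t_hs in hs[side]:
            i0 = int(math.ceil(t_hs * scenario.fs_hz))
            i1 = int(math.floor((t_hs + scenario.dt_stance_s) * scenario.fs_hz))
            i1 = min(i1, n - 1)
            s = (t[i0 : i1 + 1] - t_hs) / scenario.dt_stance_s
            mag = simulate_vgrf_profile(scenario, s)
            cop_x, cop_y = simulate_cop_trajectory(scenario, s)
            vg[i0 : i1 + 1] = -mag
            cy[i0 : i1 + 1] = cop_y
            F = np.zeros((len(s), N_CELLS))
            tilt = None
            for k in range(len(s)):
                if mag[k] == 0:
                    continue
                F[k], tilt = distribute_pressure(
                    -float(mag[k]),
                    (float(cop_x[k]), float(cop_y[k])),
                    layout,
                    radius_mm=scenario.footprint_radius_mm,
                    _tilt0=tilt,
                )
            for i in range(N_CELLS):
                rep = np.flatnonzero(F[:, i] <= thresholds[i])
                if rep.size:
                    volts[i0 + rep, i] = offsets[i] + sm.voltage_from_force_batch(
                        F[rep, i], cell_models[i]
                    )
        if scenario.noise_sd_V > 0:
            volts = volts + rng.normal(0.0, scenario.noise_sd_V, size=volts.shape)
        streams[side] = RawVoltageStream(data=volts, fs_hz=scenario.fs_hz, t0=0.0)
        true_vgrf[side] = vg
        true_cop_y[side] = cy

    truth = GroundTruth(
        scenario=scenario,
        heel_strikes={k: v.tolist() for k, v in hs.items()},
        toe_offs={k: v.tolist() for k, v in to.items()},
        dt_stance_s=scenario.dt_stance_s,
        dt_swing_s=scenario.dt_swing_s,
        dt_double_support_s=scenario.dt_double_support_s,
        cadence_hz=scenario.cadence_hz,
        st1_st2_crossing_s=cop_boundary_crossing_s(scenario) * scenario.dt_stance_s,
        true_vgrf=true_vgrf,
        true_cop_y=true_cop_y,
        times=t,
    )
    return streams["left"], streams["right"], truth
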