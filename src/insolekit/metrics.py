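"""Step-profile resampling/averaging and comparison statistics.

For validation against a reference force platform, each stance-phase vGRF
segment is linearly resampled onto 100 points (0–100 % of stance), averaged
across steps, and compared with:

    RMSE   = sqrt( sum_i (a_i - b_i)^2 / n )
    NRMSE  = RMSE / (max(a) - min(a))          (a = insole profile)
    PC     = sample Pearson correlation
    MAE    = mean |stance duration difference|

NRMSE is normalised by the range of the insole profile, so it is scale-free
with respect to a common rescaling of both profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RESAMPLE_N",
    "ComparisonReport",
    "resample_profile",
    "average_profiles",
    "nrmse",
    "pearson",
    "mae_stance",
    "compare_step_profiles",
]

#: Number of points each stance profile is resampled onto.
RESAMPLE_N = 100


def resample_profile(segment: Sequence[float], n: int = RESAMPLE_N) -> np.ndarray:
    """Linearly resample one stance segment onto n equally spaced points.

    The output endpoints equal the segment's first and last values.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 1 or len(seg) < 2:
        raise ValueError("segment must be a 1-D series of at least 2 samples")
    x_old = np.linspace(0.0, 1.0, len(seg))
    x_new = np.linspace(0.0, 1.0, n)
    return np.interp(x_new, x_old, seg)


def average_profiles(profiles: Sequence[Sequence[float]]) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample sd over a set of equal-length profiles."""
    arr = np.asarray(profiles, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need at least one profile, all of equal length")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    return mean, sd


def nrmse(a: Sequence[float], b: Sequence[float]) -> float:
    """RMSE between two profiles normalised by the range of the first.

    ``a`` is the insole profile (the normaliser); raises on zero range.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    rng = float(a.max() - a.min())
    if rng == 0:
        raise ValueError("insole profile has zero range; NRMSE undefined")
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    return rmse / rng


def pearson(a: Sequence[float], b: Sequence[float]) -> float:
    """Sample Pearson correlation between two profiles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("profiles must have equal length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson correlation undefined for a constant profile")
    return float(stats.pearsonr(a, b).statistic)


def mae_stance(insole_durations: Sequence[float], reference_durations: Sequence[float]) -> float:
    """Mean absolute error between paired stance durations (s)."""
    a = np.asarray(insole_durations, dtype=float)
    b = np.asarray(reference_durations, dtype=float)
    if a.shape != b.shape:
        raise ValueError("duration lists must be paired (equal length)")
    return float(np.mean(np.abs(a - b)))


@dataclass(frozen=True)
class ComparisonReport:
    """Insole-vs-reference comparison in the shape used for reporting."""

    nrmse_mean: float
    nrmse_sd: float
    pearson_mean: float
    pearson_sd: float
    mae_stance_s: float
    n_steps: int

    def to_dict(self) -> dict:
        return {
            "nrmse": {"mean": self.nrmse_mean, "sd": self.nrmse_sd},
            "pearson": {"mean": self.pearson_mean, "sd": self.pearson_sd},
            "mae_stance_s": self.mae_stance_s,
            "n_steps": self.n_steps,
        }


def compare_step_profiles(
    insole_profiles: Sequence[Sequence[float]],
    reference_profiles: Sequence[Sequence[float]],
    insole_stance_s: Sequence[float],
    reference_stance_s: Sequence[float],
) -> ComparisonReport:
    """Per-step NRMSE/Pearson plus stance-duration MAE, aggregated."""
    if len(insole_profiles) != len(reference_profiles) or len(insole_profiles) == 0:
        raise ValueError("need equal, nonzero numbers of paired step profiles")
    nr = [nrmse(a, b) for a, b in zip(insole_profiles, reference_profiles)]
    pc = [pearson(a, b) for a, b in zip(insole_profiles, reference_profiles)]
    nr_a, pc_a = np.asarray(nr), np.asarray(pc)
    return ComparisonReport(
        nrmse_mean=float(nr_a.mean()),
        nrmse_sd=float(nr_a.std(ddof=1)) if len(nr_a) > 1 else 0.0,
        pearson_mean=float(pc_a.mean()),
        pearson_sd=float(pc_a.std(ddof=1)) if len(pc_a) > 1 else 0.0,
        mae_stance_s=mae_stance(insole_stance_s, reference_stance_s),
        n_steps=len(nr),
    )
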