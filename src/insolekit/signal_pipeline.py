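"""Conditioning of raw 64-channel voltage streams.

The acquisition chain samples all 64 cells at 1.2 kHz, low-pass filters at
40 Hz and down-samples to 100 Hz before the voltage-to-force conversion.
This module mirrors that chain on stored streams: baseline removal
(de-offset), causal low-pass filtering, and decimation by an integer
factor.  The filter is a 2nd-order causal Butterworth by default —
real-time capable, like the on-board implementation — with order and
zero-phase filtering configurable for offline use.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .sensor_model import N_CELLS

__all__ = ["RawVoltageStream", "ProcessedStream", "deoffset", "lowpass_decimate"]


@dataclass(frozen=True)
class RawVoltageStream:
    """Timestamped 64-channel voltage stream.

    ``data`` has shape (n_samples, 64); ``fs_hz`` is the sampling rate and
    ``t0`` the time of the first sample.
    """

    data: np.ndarray
    fs_hz: float = 1200.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != N_CELLS:
            raise ValueError(f"stream data must have shape (n, {N_CELLS})")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "data", arr)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs_hz


@dataclass(frozen=True)
class ProcessedStream(RawVoltageStream):
    """De-offset, filtered and decimated stream (default 100 Hz).

    ``baseline`` records the per-channel offset that was subtracted, so the
    processing is reproducible from the raw stream.
    """

    fs_hz: float = 100.0
    baseline: np.ndarray | None = None


def deoffset(
    stream: RawVoltageStream,
    baseline_window: tuple[float, float] | None = None,
) -> tuple[RawVoltageStream, np.ndarray]:
    """Subtract the per-channel mean over an unloaded window.

    ``baseline_window`` is a (start, stop) time interval in seconds during
    which the insole is unloaded; default is the first 0.5 s of the stream.
    After de-offsetting, unloaded samples sit near 0 V and loaded samples
    go negative.  Returns the corrected stream and the baseline vector.
    """
    if baseline_window is None:
        baseline_window = (stream.t0, stream.t0 + 0.5)
    start, stop = baseline_window
    t = stream.times
    mask = (t >= start) & (t < stop)
    if not mask.any():
        raise ValueError(f"baseline window [{start}, {stop}) contains no samples")
    baseline = stream.data[mask].mean(axis=0)
    return replace(stream, data=stream.data - baseline), baseline


def lowpass_decimate(
    stream: RawVoltageStream,
    cutoff_hz: float = 40.0,
    out_fs_hz: float = 100.0,
    order: int = 2,
    zero_phase: bool = False,
    baseline: np.ndarray | None = None,
) -> ProcessedStream:
    """Low-pass filter each channel and keep every (fs/out_fs)-th sample.

    The decimation ratio must be an integer and the cutoff must lie below
    the output Nyquist frequency (anti-aliasing).  The causal filter has
    unit DC gain; ``zero_phase`` switches to forward-backward filtering for
    offline analysis at the cost of non-causality.
    """
    ratio = stream.fs_hz / out_fs_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"fs_in/fs_out = {ratio} is not an integer decimation ratio")
    ratio = int(round(ratio))
    if not 0 < cutoff_hz < out_fs_hz / 2:
        raise ValueError("cutoff must lie in (0, out_fs/2) to prevent aliasing")

    sos = signal.butter(order, cutoff_hz, btype="low", fs=stream.fs_hz, output="sos")
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, stream.data, axis=0)
    else:
        filtered = signal.sosfilt(sos, stream.data, axis=0)

    n_out = stream.n_samples // ratio
    kept = filtered[: n_out * ratio : ratio]
    return ProcessedStream(data=kept, fs_hz=out_fs_hz, t0=stream.t0, baseline=baseline)
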