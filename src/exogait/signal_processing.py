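"""Filtering and rate harmonization for multi-rate sensor comparisons.

The validation protocol compares recordings made at different rates
(wearable system 130 Hz, motion capture 150 Hz, force plate 1500 Hz):
each stream is low-pass filtered with a Butterworth filter and the faster
streams are downsampled onto the slowest stream's time grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["FilterSpec", "butterworth_filter", "downsample_to"]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass filter parameters.

    ``zero_phase`` selects forward–backward filtering (``filtfilt``), which
    leaves event timing unshifted at the cost of doubling the effective
    order; single-pass filtering preserves the analytic magnitude response
    of the stated order.
    """

    order: int = 2
    cutoff_hz: float = 10.0
    kind: str = "lowpass"
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"order must be a positive integer, got {self.order}")
        if self.cutoff_hz <= 0:
            raise ValueError(f"cutoff_hz must be positive, got {self.cutoff_hz}")
        if self.kind != "lowpass":
            raise ValueError(f"unsupported filter kind {self.kind!r}")


def butterworth_filter(signal, rate: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Low-pass a uniformly sampled series, preserving its length.

    Raises a ``ValueError`` if the cutoff is at or above the Nyquist
    frequency or the series is too short for the filter order.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    nyquist = rate / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist ({nyquist} Hz)"
        )
    if x.size <= 3 * spec.order:
        raise ValueError(
            f"series length {x.size} too short for order-{spec.order} filter"
        )
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=rate, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def downsample_to(
    timestamps,
    values,
    target_timestamps,
    *,
    antialias: bool = True,
    antialias_order: int = 4,
) -> np.ndarray:
    """Resample a timestamped series onto a target time grid.

    An anti-alias Butterworth low-pass at 0.4x the target rate is applied
    first (when the source is actually faster than the target), then values
    are linearly interpolated at the target timestamps.  Requests outside
    the source time span raise a ``ValueError`` rather than extrapolating.
    """
    t = np.asarray(timestamps, dtype=float)
    x = np.asarray(values, dtype=float)
    tt = np.asarray(target_timestamps, dtype=float)
    if t.shape != x.shape:
        raise ValueError("timestamps and values must have the same shape")
    if t.size < 2:
        raise ValueError("need at least two source samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("source timestamps must strictly increase")
    if tt.min() < t[0] or tt.max() > t[-1]:
        raise ValueError(
            f"target range [{tt.min()}, {tt.max()}] exceeds source span "
            f"[{t[0]}, {t[-1]}]"
        )
    source_rate = 1.0 / np.median(np.diff(t))
    target_rate = 1.0 / np.median(np.diff(tt)) if tt.size > 1 else source_rate
    if antialias and target_rate < source_rate:
        cutoff = 0.4 * target_rate
        if cutoff < source_rate / 2.0 and x.size > 3 * antialias_order:
            spec = FilterSpec(order=antialias_order, cutoff_hz=cutoff, zero_phase=True)
            x = butterworth_filter(x, source_rate, spec)
    return np.interp(tt, t, x)
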