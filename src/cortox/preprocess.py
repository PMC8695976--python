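"""Event-series resampling and Hanning-window filtering.

Beat- and breath-resolved records are unevenly sampled; the modelling
stage needs contemporaneous, evenly sampled, band-limited signals.
The chain applied to every channel is:

1. cubic-spline interpolation onto a shared 0.25-s grid (not-a-knot
   boundary conditions);
2. high-pass: subtraction of a 2-min moving-average Hanning window,
   removing the baseline and content below ~0.01 Hz;
3. low-pass: an 8-s Hanning moving average, suppressing respiratory
   sinus arrhythmia and content above ~0.2 Hz.

Both filters are zero-phase symmetric FIR moving averages with unit DC
gain; edges are handled by reflect-padding half a window on each side
so no samples are lost from the short 5-min records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .exceptions import (
    ConfigurationError,
    InsufficientDataError,
    RangeError,
    SchemaError,
)
from .signals import EventSeries, UniformSignal

__all__ = [
    "FilterSpec",
    "resample_spline",
    "hann_window",
    "hann_smooth",
    "hann_highpass",
    "preprocess_subject",
]

CHANNELS = ("abp", "co2", "cfv", "toi")


@dataclass(frozen=True)
class FilterSpec:
    """Preprocessing settings: grid spacing and the two window lengths."""

    dt: float = 0.25
    highpass_window_s: float = 120.0
    lowpass_window_s: float = 8.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        for w in (self.highpass_window_s, self.lowpass_window_s):
            if w < 2 * self.dt:
                raise ConfigurationError("window must cover at least 2 samples")
        if self.highpass_window_s <= self.lowpass_window_s:
            raise ConfigurationError("high-pass window must exceed low-pass window")


def resample_spline(events: EventSeries, dt: float,
                    t_start: float, t_end: float) -> UniformSignal:
    """Cubic-spline interpolation of an event series onto a uniform grid.

    The grid runs from t_start in steps of dt up to (and including)
    t_end.  No extrapolation: the grid must lie within the event span.
    """
    if len(events) < 4:
        raise InsufficientDataError(
            f"cubic spline needs >= 4 events, got {len(events)} ({events.channel!r})")
    lo, hi = events.span
    if t_start < lo - 1e-9 or t_end > hi + 1e-9:
        raise RangeError(
            f"grid [{t_start}, {t_end}] outside event span [{lo}, {hi}] "
            f"({events.channel!r})")
    if t_end < t_start:
        raise RangeError("t_end before t_start")
    n = int(np.floor((t_end - t_start) / dt + 1e-9)) + 1
    grid = t_start + dt * np.arange(n)
    spline = CubicSpline(events.times, events.values, bc_type="not-a-knot")
    return UniformSignal(t0=t_start, dt=dt, values=spline(grid),
                         units=events.units, state="resampled")


def hann_window(window_s: float, dt: float) -> np.ndarray:
    """Symmetric Hann weights over window_s seconds, normalized to sum 1.

    N = window_s/dt + 1 points: 481 for the 2-min window and 33 for the
    8-s window at dt = 0.25 s.
    """
    n = int(round(window_s / dt)) + 1
    if n < 3:
        raise ConfigurationError("window must cover at least 2 sample intervals")
    i = np.arange(n)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * i / (n - 1)))
    return w / w.sum()


def _moving_average(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted moving average with reflect padding; output length = input."""
    n = weights.size
    half = n // 2
    if values.size < n:
        raise InsufficientDataError(
            f"signal length {values.size} shorter than window {n}")
    padded = np.pad(values, (half, n - 1 - half), mode="reflect")
    return np.convolve(padded, weights, mode="valid")


def hann_smooth(signal: UniformSignal, window_s: float) -> UniformSignal:
    """Low-pass: Hann-weighted moving average (unit DC gain)."""
    weights = hann_window(window_s, signal.dt)
    return signal.with_values(_moving_average(signal.values, weights))


def hann_highpass(signal: UniformSignal, window_s: float = 120.0) -> UniformSignal:
    """High-pass: subtract the Hann moving average from the signal."""
    smooth = hann_smooth(signal, window_s)
    return signal.with_values(signal.values - smooth.values)


def shared_grid(subject_channels: dict, dt: float) -> tuple[float, float]:
    """Intersection of channel spans, snapped inward to multiples of dt."""
    starts, ends = [], []
    for ch in CHANNELS:
        if ch not in subject_channels:
            raise SchemaError(f"channel {ch!r} missing")
        lo, hi = subject_channels[ch].span
        starts.append(lo)
        ends.append(hi)
    t_start = np.ceil(max(starts) / dt - 1e-9) * dt
    t_end = np.floor(min(ends) / dt + 1e-9) * dt
    if t_end <= t_start:
        raise RangeError("channel spans do not overlap")
    return float(t_start), float(t_end)


def preprocess_subject(subject, spec: FilterSpec = FilterSpec()) -> dict[str, UniformSignal]:
    """Resample and filter all four channels of one subject.

    ``subject`` is anything with a ``channels`` mapping of
    ``{"abp", "co2", "cfv", "toi"} -> EventSeries`` (a SubjectRecord),
    or such a mapping itself.  Returns filtered, zero-mean signals on
    one shared grid, keyed by channel.

    The final step removes the residual sample mean left by the
    high-pass edge padding, so a ``filtered`` signal is exactly
    baseline-free.
    """
    channels = getattr(subject, "channels", subject)
    t_start, t_end = shared_grid(channels, spec.dt)
    out: dict[str, UniformSignal] = {}
    for ch in CHANNELS:
        sig = resample_spline(channels[ch], spec.dt, t_start, t_end)
        sig = hann_highpass(sig, spec.highpass_window_s)
        sig = hann_smooth(sig, spec.lowpass_window_s)
        values = sig.values - sig.values.mean()
        out[ch] = sig.with_values(values, state="filtered")
    return out
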