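"""Signal containers.

Two containers cover everything the pipeline moves around:

``EventSeries``
    Irregularly timed ``(time, value)`` records for one physiological
    channel — beat-averaged arterial pressure (mmHg), beat-averaged
    cerebral flow velocity (cm/s), beat-averaged tissue oxygenation
    index (%), or breath-timed end-tidal CO2 (mmHg).

``UniformSignal``
    An evenly sampled signal (default resampling interval 0.25 s), the
    form all modelling operates on.  The ``state`` flag tracks where a
    signal sits in the preprocessing chain: ``raw`` → ``resampled`` →
    ``filtered``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ShapeError

__all__ = ["EventSeries", "UniformSignal"]


@dataclass(frozen=True)
class EventSeries:
    """Irregularly sampled (time, value) records for one channel."""

    times: np.ndarray
    values: np.ndarray
    channel: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise ShapeError("times and values must be 1-D arrays of equal length")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ShapeError(f"event times must be strictly increasing ({self.channel!r})")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(values))):
            raise ShapeError(f"non-finite event data ({self.channel!r})")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) event time in seconds."""
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class UniformSignal:
    """Evenly sampled signal: ``values[i]`` is taken at ``t0 + i*dt``."""

    t0: float
    dt: float
    values: np.ndarray
    units: str = ""
    state: str = "raw"  # raw | resampled | filtered

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ShapeError("dt must be positive")
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ShapeError("values must be 1-D")
        if not np.all(np.isfinite(values)):
            raise ShapeError("non-finite signal values")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    def with_values(self, values: np.ndarray, state: str | None = None) -> "UniformSignal":
        """Copy of this signal with new samples (same grid)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       state=self.state if state is None else state)


def as_values(signal) -> np.ndarray:
    """Accept a UniformSignal or a bare array; return the sample array."""
    if isinstance(signal, UniformSignal):
        return signal.values
    return np.asarray(signal, dtype=float)


def common_dt(*signals, dt: float | None = None) -> float:
    """Infer the shared sampling interval from UniformSignal arguments.

    Raises ShapeError on a mismatch; falls back to the explicit ``dt``
    when only bare arrays are supplied.
    """
    found = None
    for s in signals:
        if isinstance(s, UniformSignal):
            if found is None:
                found = s.dt
            elif abs(s.dt - found) > 1e-12:
                raise ShapeError(f"sampling intervals differ: {found} vs {s.dt}")
    if found is not None:
        if dt is not None and abs(dt - found) > 1e-12:
            raise ShapeError(f"explicit dt {dt} conflicts with signal dt {found}")
        return found
    if dt is None:
        raise ShapeError("dt must be given when inputs are bare arrays")
    return dt
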