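"""Model-based physio-markers derived from estimated kernels.

Each fitted subject model is probed with a unit-step input on one
channel (the other two held at zero) and the predicted tissue
oxygenation response is averaged over a 50-s horizon.  The three
resulting indices are:

- **CCR** (cortical CO2 reactivity): TOI % per mmHg step of end-tidal
  CO2;
- **CTP** (cortical tissue perfusivity): TOI % per cm/s step of
  cerebral flow velocity;
- **CAP** (cortical autoregulation to pressure): TOI % per mmHg step
  of arterial pressure.

For a linear convolution model the unit-step response is simply the
cumulative sum of the kernel, so the indices are linear functionals of
the kernels.  The frequency-domain view (gain functions) and
group-average kernel summaries live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, InsufficientDataError, SchemaError
from .lek import ModelFit

__all__ = [
    "StepResponse",
    "MarkerSet",
    "GainFunction",
    "step_response",
    "index_from_step",
    "compute_markers",
    "gain_function",
    "aggregate_kernels",
]

DEFAULT_HORIZON_S = 50.0


@dataclass(frozen=True)
class StepResponse:
    """Predicted output response to a unit-step input, per sample."""

    dt: float
    values: np.ndarray
    input_label: str = ""

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.values.size)


@dataclass(frozen=True)
class MarkerSet:
    """Per-subject physio-markers (plus prediction NMSE)."""

    subject_id: str
    group: str
    ccr: float
    ctp: float
    cap: float
    nmse: float

    def as_dict(self) -> dict:
        return {"subject_id": self.subject_id, "group": self.group,
                "ccr": self.ccr, "ctp": self.ctp, "cap": self.cap,
                "nmse": self.nmse}

    def feature(self, name: str) -> float:
        try:
            return getattr(self, name)
        except AttributeError:
            raise SchemaError(f"unknown marker feature {name!r}") from None


@dataclass(frozen=True)
class GainFunction:
    """|H(f)| of a kernel on a frequency grid spanning (0, Nyquist]."""

    frequencies_hz: np.ndarray
    magnitude: np.ndarray
    input_label: str = ""


def step_response(kernel: np.ndarray, dt: float,
                  horizon_s: float = DEFAULT_HORIZON_S,
                  input_label: str = "") -> StepResponse:
    """Unit-step response of a kernel, truncated at the horizon.

    s(n) = sum_{m<=n} k(m): the discrete convolution of the kernel
    with a unit step (input = 1 for all n >= 0, no dt scaling), so the
    response is per 1 physical unit of the input.
    """
    kernel = np.asarray(kernel, dtype=float)
    n50 = int(round(horizon_s / dt))
    if n50 < 1:
        raise ConfigurationError("horizon shorter than one sample")
    if kernel.size < n50:
        raise ConfigurationError(
            f"kernel has {kernel.size} lags, needs >= {n50} for a "
            f"{horizon_s}-s horizon")
    return StepResponse(dt=dt, values=np.cumsum(kernel[:n50]),
                        input_label=input_label)


def index_from_step(step: StepResponse) -> float:
    """Time-average of the step response over its horizon."""
    if step.values.size == 0:
        raise InsufficientDataError("empty step response")
    return float(step.values.mean())


def compute_markers(fit: ModelFit, subject_id: str = "", group: str = "",
                    horizon_s: float = DEFAULT_HORIZON_S) -> MarkerSet:
    """CCR/CTP/CAP from a fitted model's kernels plus its NMSE."""
    k = fit.kernels

    def idx(kernel, label):
        return index_from_step(step_response(kernel, k.dt, horizon_s, label))

    return MarkerSet(
        subject_id=subject_id,
        group=group,
        ccr=idx(k.k_co2, "co2"),
        ctp=idx(k.k_cfv, "cfv"),
        cap=idx(k.k_abp, "abp"),
        nmse=fit.nmse_pct,
    )


def gain_function(kernel: np.ndarray, dt: float, n_fft: int = 2048,
                  input_label: str = "") -> GainFunction:
    """Gain function |H(f)|: magnitude of the kernel's DFT.

    The kernel is zero-padded to n_fft; frequencies run from 0 to the
    Nyquist frequency 1/(2 dt).
    """
    kernel = np.asarray(kernel, dtype=float)
    if n_fft < kernel.size:
        raise ConfigurationError(f"n_fft={n_fft} < kernel length {kernel.size}")
    spectrum = np.fft.rfft(kernel, n=n_fft)
    freqs = np.fft.rfftfreq(n_fft, d=dt)
    return GainFunction(frequencies_hz=freqs, magnitude=np.abs(spectrum),
                        input_label=input_label)


def aggregate_kernels(kernels, labels) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Lag-wise mean and sample SD of kernels, per group label.

    ``kernels`` is a sequence of equal-length lag arrays; ``labels``
    the matching group labels.  Groups need >= 2 members for a sample
    SD.
    """
    kernels = [np.asarray(k, dtype=float) for k in kernels]
    labels = list(labels)
    if len(kernels) != len(labels):
        raise SchemaError("kernels and labels length mismatch")
    out = {}
    for g in dict.fromkeys(labels):  # preserve first-seen order
        stack = np.vstack([k for k, lab in zip(kernels, labels) if lab == g])
        if stack.shape[0] < 2:
            raise InsufficientDataError(f"group {g!r} has < 2 subjects")
        out[g] = (stack.mean(axis=0), stack.std(axis=0, ddof=1))
    return out
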