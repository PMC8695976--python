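"""Three-input linear convolution model estimated by Laguerre expansion.

The model relates beat-resolved arterial blood pressure ``p(n)``,
end-tidal CO2 ``x(n)`` and cerebral flow velocity ``z(n)`` to the
tissue oxygenation index ``y(n)`` through one discrete convolution per
input::

    y(n) = k0 + sum_m k_p(m) p(n-m) + sum_m k_x(m) x(n-m)
              + sum_m k_z(m) z(n-m)

The kernels ``k_p, k_x, k_z`` (impulse-response functions) fully
characterise the linear dynamics.  Estimating M+1 free lag weights per
input directly is hopeless on five-minute records, so each kernel is
expanded on a small set of discrete Laguerre functions (DLFs) — an
orthonormal, exponentially decaying basis with a single shape
parameter ``alpha`` in (0, 1) controlling the decay time.  With L
functions per input the regression has only 3L+1 free parameters,
estimated by ordinary least squares on the filtered time series.

The DLFs used here are the impulse responses of the standard Laguerre
filter cascade: a first-order low-pass with pole sqrt(alpha) followed
by repeated all-pass sections, so that

    b_0(n) = sqrt(1 - alpha) * alpha**(n/2)

and the family is orthonormal over n = 0..inf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .exceptions import (
    ConfigurationError,
    DegenerateStatisticError,
    IllConditionedError,
    InsufficientDataError,
    ShapeError,
)
from .signals import UniformSignal, as_values, common_dt

__all__ = [
    "LaguerreBasis",
    "KernelSet",
    "ModelCoefficients",
    "ModelFit",
    "dlf_basis",
    "basis_convolve",
    "fit_three_input",
    "predict",
    "nmse",
    "select_alpha",
]

#: canonical input ordering used throughout the package
INPUT_ORDER = ("abp", "co2", "cfv")

CONDITION_WARN_THRESHOLD = 1e8


@dataclass(frozen=True)
class LaguerreBasis:
    """Discrete Laguerre functions b_j(m), j = 0..L-1, m = 0..M.

    ``B`` has shape (M+1, L); column j holds b_j evaluated on the lag
    grid.  Orthonormality over 0..inf holds to the extent that M*dt
    covers the basis decay time (checked in tests, not enforced here).
    """

    alpha: float
    L: int
    M: int
    B: np.ndarray

    def reconstruct(self, coeffs: np.ndarray) -> np.ndarray:
        """Kernel on lags 0..M from expansion coefficients."""
        return self.B @ np.asarray(coeffs, dtype=float)


@dataclass(frozen=True)
class KernelSet:
    """Estimated (or ground-truth) kernels of the three-input model.

    Units: k_abp in TOI% per mmHg, k_co2 in TOI% per mmHg, k_cfv in
    TOI% per (cm/s); k0 in TOI%.  Lag arrays cover 0..M at spacing dt.
    """

    dt: float
    k0: float
    k_abp: np.ndarray
    k_co2: np.ndarray
    k_cfv: np.ndarray

    def __post_init__(self) -> None:
        for name in ("k_abp", "k_co2", "k_cfv"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ShapeError(f"non-finite kernel {name}")
            object.__setattr__(self, name, arr)
        if not np.isfinite(self.k0):
            raise ShapeError("non-finite k0")

    def kernel(self, input_name: str) -> np.ndarray:
        return {"abp": self.k_abp, "co2": self.k_co2, "cfv": self.k_cfv}[input_name]

    @property
    def lags_s(self) -> np.ndarray:
        return self.dt * np.arange(self.k_abp.size)

    def to_dict(self) -> dict:
        return {
            "dt": self.dt,
            "k0": float(self.k0),
            "k_abp": self.k_abp.tolist(),
            "k_co2": self.k_co2.tolist(),
            "k_cfv": self.k_cfv.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSet":
        return cls(dt=d["dt"], k0=d["k0"],
                   k_abp=np.asarray(d["k_abp"]),
                   k_co2=np.asarray(d["k_co2"]),
                   k_cfv=np.asarray(d["k_cfv"]))


@dataclass(frozen=True)
class ModelCoefficients:
    """Expansion coefficients: k0 plus c[input][j] for each input."""

    k0: float
    c_abp: np.ndarray
    c_co2: np.ndarray
    c_cfv: np.ndarray

    def coeffs(self, input_name: str) -> np.ndarray:
        return {"abp": self.c_abp, "co2": self.c_co2, "cfv": self.c_cfv}[input_name]


@dataclass(frozen=True)
class ModelFit:
    """Result of one subject-level model estimation."""

    bases: tuple[LaguerreBasis, LaguerreBasis, LaguerreBasis]
    coefficients: ModelCoefficients
    kernels: KernelSet
    nmse_pct: float
    n_samples: int
    condition_number: float

    @property
    def alpha(self) -> tuple[float, float, float]:
        return tuple(b.alpha for b in self.bases)


def dlf_basis(alpha: float, L: int, M: int) -> LaguerreBasis:
    """Construct the discrete Laguerre basis on lags 0..M.

    b_0 is the impulse response of sqrt(1-alpha)/(1 - sqrt(alpha) z^-1);
    each subsequent function applies the all-pass section
    (z^-1 - sqrt(alpha))/(1 - sqrt(alpha) z^-1).  This two-term
    recursion is numerically stable for all alpha in (0, 1).
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if L < 1:
        raise ConfigurationError("order L must be >= 1")
    if M + 1 < L:
        raise ConfigurationError("need at least as many lags (M+1) as functions L")
    a = np.sqrt(alpha)
    impulse = np.zeros(M + 1)
    impulse[0] = 1.0
    col = lfilter([np.sqrt(1.0 - alpha)], [1.0, -a], impulse)
    cols = [col]
    for _ in range(1, L):
        col = lfilter([-a, 1.0], [1.0, -a], col)
        cols.append(col)
    return LaguerreBasis(alpha=alpha, L=L, M=M, B=np.column_stack(cols))


def basis_convolve(signal, basis: LaguerreBasis) -> np.ndarray:
    """Regressor matrix V with V[n, j] = sum_m b_j(m) * input(n-m).

    The input is taken as zero before its first sample; rows are
    aligned with output samples (the caller discards the first M
    transient rows when fitting).
    """
    x = as_values(signal)
    if x.size <= basis.M:
        raise InsufficientDataError(
            f"input length {x.size} must exceed basis memory M={basis.M}")
    cols = [lfilter(basis.B[:, j], [1.0], x) for j in range(basis.L)]
    return np.column_stack(cols)


def _as_bases(bases) -> tuple[LaguerreBasis, LaguerreBasis, LaguerreBasis]:
    if isinstance(bases, LaguerreBasis):
        return (bases, bases, bases)
    bases = tuple(bases)
    if len(bases) != 3:
        raise ConfigurationError("need one basis or a basis per input (3)")
    return bases


def fit_three_input(p, x, z, y, bases, dt: float | None = None) -> ModelFit:
    """Least-squares fit of the three-input convolution model.

    Parameters
    ----------
    p, x, z, y
        Arterial pressure, end-tidal CO2, flow velocity inputs and the
        tissue-oxygenation output, as UniformSignal or plain arrays of
        equal length (filtered, contemporaneous).
    bases
        A single LaguerreBasis shared by the three inputs, or a
        3-tuple of bases (ABP, CO2, CFV order).
    dt
        Required only when all four signals are bare arrays.

    The regression runs on samples n = M..N-1 (M = largest basis
    memory), excluding the initial transient where the convolution
    would implicitly zero-pad unknown pre-record inputs.  The
    prediction NMSE is scored on that same range.
    """
    bases = _as_bases(bases)
    dt = common_dt(p, x, z, y, dt=dt)
    arrays = [as_values(s) for s in (p, x, z)]
    yv = as_values(y)
    n = yv.size
    if any(a.size != n for a in arrays):
        raise ShapeError("input/output lengths differ")
    M = max(b.M for b in bases)
    n_params = 1 + sum(b.L for b in bases)
    if n - M < 2 * n_params:
        raise InsufficientDataError(
            f"{n} samples with memory {M} leave too few rows for "
            f"{n_params} parameters")

    regressors = [basis_convolve(a, b) for a, b in zip(arrays, bases)]
    design = np.column_stack([np.ones(n)] + regressors)[M:]
    target = yv[M:]

    cond = np.linalg.cond(design)
    coef, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < design.shape[1]:
        raise IllConditionedError(
            f"rank-deficient design matrix (rank {rank} < {design.shape[1]}, "
            f"condition number {cond:.3g})")
    if cond > CONDITION_WARN_THRESHOLD:
        warnings.warn(f"ill-conditioned regression (cond={cond:.3g})",
                      RuntimeWarning, stacklevel=2)

    k0 = float(coef[0])
    splits = np.cumsum([1] + [b.L for b in bases])
    c_abp, c_co2, c_cfv = (coef[splits[i]:splits[i + 1]] for i in range(3))
    kernels = KernelSet(
        dt=dt, k0=k0,
        k_abp=bases[0].reconstruct(c_abp),
        k_co2=bases[1].reconstruct(c_co2),
        k_cfv=bases[2].reconstruct(c_cfv),
    )
    y_hat = design @ coef
    if np.ptp(target) == 0.0:
        # constant output: NMSE is 0 iff the (trivial) fit is exact
        ss_res = float(np.sum((target - y_hat) ** 2))
        if ss_res > 1e-18 * max(1.0, float(target @ target)):
            raise DegenerateStatisticError(
                "constant output imperfectly fitted; NMSE undefined")
        fit_nmse = 0.0
    else:
        fit_nmse = nmse(target, y_hat)
    return ModelFit(
        bases=bases,
        coefficients=ModelCoefficients(k0=k0, c_abp=c_abp, c_co2=c_co2, c_cfv=c_cfv),
        kernels=kernels,
        nmse_pct=fit_nmse,
        n_samples=target.size,
        condition_number=float(cond),
    )


def predict(fit: ModelFit | KernelSet, p, x, z, dt: float | None = None) -> UniformSignal:
    """Model-predicted output for arbitrary input waveforms.

    Inputs before the record start are taken as zero, so the first
    ~M samples carry a startup transient.  Deterministic and linear in
    the inputs (minus the constant k0).
    """
    kernels = fit.kernels if isinstance(fit, ModelFit) else fit
    dt = common_dt(p, x, z, dt=dt if dt is not None else kernels.dt)
    if abs(dt - kernels.dt) > 1e-12:
        raise ConfigurationError(f"input dt {dt} != kernel dt {kernels.dt}")
    arrays = [as_values(s) for s in (p, x, z)]
    if len({a.size for a in arrays}) != 1:
        raise ShapeError("input lengths differ")
    yv = np.full(arrays[0].size, kernels.k0)
    for a, name in zip(arrays, INPUT_ORDER):
        yv = yv + lfilter(kernels.kernel(name), [1.0], a)
    t0 = p.t0 if isinstance(p, UniformSignal) else 0.0
    return UniformSignal(t0=t0, dt=dt, values=yv, units="%", state="filtered")


def nmse(y, y_hat) -> float:
    """Normalized mean-square prediction error, in percent.

    100 * sum((y - y_hat)^2) / sum((y - mean(y))^2); 0 for a perfect
    prediction, 100 for predicting the mean.
    """
    yv = as_values(y)
    hv = as_values(y_hat)
    if yv.size != hv.size:
        raise ShapeError("length mismatch")
    if yv.size < 2:
        raise InsufficientDataError("need at least 2 samples")
    denom = float(np.sum((yv - yv.mean()) ** 2))
    if denom == 0.0:
        raise DegenerateStatisticError("output has zero variance; NMSE undefined")
    return 100.0 * float(np.sum((yv - hv) ** 2)) / denom


def select_alpha(p, x, z, y, alpha_grid, L: int, M: int,
                 dt: float | None = None) -> tuple[float, ModelFit]:
    """Grid search for the Laguerre decay parameter.

    Fits the model at every grid point (same alpha for all three
    inputs) and returns the point minimizing in-sample prediction
    NMSE.  Ties break toward the smaller alpha (grid is sorted
    ascending internally), so the result is deterministic.
    """
    grid = sorted(float(a) for a in np.atleast_1d(np.asarray(alpha_grid, dtype=float)))
    if not grid:
        raise ConfigurationError("alpha grid is empty")
    if not all(0.0 < a < 1.0 for a in grid):
        raise ConfigurationError("alpha grid values must lie in (0, 1)")
    best_alpha, best_fit = None, None
    for alpha in grid:
        fit = fit_three_input(p, x, z, y, dlf_basis(alpha, L, M), dt=dt)
        if best_fit is None or fit.nmse_pct < best_fit.nmse_pct:
            best_alpha, best_fit = alpha, fit
    return best_alpha, best_fit
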