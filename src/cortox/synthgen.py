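"""Synthetic cohort generator with known ground truth.

The study data this pipeline is designed for (five-minute resting
recordings of beat-averaged arterial pressure, beat-averaged cerebral
flow velocity, beat-averaged tissue oxygenation index and breath-timed
end-tidal CO2, from a control group and a mild-cognitive-impairment
group) are not publicly deposited.  This module emulates such a cohort
with fully known ground truth so that every downstream stage —
resampling, filtering, kernel estimation, marker computation, group
statistics — is testable end to end:

- spontaneous fluctuations are band-limited Gaussian processes
  (0.01–0.15 Hz by default, where slow hemodynamic regulation lives);
- the oxygenation output is produced by the same three-input linear
  convolution model the estimator assumes, using group-specific
  ground-truth kernels built from difference-of-gamma templates
  (controls: positive early + positive slow CO2 response; patients:
  negative early CO2 response with a small late rebound, and roughly
  halved flow-velocity coupling);
- white Gaussian output noise is scaled in closed form so the
  noiseless model's prediction NMSE on the noisy record hits the
  configured per-group target exactly;
- heart beats (~0.9 s) and breaths (~4 s) are i.i.d. truncated-Gaussian
  renewal processes; channels are read off the latent uniform signals
  at those event times.

Everything is a pure function of the configuration, including its
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .exceptions import ConfigurationError, SchemaError, ShapeError
from .lek import INPUT_ORDER, KernelSet
from .signals import EventSeries, UniformSignal, as_values

__all__ = [
    "GammaComponent",
    "KernelTemplate",
    "GroupSpec",
    "SynthConfig",
    "SubjectRecord",
    "default_kernel_templates",
    "default_config",
    "make_latent_input",
    "synthesize_output",
    "sample_events",
    "make_cohort",
    "write_cohort",
    "read_cohort",
]

#: group labels used throughout
CONTROL, PATIENT = "control", "patient"

#: channels and their units
CHANNEL_UNITS = {"abp": "mmHg", "co2": "mmHg", "cfv": "cm/s", "toi": "%"}

#: which latent input drives which kernel
INPUT_CHANNELS = ("abp", "co2", "cfv")


# --------------------------------------------------------------------------
# ground-truth kernel templates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaComponent:
    """One gamma-like lobe of a lagged response curve.

    ``amplitude`` carries the sign and peak height (output units per
    input unit); ``peak_s`` the lag of the maximum; ``width_s``
    controls the lobe's spread (smaller = sharper).
    """

    amplitude: float
    peak_s: float
    width_s: float

    def evaluate(self, lags_s: np.ndarray) -> np.ndarray:
        if self.peak_s <= 0 or self.width_s <= 0:
            raise ConfigurationError("peak and width must be positive")
        shape = (self.peak_s / self.width_s) ** 2
        t = np.asarray(lags_s, dtype=float)
        out = np.zeros_like(t)
        pos = t > 0
        r = t[pos] / self.peak_s
        out[pos] = np.exp(shape * (np.log(r) + 1.0 - r))
        return self.amplitude * out


@dataclass(frozen=True)
class KernelTemplate:
    """Ground-truth kernel as a sum of one or two gamma-like lobes."""

    components: tuple[GammaComponent, ...]

    def evaluate(self, lags_s: np.ndarray) -> np.ndarray:
        lags_s = np.asarray(lags_s, dtype=float)
        total = np.zeros_like(lags_s)
        for c in self.components:
            total += c.evaluate(lags_s)
        return total

    def step_average(self, horizon_s: float = 50.0, dt: float = 0.25) -> float:
        """Time-average of the unit-step response over the horizon.

        This is exactly the physio-marker the pipeline computes from an
        estimated kernel, evaluated on the true template.
        """
        n50 = int(round(horizon_s / dt))
        k = self.evaluate(dt * np.arange(n50))
        return float(np.cumsum(k).mean())

    def scaled(self, factor: float) -> "KernelTemplate":
        return KernelTemplate(tuple(
            replace(c, amplitude=c.amplitude * factor) for c in self.components))

    def scaled_to_step_average(self, target: float, horizon_s: float = 50.0,
                               dt: float = 0.25) -> "KernelTemplate":
        base = self.step_average(horizon_s, dt)
        if base == 0.0:
            raise ConfigurationError("template has zero step average; cannot scale")
        return self.scaled(target / base)

    def to_dict(self) -> dict:
        return {"components": [[c.amplitude, c.peak_s, c.width_s]
                               for c in self.components]}

    @classmethod
    def from_dict(cls, d: dict) -> "KernelTemplate":
        return cls(tuple(GammaComponent(*row) for row in d["components"]))


# Step-average targets the default templates are scaled to: the group
# means of the CCR / CTP / CAP indices under study conditions
# (TOI % per unit step of CO2 mmHg, CFV cm/s, ABP mmHg).
CONTROL_INDEX_TARGETS = {"co2": 0.144, "cfv": 0.184, "abp": -0.022}
PATIENT_INDEX_TARGETS = {"co2": -0.059, "cfv": 0.085, "abp": -0.029}


def default_kernel_templates() -> dict[str, dict[str, KernelTemplate]]:
    """Group-specific ground-truth kernel shapes.

    Controls' CO2 kernel: large positive early lobe (< 4 s) plus a
    positive slow lobe peaking near 20 s.  Patients' CO2 kernel:
    negative early lobe (< 8 s) with a small positive late rebound.
    Flow-velocity kernels share one shape, with the patient amplitude
    roughly halved; pressure kernels are small, net-negative, and
    nearly identical between groups.  Each template is scaled so its
    50-s step average equals the group's index target.
    """
    shapes = {
        CONTROL: {
            "co2": KernelTemplate((GammaComponent(1.0, 2.0, 1.5),
                                   GammaComponent(1.3, 20.0, 6.0))),
            "cfv": KernelTemplate((GammaComponent(1.0, 4.0, 3.0),
                                   GammaComponent(0.5, 15.0, 6.0))),
            "abp": KernelTemplate((GammaComponent(-1.0, 5.0, 4.0),
                                   GammaComponent(0.3, 15.0, 6.0))),
        },
        PATIENT: {
            "co2": KernelTemplate((GammaComponent(-1.0, 3.0, 2.5),
                                   GammaComponent(0.35, 25.0, 6.0))),
            "cfv": KernelTemplate((GammaComponent(1.0, 4.0, 3.0),
                                   GammaComponent(0.5, 15.0, 6.0))),
            "abp": KernelTemplate((GammaComponent(-1.0, 5.0, 4.0),
                                   GammaComponent(0.3, 15.0, 6.0))),
        },
    }
    targets = {CONTROL: CONTROL_INDEX_TARGETS, PATIENT: PATIENT_INDEX_TARGETS}
    return {
        group: {inp: shapes[group][inp].scaled_to_step_average(targets[group][inp])
                for inp in ("co2", "cfv", "abp")}
        for group in (CONTROL, PATIENT)
    }


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One group's size, ground-truth kernels, noise level, covariates.

    Covariate defaults (set in :func:`default_config`) follow the
    study cohort: 12 controls / 36 patients, control DLMR ~14 vs
    patient ~9, female proportions 5/12 vs 24/36, and the groups'
    channel baselines.
    """

    name: str
    n: int
    templates: Mapping[str, KernelTemplate]
    noise_nmse_pct: float
    age_mean: float
    age_sd: float
    female_prop: float
    mmse_mean: float
    mmse_sd: float
    dlmr_mean: float
    dlmr_sd: float
    baselines: Mapping[str, float]  # per-channel resting means

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigurationError("group size must be positive")
        if not (0.0 <= self.noise_nmse_pct < 100.0):
            raise ConfigurationError("noise NMSE must be in [0, 100)")
        if not (0.0 <= self.female_prop <= 1.0):
            raise ConfigurationError("female proportion must be in [0, 1]")
        for sd in (self.age_sd, self.mmse_sd, self.dlmr_sd):
            if sd < 0:
                raise ConfigurationError("covariate SDs must be >= 0")
        missing = set(CHANNEL_UNITS) - set(self.baselines)
        if missing:
            raise ConfigurationError(f"baselines missing for {sorted(missing)}")


@dataclass(frozen=True)
class SynthConfig:
    """Full specification of a synthetic cohort (seed included)."""

    control: GroupSpec
    patient: GroupSpec
    duration_s: float = 300.0
    dt: float = 0.25
    beat_interval_mean_s: float = 0.9
    beat_interval_sd_s: float = 0.05
    breath_interval_mean_s: float = 4.0
    breath_interval_sd_s: float = 0.5
    input_sds: Mapping[str, float] = field(
        default_factory=lambda: {"abp": 3.0, "co2": 1.5, "cfv": 3.0})
    band_lo_hz: float = 0.01
    band_hi_hz: float = 0.15
    noise_band_lo_hz: float = 0.01
    noise_band_hi_hz: float = 0.20
    kernel_jitter_sd: float = 0.30
    memory_lags: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.dt <= 0:
            raise ConfigurationError("duration and dt must be positive")
        for mean, sd in ((self.beat_interval_mean_s, self.beat_interval_sd_s),
                         (self.breath_interval_mean_s, self.breath_interval_sd_s)):
            if mean <= 0:
                raise ConfigurationError("event intervals must be positive")
            if mean <= 3.0 * sd:
                raise ConfigurationError(
                    "interval mean must exceed 3x its SD (keeps intervals positive)")
        if not (0.0 < self.band_lo_hz < self.band_hi_hz <= 0.5 / self.dt):
            raise ConfigurationError("need 0 < band_lo < band_hi <= Nyquist")
        if not (0.0 < self.noise_band_lo_hz < self.noise_band_hi_hz <= 0.5 / self.dt):
            raise ConfigurationError("need 0 < noise_band_lo < noise_band_hi <= Nyquist")
        if any(sd < 0 for sd in self.input_sds.values()):
            raise ConfigurationError("input SDs must be >= 0")
        if self.kernel_jitter_sd < 0:
            raise ConfigurationError("kernel jitter SD must be >= 0")

    @property
    def groups(self) -> tuple[GroupSpec, GroupSpec]:
        return (self.control, self.patient)

    def to_dict(self) -> dict:
        def group_dict(g: GroupSpec) -> dict:
            return {
                "name": g.name, "n": g.n,
                "templates": {k: t.to_dict() for k, t in g.templates.items()},
                "noise_nmse_pct": g.noise_nmse_pct,
                "age_mean": g.age_mean, "age_sd": g.age_sd,
                "female_prop": g.female_prop,
                "mmse_mean": g.mmse_mean, "mmse_sd": g.mmse_sd,
                "dlmr_mean": g.dlmr_mean, "dlmr_sd": g.dlmr_sd,
                "baselines": dict(g.baselines),
            }
        return {
            "control": group_dict(self.control),
            "patient": group_dict(self.patient),
            "duration_s": self.duration_s, "dt": self.dt,
            "beat_interval_mean_s": self.beat_interval_mean_s,
            "beat_interval_sd_s": self.beat_interval_sd_s,
            "breath_interval_mean_s": self.breath_interval_mean_s,
            "breath_interval_sd_s": self.breath_interval_sd_s,
            "input_sds": dict(self.input_sds),
            "band_lo_hz": self.band_lo_hz, "band_hi_hz": self.band_hi_hz,
            "noise_band_lo_hz": self.noise_band_lo_hz,
            "noise_band_hi_hz": self.noise_band_hi_hz,
            "kernel_jitter_sd": self.kernel_jitter_sd,
            "memory_lags": self.memory_lags,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        def group(gd: dict) -> GroupSpec:
            gd = dict(gd)
            gd["templates"] = {k: KernelTemplate.from_dict(t)
                               for k, t in gd["templates"].items()}
            return GroupSpec(**gd)
        d = dict(d)
        d["control"] = group(d["control"])
        d["patient"] = group(d["patient"])
        return cls(**d)


def default_config(n_controls: int = 12, n_patients: int = 36,
                   rng_seed: int = 0, **overrides) -> SynthConfig:
    """Cohort configuration mirroring the study conditions.

    12 controls and 36 patients by default; covariates, channel
    baselines and per-group output-noise NMSE targets (22.17% vs
    37.95%) follow the study's printed group summaries.
    """
    templates = default_kernel_templates()
    control = GroupSpec(
        name=CONTROL, n=n_controls, templates=templates[CONTROL],
        noise_nmse_pct=22.17,
        age_mean=68.80, age_sd=5.14, female_prop=5 / 12,
        mmse_mean=29.00, mmse_sd=0.95, dlmr_mean=14.17, dlmr_sd=1.85,
        baselines={"toi": 68.01, "cfv": 49.63, "co2": 35.10, "abp": 91.95},
    )
    patient = GroupSpec(
        name=PATIENT, n=n_patients, templates=templates[PATIENT],
        noise_nmse_pct=37.95,
        age_mean=66.19, age_sd=6.25, female_prop=24 / 36,
        mmse_mean=29.31, mmse_sd=0.83, dlmr_mean=8.86, dlmr_sd=2.31,
        baselines={"toi": 63.17, "cfv": 47.01, "co2": 35.88, "abp": 91.44},
    )
    return SynthConfig(control=control, patient=patient, rng_seed=rng_seed,
                       **overrides)


# --------------------------------------------------------------------------
# subjects
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectRecord:
    """One subject: four event-sampled channels plus covariates.

    ``truth`` holds the ground-truth kernels for synthetic subjects and
    is None for externally supplied data.
    """

    subject_id: str
    group: str
    channels: Mapping[str, EventSeries]
    covariates: Mapping[str, float]
    truth: KernelSet | None = None

    def __post_init__(self) -> None:
        missing = set(CHANNEL_UNITS) - set(self.channels)
        if missing:
            raise SchemaError(
                f"subject {self.subject_id!r} missing channels {sorted(missing)}")


# --------------------------------------------------------------------------
# generator primitives
# --------------------------------------------------------------------------

def make_latent_input(duration_s: float, dt: float, band_lo_hz: float,
                      band_hi_hz: float, sd: float,
                      rng: np.random.Generator) -> UniformSignal:
    """Zero-mean Gaussian signal band-limited to [band_lo, band_hi] Hz.

    Built by FFT masking of white noise, then rescaled so the sample
    SD equals ``sd`` exactly.  Guarantees the in-band power fraction
    by construction (all out-of-band Fourier coefficients are zeroed;
    only the tiny leakage from final mean-removal escapes the band).
    """
    nyquist = 0.5 / dt
    if not (0.0 < band_lo_hz < band_hi_hz <= nyquist + 1e-12):
        raise ConfigurationError(
            f"need 0 < band_lo < band_hi <= Nyquist ({nyquist} Hz)")
    n = int(round(duration_s / dt))
    if n < 2:
        raise ConfigurationError("duration too short")
    if sd < 0:
        raise ConfigurationError("sd must be >= 0")
    if sd == 0.0:
        return UniformSignal(t0=0.0, dt=dt, values=np.zeros(n))
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=dt)
    spectrum[(freqs < band_lo_hz) | (freqs > band_hi_hz)] = 0.0
    values = np.fft.irfft(spectrum, n=n)
    values -= values.mean()
    s = values.std()
    if s == 0.0:  # empty band after masking (degenerate n)
        raise ConfigurationError("band contains no Fourier frequencies")
    values *= sd / s
    return UniformSignal(t0=0.0, dt=dt, values=values)


def synthesize_output(inputs, kernels: KernelSet, noise_nmse_pct: float,
                      rng: np.random.Generator,
                      noise_band_hz: tuple[float, float] | None = None) -> UniformSignal:
    """Forward-simulate the three-input model and add calibrated noise.

    ``inputs`` is the (abp, co2, cfv) triple of UniformSignal/arrays.
    Gaussian noise is added at the output — white by default, or
    band-limited to ``noise_band_hz`` (the generator passes the
    analysis band so the configured NMSE level survives the band-pass
    preprocessing; purely white noise would be mostly removed by the
    8-s low-pass).  The noise scale is solved from a quadratic so that
    the noiseless model's prediction NMSE on the returned record
    equals ``noise_nmse_pct`` exactly (for the realized noise draw,
    not merely in expectation).
    """
    from scipy.signal import lfilter

    if not (0.0 <= noise_nmse_pct < 100.0):
        raise ConfigurationError("noise NMSE must be in [0, 100)")
    arrays = [as_values(s) for s in inputs]
    if len(arrays) != 3:
        raise ShapeError("expected three inputs (abp, co2, cfv)")
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ShapeError("input lengths differ")
    dt = kernels.dt
    for s in inputs:
        if isinstance(s, UniformSignal) and abs(s.dt - dt) > 1e-12:
            raise ShapeError("input dt differs from kernel dt")

    clean = np.full(n, kernels.k0)
    for a, name in zip(arrays, INPUT_ORDER):
        clean = clean + lfilter(kernels.kernel(name), [1.0], a)

    if noise_nmse_pct == 0.0:
        return UniformSignal(t0=0.0, dt=dt, values=clean, units="%")

    q = noise_nmse_pct / 100.0
    g = rng.standard_normal(n)
    if noise_band_hz is not None:
        lo, hi = noise_band_hz
        nyquist = 0.5 / dt
        if not (0.0 < lo < hi <= nyquist + 1e-12):
            raise ConfigurationError("noise band must satisfy 0 < lo < hi <= Nyquist")
        spectrum = np.fft.rfft(g)
        freqs = np.fft.rfftfreq(n, d=dt)
        spectrum[(freqs < lo) | (freqs > hi)] = 0.0
        g = np.fft.irfft(spectrum, n=n)
        if not np.any(g):
            raise ConfigurationError("noise band contains no Fourier frequencies")
    d = clean - clean.mean()
    c = g - g.mean()
    # NMSE(sigma) = sigma^2 g.g / ||d + sigma c||^2 = q, a quadratic in sigma
    a2 = g @ g - q * (c @ c)
    a1 = -2.0 * q * (d @ c)
    a0 = -q * (d @ d)
    if d @ d == 0.0:
        raise ConfigurationError(
            "noiseless output has zero variance; cannot calibrate noise")
    sigma = (-a1 + np.sqrt(a1 * a1 - 4.0 * a2 * a0)) / (2.0 * a2)
    return UniformSignal(t0=0.0, dt=dt, values=clean + sigma * g, units="%")


def sample_events(uniform: UniformSignal, mean_interval_s: float,
                  sd_interval_s: float, rng: np.random.Generator,
                  channel: str = "", units: str = "") -> EventSeries:
    """Read a uniform signal at renewal-process event times.

    Inter-event intervals are i.i.d. Gaussian truncated to positive
    values (the precondition mean > 3*SD makes truncation rare);
    values are linearly interpolated from the uniform signal.
    """
    if mean_interval_s <= 0 or sd_interval_s < 0:
        raise ConfigurationError("intervals must be positive, SD >= 0")
    if sd_interval_s > 0 and mean_interval_s <= 3.0 * sd_interval_s:
        raise ConfigurationError("interval mean must exceed 3x its SD")
    t_end = uniform.t0 + uniform.dt * (len(uniform) - 1)
    times = []
    t = uniform.t0
    floor = 0.1 * mean_interval_s
    while True:
        t = t + max(floor, rng.normal(mean_interval_s, sd_interval_s))
        if t > t_end:
            break
        times.append(t)
    times = np.asarray(times)
    values = np.interp(times, uniform.times, uniform.values)
    return EventSeries(times=times, values=values, channel=channel, units=units)


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

def _make_subject(subject_id: str, group: GroupSpec, config: SynthConfig,
                  rng: np.random.Generator) -> SubjectRecord:
    dt = config.dt
    lags = dt * np.arange(config.memory_lags + 1)

    # per-subject ground-truth kernels: template x multiplicative jitter
    true_kernels = {}
    for inp in INPUT_CHANNELS:
        factor = max(0.1, rng.normal(1.0, config.kernel_jitter_sd))
        true_kernels[inp] = group.templates[inp].scaled(factor).evaluate(lags)
    truth = KernelSet(dt=dt, k0=group.baselines["toi"],
                      k_abp=true_kernels["abp"], k_co2=true_kernels["co2"],
                      k_cfv=true_kernels["cfv"])

    latents = {
        inp: make_latent_input(config.duration_s, dt, config.band_lo_hz,
                               config.band_hi_hz, config.input_sds[inp], rng)
        for inp in INPUT_CHANNELS
    }
    toi = synthesize_output(
        (latents["abp"], latents["co2"], latents["cfv"]),
        truth, group.noise_nmse_pct, rng,
        noise_band_hz=(config.noise_band_lo_hz, config.noise_band_hi_hz))

    # one beat train shared by the beat-averaged channels, one breath train
    beat_probe = UniformSignal(t0=0.0, dt=dt,
                               values=np.zeros(int(round(config.duration_s / dt))))
    beats = sample_events(beat_probe, config.beat_interval_mean_s,
                          config.beat_interval_sd_s, rng).times
    breaths = sample_events(beat_probe, config.breath_interval_mean_s,
                            config.breath_interval_sd_s, rng).times

    def channel(name: str, latent: UniformSignal, times: np.ndarray) -> EventSeries:
        values = np.interp(times, latent.times,
                           latent.values + group.baselines[name]
                           if name != "toi" else latent.values)
        return EventSeries(times=times, values=values, channel=name,
                           units=CHANNEL_UNITS[name])

    channels = {
        "abp": channel("abp", latents["abp"], beats),
        "cfv": channel("cfv", latents["cfv"], beats),
        "toi": channel("toi", toi, beats),
        "co2": channel("co2", latents["co2"], breaths),
    }

    covariates = {
        "age": round(float(rng.normal(group.age_mean, group.age_sd)), 1),
        "gender": float(rng.random() < group.female_prop),  # 1 female, 0 male
        "mmse": float(np.clip(round(rng.normal(group.mmse_mean, group.mmse_sd)), 0, 30)),
        "dlmr": float(max(0.0, round(rng.normal(group.dlmr_mean, group.dlmr_sd)))),
    }
    return SubjectRecord(subject_id=subject_id, group=group.name,
                         channels=channels, covariates=covariates, truth=truth)


def make_cohort(config: SynthConfig) -> list[SubjectRecord]:
    """Generate the full cohort, reproducibly from config.rng_seed.

    Each subject draws from an independent child stream of the root
    seed, so the cohort is invariant to the order of generation.
    """
    root = np.random.SeedSequence(config.rng_seed)
    n_total = config.control.n + config.patient.n
    children = root.spawn(n_total)
    cohort = []
    i = 0
    for group in config.groups:
        prefix = "C" if group.name == CONTROL else "P"
        for j in range(group.n):
            rng = np.random.default_rng(children[i])
            cohort.append(_make_subject(f"{prefix}{j + 1:03d}", group, config, rng))
            i += 1
    return cohort


# --------------------------------------------------------------------------
# disk round-trip (delimited text only)
# --------------------------------------------------------------------------

def write_cohort(cohort: list[SubjectRecord], outdir, config: SynthConfig | None = None) -> None:
    """Write one time_s,value CSV per subject-channel plus a manifest.

    A sidecar ``truth.json`` stores the ground-truth kernels (and the
    generating configuration when given) for parameter-recovery tests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = ["subject_id,group,age,gender,mmse,dlmr"]
    truth = {"config": config.to_dict() if config is not None else None,
             "kernels": {}}
    for s in cohort:
        for name, series in s.channels.items():
            lines = ["time_s,value"] + [
                f"{t:.6f},{v:.8f}" for t, v in zip(series.times, series.values)]
            (outdir / f"{s.subject_id}_{name}.csv").write_text("\n".join(lines) + "\n")
        c = s.covariates
        manifest_rows.append(
            f"{s.subject_id},{s.group},{c['age']},{int(c['gender'])},"
            f"{int(c['mmse'])},{int(c['dlmr'])}")
        if s.truth is not None:
            truth["kernels"][s.subject_id] = s.truth.to_dict()
    (outdir / "manifest.csv").write_text("\n".join(manifest_rows) + "\n")
    (outdir / "truth.json").write_text(json.dumps(truth))


def read_cohort(indir) -> list[SubjectRecord]:
    """Load a cohort written by :func:`write_cohort` (or hand-made CSVs)."""
    indir = Path(indir)
    manifest_path = indir / "manifest.csv"
    if not manifest_path.exists():
        raise SchemaError(f"no manifest.csv in {indir}")
    truth_kernels = {}
    truth_path = indir / "truth.json"
    if truth_path.exists():
        truth_kernels = json.loads(truth_path.read_text()).get("kernels", {})
    cohort = []
    lines = manifest_path.read_text().strip().splitlines()
    for row in lines[1:]:
        sid, group, age, gender, mmse, dlmr = row.split(",")
        channels = {}
        for name in CHANNEL_UNITS:
            path = indir / f"{sid}_{name}.csv"
            if not path.exists():
                raise SchemaError(f"subject {sid!r}: channel file missing ({name})")
            data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
            channels[name] = EventSeries(times=data[:, 0], values=data[:, 1],
                                         channel=name, units=CHANNEL_UNITS[name])
        truth = (KernelSet.from_dict(truth_kernels[sid])
                 if sid in truth_kernels else None)
        cohort.append(SubjectRecord(
            subject_id=sid, group=group, channels=channels,
            covariates={"age": float(age), "gender": float(gender),
                        "mmse": float(mmse), "dlmr": float(dlmr)},
            truth=truth))
    return cohort
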