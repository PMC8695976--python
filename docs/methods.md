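# Methods

## Model

Each subject's cortical tissue oxygenation dynamics are described by a
three-input, single-output linear convolution model

    y(n) = k₀ + Σ_{m=0}^{M} k_p(m) p(n−m)
              + Σ_{m=0}^{M} k_x(m) x(n−m)
              + Σ_{m=0}^{M} k_z(m) z(n−m),

with inputs p = arterial blood pressure (mmHg), x = end-tidal CO₂
(mmHg), z = cerebral flow velocity (cm/s) and output y = tissue
oxygenation index (%), all sampled at Δt = 0.25 s. The model assumes
linear, time-invariant dynamics over the 5-min record and exogenous
inputs (no closed-loop feedback is simulated or modelled). Memory is
M = 200 lags (50 s), matching the horizon over which the step-response
indices are averaged.

### Laguerre expansion

Estimating 3(M+1)+1 = 604 free lag weights from ~1100 usable samples is
hopeless, so each kernel is expanded on L = 4 discrete Laguerre
functions (DLFs) — the impulse responses of a first-order low-pass
with pole √α followed by all-pass sections, orthonormal over n ≥ 0,
with b₀(n) = √(1−α)·α^{n/2}. The regression then has 3L + 1 = 13
parameters, fitted by ordinary least squares on samples n = M…N−1 (the
first M samples are excluded from both fitting and NMSE scoring
because the convolution would implicitly zero-pad unknown pre-record
inputs). Plain OLS is used (no ridge); the design-matrix condition
number is recorded and a warning is emitted above 10⁸; rank deficiency
is an error.

The decay parameter α ∈ (0,1) sets the basis time scale: the time
constant of b₀ is −Δt/ln√α. For the default grid
{0.70, 0.75, 0.80, 0.85, 0.90, 0.95} this spans roughly 1.4–10 s per
function — with L = 4 functions the basis covers effective memories of
~10–70 s, which is what kernels with components peaking near 20 s
require. (Substantially smaller α values cannot represent such slow
components at this sampling rate; their basis decays within a couple
of seconds.) One α is shared by the three inputs and chosen per
subject as the grid point minimizing in-sample prediction NMSE; ties
break toward smaller α. Signals are not normalized before fitting, so
kernels keep physical units (TOI % per mmHg or per cm/s).

### Physio-markers

For a linear model the predicted response to a unit step of one input
(others at zero) is the cumulative sum of that kernel; no Δt scaling
is applied, so the response is per 1 physical unit of the input. The
indices CCR (CO₂), CTP (CFV) and CAP (ABP) are arithmetic means of the
step response over samples n = 0…199 (50 s). Prediction NMSE is
100·Σ(y−ŷ)²/Σ(y−ȳ)², the deviation-from-mean form (after high-pass
filtering the mean is ~0, making this nearly identical to the
Σy²-normalized form). Gain functions are magnitudes of the
zero-padded kernel DFT (default 2048 points) on 0…Nyquist; they are
computed per subject and may be averaged per group, and |H(0)| equals
the terminal step-response value by construction.

**Known bias at the default order.** With inputs band-limited to
0.01–0.15 Hz (spontaneous variability after the mandated filtering),
kernel content near DC is only weakly identified, and the L = 4
expansion of kernels that are not exactly in its span leaves a
systematic ~10–20% bias in the step-average indices. Group sign
patterns and contrasts are unaffected (the replicate tests recover
them in 100/100 seeded cohorts). Raising L to 8 removes the bias on
the default templates (<1% span error); the default stays at L = 4 to
keep the parameter count far below the sample count, mirroring
small-parameter practice on 5-min records.

## Preprocessing

1. **Resampling.** Cubic splines (not-a-knot boundary conditions)
   interpolate each irregular event series onto the shared 0.25-s
   grid; the grid is the intersection of all channel spans, snapped
   inward to multiples of Δt, and no extrapolation is permitted.
2. **High-pass.** Subtraction of a 120-s moving-average Hanning window
   (481 normalized symmetric Hann weights), removing baseline and
   content below ~0.01 Hz.
3. **Low-pass.** An 8-s Hanning moving average (33 weights),
   suppressing respiratory sinus arrhythmia and content above
   ~0.2 Hz.

Both filters have exactly unit DC gain and output length equal to
input length via reflect-padding of half a window per side — chosen
because 5-min records are short relative to the 2-min window, so
discarding edges would be costly. Reflect padding leaves a small
residual mean after the high-pass; a final exact mean removal (also a
linear operation) makes filtered signals baseline-free to machine
precision. High-pass precedes low-pass; for these linear filters the
order only matters at the edges and is fixed for reproducibility.

## Synthetic cohort generator

The generator emulates the study conditions so the full pipeline is
testable without patient data: 12 controls and 36 patients, 300-s
records, heart beats as a truncated-Gaussian renewal process
(0.9 ± 0.05 s), breaths likewise (4.0 ± 0.5 s), and CO₂ values placed
at breath times while ABP/CFV/TOI share the beat times.

- **Latent inputs** are Gaussian processes band-limited by FFT masking
  to 0.01–0.15 Hz (the upper edge sits inside the low-pass passband;
  content above it would not survive preprocessing anyway), with
  resting SDs of 3 mmHg (ABP), 1.5 mmHg (CO₂) and 3 cm/s (CFV) around
  group-specific baselines.
- **Ground-truth kernels** are sums of two gamma-like lobes per input.
  Controls' CO₂ kernel has a positive early lobe (peak 2 s) plus a
  positive slow lobe (peak 20 s); patients' CO₂ kernel has a negative
  early lobe (peak 3 s) with a small late rebound; CFV kernels share
  one shape with the patient amplitude roughly halved; ABP kernels are
  small and net-negative in both groups. Each template is scaled so
  its 50-s step average equals the group's published index mean (CCR
  0.144 vs −0.059; CTP 0.184 vs 0.085; CAP −0.022 vs −0.029).
- **Between-subject variability** is one multiplicative amplitude
  factor per kernel, N(1, 0.30²) clipped positive — it preserves each
  group's kernel polarity. Realized cohort index SDs are therefore
  smaller than the study's printed SDs, which fold in physiological
  heterogeneity (kernel-shape variation, nonstationarity, measurement
  artifacts) that the generator does not emulate; tests passing on
  synthetic cohorts demonstrate pipeline correctness under the
  configured conditions, not field performance on real recordings.
- **Output noise** is Gaussian, band-limited to 0.01–0.20 Hz by
  default, with its scale solved in closed form (a quadratic) so the
  noiseless model's prediction NMSE on each generated record equals
  the group target exactly (22.17% controls, 37.95% patients). The
  band matters: purely white noise is almost entirely removed by the
  filter cascade, which would erase the intended group NMSE contrast;
  white noise remains available via `noise_band_hz=None`. Because the
  filters still remove part of the in-band noise and in-sample OLS
  absorbs some of the rest, fitted NMSE comes out near 14%/20% —
  below the configured raw-record levels but with the study's group
  ordering.
- **Covariates** follow the published group summaries (age, MMSE and
  DLMR as rounded Gaussians, gender as Bernoulli with proportions
  5/12 and 24/36).

Everything derives from one root seed through per-subject child
streams, so cohorts are exactly reproducible and order-independent.

## Cohort statistics

Group comparisons use the two-sample t-test with unequal variances
(Welch) and Welch–Satterthwaite degrees of freedom, two-sided, for all
markers and covariates (gender coded +1 female / 0 male and fed to the
same test). No multiple-testing correction is applied, matching the
analysis being mirrored.

Two-feature composites use the Fisher linear discriminant with pooled
within-class covariance: w ∝ S_w⁻¹(μ_control − μ_patient), rescaled so
the first feature's weight is +1 (composite = f₁ + w₂·f₂). The printed
coefficients of the mirrored analysis (e.g. 1.337 on CTP) are
data-dependent outcomes; the package always re-derives the weights
from the cohort at hand. The decision threshold is the midpoint of the
projected class means; boundary points go to the negative class.
Classification metrics are resubstitution values (train = test), as in
the mirrored analysis, and the report says so; percentages are stored
exactly and rounded half-even to one decimal only for display.
Cognitive-score association is OLS regression with the Pearson-r
t-test p-value.

## Numerical and testing notes

- Laguerre functions are generated by the numerically stable two-term
  filter recursion, not the closed-form binomial sum.
- The exact noise-calibration quadratic
  σ²(gᵀg − q·cᵀc) − 2qσ(dᵀc) − q(dᵀd) = 0 (g the raw noise draw, c its
  centred version, d the centred clean output, q the target ratio) has
  a unique positive root whenever the clean output has variance; a
  zero-variance clean output with a nonzero noise target is an error.
- A constant fitted output is handled specially: NMSE is 0 when the
  trivial fit is exact, an error otherwise (the ratio is undefined).
- Test oracles are independent of the implementation path: brute-force
  O(N·M) convolutions, brute-force DTFT/DFT sums, Gram-matrix sums,
  closed-form discriminant algebra, permutation tests, and scipy's
  Welch test as a cross-library check.
- Replicate-level properties (group-sign recovery, test calibration)
  use fixed seed sets; the 100-replicate pipeline property runs the
  full simulate → preprocess → fit → markers chain at the default
  cohort size (12 + 36 subjects, 300 s), ~1 s per cohort.

## Limitations

- Linear, time-invariant, open-loop model only; no Volterra/nonlinear
  terms, no baroreflex or chemoreflex feedback.
- The generator produces stationary Gaussian inputs and i.i.d.
  renewal event times; real recordings contain artifacts, slow drifts
  and respiratory coupling that are out of scope.
- Resubstitution classification metrics are optimistically biased by
  construction; they are reported for parity with the mirrored
  analysis, not as an accuracy claim.
- The published per-subject recordings are unavailable, so cohort
  statistics can be validated only against published summary
  statistics and on synthetic cohorts.
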