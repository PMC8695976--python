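#!/usr/bin/env python
"""Resample and filter every subject's channels onto a shared 0.25-s grid.

Cubic-spline interpolation, 2-min Hanning high-pass, 8-s Hanning
low-pass: the result is four contemporaneous zero-mean signals per
subject, band-limited to roughly 0.01-0.2 Hz.  Writes one CSV per
subject under results/02_preprocessed/.
"""

import argparse
from pathlib import Path

import pandas as pd

from cortox.preprocess import CHANNELS, FilterSpec, preprocess_subject
from cortox.synthgen import read_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-root", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort = read_cohort(args.out_root / "01_cohort")
    out = args.out_root / "02_preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    spec = FilterSpec()
    n_samples = None
    for subject in cohort:
        signals = preprocess_subject(subject, spec)
        grid = signals["abp"].times
        pd.DataFrame({"time_s": grid,
                      **{ch: signals[ch].values for ch in CHANNELS}}).to_csv(
            out / f"{subject.subject_id}.csv", index=False)
        n_samples = len(grid)

    print(f"preprocessed {len(cohort)} subjects at dt={spec.dt}s "
          f"(~{n_samples} samples each; high-pass {spec.highpass_window_s:.0f}s, "
          f"low-pass {spec.lowpass_window_s:.0f}s Hanning windows)")
    print(f"wrote filtered signals to {out}")


if __name__ == "__main__":
    main()
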