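#!/usr/bin/env python
"""Derive the physio-marker table from the fitted kernels.

CCR, CTP and CAP are the 50-s time-averages of the model-predicted
tissue-oxygenation response to a unit step of CO2, CFV and ABP
respectively; prediction NMSE comes from each fit.  Also writes the
group-average kernels (lag-wise mean and SD) per input.  Outputs:
results/04_markers.csv and results/04_group_kernels.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cortox.lek import KernelSet
from cortox.markers import aggregate_kernels, index_from_step, step_response
from cortox.synthgen import read_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-root", type=Path, default=Path("results"))
    parser.add_argument("--horizon", type=float, default=50.0)
    args = parser.parse_args()

    cohort = {s.subject_id: s for s in read_cohort(args.out_root / "01_cohort")}
    fit_dir = args.out_root / "03_fits"
    rows, kernel_rows = [], {"abp": [], "co2": [], "cfv": []}
    labels = []
    for path in sorted(fit_dir.glob("*.json")):
        d = json.loads(path.read_text())
        k = KernelSet.from_dict(d["kernels"])
        subject = cohort[d["subject_id"]]
        rows.append({
            "subject_id": d["subject_id"], "group": subject.group,
            "ccr": index_from_step(step_response(k.k_co2, k.dt, args.horizon)),
            "ctp": index_from_step(step_response(k.k_cfv, k.dt, args.horizon)),
            "cap": index_from_step(step_response(k.k_abp, k.dt, args.horizon)),
            "nmse": d["nmse_pct"], **subject.covariates})
        for name in kernel_rows:
            kernel_rows[name].append(k.kernel(name))
        labels.append(subject.group)

    markers = pd.DataFrame(rows)
    markers.to_csv(args.out_root / "04_markers.csv", index=False)

    group_frames = []
    for name, kernels in kernel_rows.items():
        for group, (mean, sd) in aggregate_kernels(kernels, labels).items():
            group_frames.append(pd.DataFrame({
                "input": name, "group": group,
                "lag_s": 0.25 * pd.RangeIndex(len(mean)),
                "kernel_mean": mean, "kernel_sd": sd}))
    pd.concat(group_frames).to_csv(args.out_root / "04_group_kernels.csv",
                                   index=False)

    summary = markers.groupby("group")[["ccr", "ctp", "cap", "nmse"]].mean()
    print("group-mean markers:")
    print(summary.round(3).to_string())
    print(f"wrote {args.out_root / '04_markers.csv'} and group-average kernels")


if __name__ == "__main__":
    main()
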