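#!/usr/bin/env python
"""Cohort statistics on the marker table.

Welch (unequal-variance) t-tests per marker and covariate,
Fisher-discriminant composites (CCR with CTP; CCR with prediction
NMSE) with resubstitution classification metrics at the midpoint
boundary, and the regression of delayed-recall memory scores on the
CCR index.  Writes results/05_report.json and prints the headline
numbers.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cortox.pipeline import cohort_report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-root", type=Path, default=Path("results"))
    args = parser.parse_args()

    markers = pd.read_csv(args.out_root / "04_markers.csv")
    report = cohort_report(markers)
    out = args.out_root / "05_report.json"
    out.write_text(json.dumps(report, indent=2))

    gc = report["group_comparisons"]
    print("Welch p-values (controls vs patients):")
    for key in ("ccr", "ctp", "cap", "nmse"):
        print(f"  {key:4s}: mean {gc[key]['mean1']:+.3f} vs "
              f"{gc[key]['mean2']:+.3f}, p = {gc[key]['p']:.3g}")
    for name, comp in report["composites"].items():
        w2 = comp["discriminant"]["weights"][1]
        cls = comp["classification"]
        print(f"composite {name}: weight {w2:+.3f}, Welch p = "
              f"{comp['welch']['p']:.3g}; sens/spec/acc = "
              f"{cls['sensitivity_pct']}/{cls['specificity_pct']}/"
              f"{cls['accuracy_pct']}%")
    reg = report["regressions"]["dlmr_vs_ccr"]
    print(f"DLMR vs CCR regression: r = {reg['r']:.3f}, p = {reg['p']:.3g}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
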