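"""Compare overall survival between RMPA subtypes.

Kaplan-Meier curves and the two-group log-rank test, overall and
stratified by WHO grade.  Writes the statistics and the step functions.
"""

import argparse
from pathlib import Path

import pandas as pd

from rmpa.data_io import read_clinical_table
from rmpa.survival_stats import km_estimate, logrank_test, stratified_compare


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--assignments", type=Path,
                        default=Path("results/assignments.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/survival.csv"))
    args = parser.parse_args()

    clinical = read_clinical_table(args.cohort / "clinical.csv")
    labels = pd.read_csv(args.assignments, index_col=0)["label"]
    usable = clinical.usable_for_survival
    data = clinical.data[usable]

    res = logrank_test(data["time"], data["event"], labels[data.index])
    print(f"overall log-rank: chi2={res.statistic:.3f}, p={res.p_value:.3g}")

    curves = []
    for lab in labels.unique():
        sub = data[labels[data.index] == lab]
        curve = km_estimate(sub["time"], sub["event"])
        print(f"  {lab}: n={len(sub)}, median survival {curve.median:.1f} months")
        curves.append(pd.DataFrame({
            "group": lab, "time": curve.event_times,
            "survival": curve.survival, "at_risk": curve.at_risk,
        }))

    strat = stratified_compare(clinical, labels, stratum="grade")
    print("stratified by grade:")
    print(strat.round(4).to_string())

    args.out.parent.mkdir(parents=True, exist_ok=True)
    strat.to_csv(args.out)
    pd.concat(curves).to_csv(args.out.parent / "km_curves.csv", index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
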