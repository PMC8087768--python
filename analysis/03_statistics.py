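#!/usr/bin/env python
"""Statistical stage over the processed cohort.

Per-gait summary (Froude and SNW means +- SD), one-tailed moment-arm
correlations for ankle SNW and the mass-specific tendon outcomes, and the
subject-random-intercept mixed model of ankle SNW at sprint speed.
Writes results/gait_summary.tsv, results/correlations.tsv and
results/mixed_model.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from heelspring.io_formats import read_results, read_subject_config
from heelspring.stats_analysis import correlation_table, gait_summary, snw_mixed_model

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> int:
    outcomes_path = RESULTS / "outcomes.tsv"
    if not outcomes_path.exists():
        print("run analysis/02_process_trials.py first", file=sys.stderr)
        return 1
    df = read_results(outcomes_path)
    subjects = read_subject_config(ROOT / "scratch" / "cohort" / "subjects.yaml")
    sdf = pd.DataFrame([s.__dict__ for s in subjects])

    summary = gait_summary(df)
    summary.to_csv(RESULTS / "gait_summary.tsv", sep="\t", index=False, float_format="%.4f")
    print("per-gait summary:")
    print(summary.to_string(index=False))

    corr = correlation_table(df, sdf)
    corr.to_csv(RESULTS / "correlations.tsv", sep="\t", index=False, float_format="%.4g")
    print("\nmoment-arm correlations (one-tailed, steps pooled):")
    print(corr[["gait", "variable", "n", "r", "t", "p_one_tailed"]].to_string(index=False))
    sig = corr[(corr.p_one_tailed <= 0.05)]
    print(f"\nsignificant at p<=0.05: "
          + "; ".join(f"{r.variable} @ {r.gait} (r={r.r:.2f})" for r in sig.itertuples()))

    fit = snw_mixed_model(df, sdf, gait="sprint")
    mm = pd.DataFrame({"beta": fit.beta, "wald_z": fit.wald_z, "p": fit.p_value})
    mm.to_csv(RESULTS / "mixed_model.tsv", sep="\t", float_format="%.4g")
    print("\nmixed model of ankle SNW at sprint (z-scored fixed effects, "
          f"subject random-intercept var {fit.random_intercept_var:.3f}):")
    print(mm.to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
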