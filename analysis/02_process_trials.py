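#!/usr/bin/env python
"""Run the inverse-dynamics + tendon pipeline over the simulated cohort.

Reads the trial files written by 01_simulate_cohort.py and writes the
per-step outcome table (SNW per joint, tendon stress/strain/energy, Froude,
external moment arm) to results/outcomes.tsv.
"""

import sys
from pathlib import Path

from heelspring.cli import main as cli_main
from heelspring.io_formats import read_results

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
OUT = ROOT / "results" / "outcomes.tsv"


def main() -> int:
    if not (COHORT_DIR / "trials.tsv").exists():
        print("run analysis/01_simulate_cohort.py first", file=sys.stderr)
        return 1
    OUT.parent.mkdir(exist_ok=True)
    cli_main(["process", "--trials", str(COHORT_DIR), "--out", str(OUT)])
    df = read_results(OUT)
    print(f"processed {df.subject_id.nunique()} subjects, {len(df)} support phases -> {OUT}")
    for gait, grp in df.groupby("gait", sort=False):
        print(f"  {gait:10s} ankle SNW {grp.snw_ankle.mean():.3f} +- {grp.snw_ankle.std():.3f}, "
              f"peak stress {grp.stress_peak.mean()/1e6:6.1f} MPa")
    return 0


if __name__ == "__main__":
    sys.exit(main())
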