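#!/usr/bin/env python
"""Effect-recovery experiments: injected vs null cohorts, and LMM recovery.

Five seeds of paired 24-subject cohorts at run/sprint: the injected cohorts
must reproduce the expected sign pattern (positive ankle-SNW / moment-arm
correlation, negative mass-specific stress and energy correlations), all
significant at the step level; the null cohorts are judged on subject means
with Holm family-wise correction.  A 50 x 10 mixed-model simulation checks
coefficient recovery.  Writes results/recovery_correlations.tsv and
results/lmm_recovery.tsv.
"""

import logging
import sys
from pathlib import Path

import pandas as pd

from heelspring.recovery import evaluate_recovery, lmm_recovery

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> int:
    logging.disable(logging.WARNING)
    summary = evaluate_recovery(seeds=(1, 2, 3, 4, 5))
    rows = []
    for res in summary.injected_tables + summary.null_tables:
        t = res.directional("step" if res.injected else "subject")
        t = t.assign(seed=res.seed, cohort="injected" if res.injected else "null")
        rows.append(t)
    table = pd.concat(rows, ignore_index=True)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "recovery_correlations.tsv", sep="\t", index=False,
                 float_format="%.4g")
    print("injected cohorts: all directional tests significant ->",
          summary.injected_all_significant)
    print("null cohorts: no family-wise significant correlation ->",
          summary.null_clean,
          f"(min Holm-adjusted p = {summary.null_holm_p.min():.3f})")

    betas = (0.5, -0.3, 0.2)
    fit = lmm_recovery(7, betas=betas)
    lm = pd.DataFrame({
        "injected": list(betas),
        "recovered": [fit[f"beta_x{i+1}"] for i in range(3)],
    }, index=[f"x{i+1}" for i in range(3)])
    lm.to_csv(RESULTS / "lmm_recovery.tsv", sep="\t", float_format="%.4g")
    print("\nmixed-model coefficient recovery (50 subjects x 10 steps):")
    print(lm.to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
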