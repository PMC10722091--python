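#!/usr/bin/env python
"""Score the pipeline run against the cohort's planted truth.

Re-runs the pipeline in memory on the same cohort configuration as
01/02 and reports, per stage, how much of the planted structure was
recovered: differential recall and effect accuracy, NCF precision/recall,
PSA sensitivity/specificity and the batch-parameter error.  Writes
results/recovery_metrics.tsv.
"""

import importlib.util
import sys
from pathlib import Path

from abarray import pipeline, simulate

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

spec = importlib.util.spec_from_file_location(
    "sim_driver", Path(__file__).parent / "01_simulate_cohort.py")
sim_driver = importlib.util.module_from_spec(spec)
spec.loader.exec_module(sim_driver)


def main():
    cfg = pipeline.RunConfig(outdir="")
    res, recovery = pipeline.simulate_and_score(
        cfg, cohort_cfg=sim_driver.cohort_config()
    )
    RESULTS.mkdir(exist_ok=True)
    recovery.to_csv(RESULTS / "recovery_metrics.tsv", sep="\t", index=False)
    print(recovery.to_string(index=False))
    print(f"\nwritten to {RESULTS / 'recovery_metrics.tsv'}")


if __name__ == "__main__":
    main()
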