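#!/usr/bin/env python
"""Run the full analysis pipeline on the simulated cohort.

Reads the GPR/layout/manifest/FASTA/GMT written by 01_simulate_cohort.py,
runs consensus QC, Cy3-BSA scaling, PSA exclusion, negative-control
filtration, cyclic loess, batch correction, the three differential
contrasts, MoCA correlation, the cross-reactivity screen and gene-set
enrichment.  Full stage tables land in scratch/run/; the run report is
copied to results/.
"""

import json
import shutil
from pathlib import Path

from abarray import pipeline

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RUN_DIR = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def run_config() -> pipeline.RunConfig:
    return pipeline.RunConfig(
        gpr_dir=str(COHORT_DIR / "gpr"),
        layout=str(COHORT_DIR / "layout.tsv"),
        manifest=str(COHORT_DIR / "manifest.csv"),
        fasta=str(COHORT_DIR / "panel.fasta"),
        gmt=str(COHORT_DIR / "sets.gmt"),
        outdir=str(RUN_DIR),
    )


def main():
    res = pipeline.run_pipeline(run_config())
    RESULTS.mkdir(exist_ok=True)
    shutil.copy(RUN_DIR / "run_report.json", RESULTS / "run_report.json")

    rep = res.report
    s = rep["samples"]
    print(f"samples: {s['total']} total, {s['psa_flagged']} PSA, "
          f"{s['qc_failed']} QC-failed -> {s['retained']} retained")
    a = rep["antigens"]
    print(f"antigens: {a['panel']} panel -> NCF removed {a['ncf_removed']} "
          f"-> {a['tested']} tested")
    for name, c in rep["contrasts"].items():
        print(f"  {name}: {c['significant']} significant "
              f"({c['up']} up / {c['down']} down)")
    m = rep["moca"]
    print(f"MoCA correlations: {m['passing']} passing "
          f"({m['negative']} negative / {m['positive']} positive) "
          f"of {m['tested']} tested")
    if res.crossreact is not None:
        n_pairs = len(res.crossreact)
        n_xr = int((res.crossreact["verdict"] == "possible_crossreactivity").sum())
        print(f"cross-reactivity: {n_pairs} correlated pairs screened, "
              f"{n_xr} flagged possible cross-reactivity")
    print(json.dumps(rep, indent=2))


if __name__ == "__main__":
    main()
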