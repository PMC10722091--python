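#!/usr/bin/env python
"""Condense the full stage tables into small summary tables under results/.

Pulls the top differential antigens per contrast (with planted-truth
annotation), the strongest MoCA correlations, the cross-reactivity pair
table and the top enrichment rows out of scratch/run/ so the headline
findings are reviewable without the multi-hundred-row stage outputs.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RUN_DIR = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"

CONTRASTS = ("dementia_vs_control", "dementia_vs_MCI", "MCI_vs_control")


def _read(path):
    return pd.read_csv(path, sep="\t", comment="#")


def main():
    RESULTS.mkdir(exist_ok=True)
    truth_de = _read(COHORT_DIR / "truth_de.tsv")

    frames = []
    for name in CONTRASTS:
        t = _read(RUN_DIR / f"differential_{name}.tsv")
        t = t[t["significant"]].nsmallest(15, "p").copy()
        t.insert(0, "contrast", name)
        planted = set(truth_de.loc[truth_de["contrast"] == name, "antigen_id"])
        t["planted"] = t["antigen_id"].isin(planted)
        frames.append(t)
    top = pd.concat(frames, ignore_index=True)
    top.to_csv(RESULTS / "differential_top.tsv", sep="\t", index=False)

    moca = _read(RUN_DIR / "moca_correlation.tsv")
    hits = moca[moca["passes_filter"]].copy()
    hits.to_csv(RESULTS / "moca_hits.tsv", sep="\t", index=False)

    xr = _read(RUN_DIR / "crossreactivity.tsv")
    xr.to_csv(RESULTS / "crossreactivity_pairs.tsv", sep="\t", index=False)

    enr = []
    for name in CONTRASTS:
        p = RUN_DIR / f"enrichment_{name}.tsv"
        if p.exists():
            t = _read(p).nsmallest(3, "fdr")
            t.insert(0, "contrast", name)
            enr.append(t)
    enrichment = pd.concat(enr, ignore_index=True)
    enrichment.to_csv(RESULTS / "enrichment_top.tsv", sep="\t", index=False)

    print(f"top differential antigens (planted recovery "
          f"{top['planted'].mean():.0%} among top hits):")
    print(top.head(10).to_string(index=False))
    print(f"\nMoCA hits: {len(hits)} "
          f"({(hits['rho'] < 0).sum()} negative, {(hits['rho'] > 0).sum()} positive)")
    print(hits.reindex(hits['rho'].abs().sort_values(ascending=False).index)
          .head(6).to_string(index=False))
    print(f"\ncross-reactivity pairs:\n{xr.to_string(index=False)}")
    print(f"\ntop enrichment rows:\n{enrichment.to_string(index=False)}")


if __name__ == "__main__":
    main()
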