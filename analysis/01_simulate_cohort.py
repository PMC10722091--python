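#!/usr/bin/env python
"""Generate the study-scale synthetic cohort the analysis runs on.

Writes one GPR file per sample plus the array layout, sample manifest,
synthetic protein FASTA, synthetic gene sets (GMT) and the planted-truth
tables under scratch/cohort/.  The cohort mirrors the motivating study's
shape: 98 clean samples (38 control / 42 MCI / 18 dementia) plus 4
polyspecific (PSA) samples and 1 control-failure sample, two run-year
batches, 600 analytes with 30 dementia-contrast and 20 MCI-contrast
differential antigens, 15 nonspecific antigens, 3 MoCA-coupled antigens
and 2 duplicate-sequence twin pairs for the cross-reactivity screen.
"""

from pathlib import Path

from abarray import io as aio, simulate

SEED = 2026
ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"


def cohort_config() -> simulate.CohortConfig:
    return simulate.CohortConfig(seed=SEED, correlated_pairs=2, anticorrelated_pairs=1)


def main():
    cfg = cohort_config()
    cohort = simulate.generate_cohort(cfg)
    simulate.write_cohort(cohort, COHORT_DIR)
    aio.write_fasta(COHORT_DIR / "panel.fasta", simulate.synthetic_fasta(cohort))
    aio.write_gmt(COHORT_DIR / "sets.gmt", simulate.synthetic_gmt(cohort))

    t = cohort.truth
    print(f"cohort written to {COHORT_DIR}")
    print(f"  samples: {len(cohort.manifest)} "
          f"({cohort.manifest.groupby('group').size().to_dict()})")
    print(f"  planted PSA samples: {t.psa_samples}")
    print(f"  planted QC failures: {t.qc_fail_samples}")
    print(f"  planted differential antigens: "
          f"{t.de.groupby('contrast').size().to_dict()}")
    print(f"  nonspecific antigens: {len(t.nonspecific)}; "
          f"MoCA-coupled: {len(t.moca_coupled)}; "
          f"twin pairs: {len(t.correlated_pairs)}")


if __name__ == "__main__":
    main()
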