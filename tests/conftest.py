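import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from abarray import pipeline, simulate


@pytest.fixture(scope="session")
def cohort():
    """Default-scale synthetic cohort (full spot rendering), shared read-only."""
    return simulate.generate_cohort(simulate.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline_result(cohort):
    """Full pipeline run on the default cohort's in-memory spot table."""
    cfg = pipeline.RunConfig(outdir="")
    return pipeline._run_from_spots(
        cfg, cohort.layout, cohort.manifest, cohort.spots, write_outputs=False
    )


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A small cohort written to disk in every external format."""
    cfg = simulate.CohortConfig(
        seed=7, n_antigens=60, n_negative_controls=8, n_cy3_bsa=4, n_igg_pos=1,
        group_sizes={"control": 8, "MCI": 8, "dementia": 6},
        psa_samples=1, qc_fail_samples=1,
        n_de_dementia=6, n_de_mci=4, n_nonspecific=3,
        moca_couplings=(-0.5,),
    )
    cohort = simulate.generate_cohort(cfg)
    outdir = tmp_path_factory.mktemp("cohort")
    simulate.write_cohort(cohort, outdir)
    return outdir, cohort
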