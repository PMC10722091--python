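"""End-to-end orchestration: config, stage sequencing, reports.

Stage order is fixed: net → consensus → Cy3-BSA scale → NCF → cyclic loess →
batch correction → PSA detection and sample exclusion → differential
reactivity → MoCA correlation → cross-reactivity → enrichment.  Every
exclusion (sample or antigen) is logged with a machine-parseable reason code
and every output file carries the config hash.

The public entry points are :func:`run_pipeline` (process a cohort on disk)
and :func:`simulate_and_score` (generate a synthetic cohort, run the
pipeline, score recovery against the planted truth).  The numbered analysis
scripts are thin drivers over these functions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical, crossreact, differential, enrich, io as aio, qc, simulate
from .core import ValidationError
from .normalize import LoessConfig, cyclic_loess, eb_batch_correct

__all__ = ["RunConfig", "run_pipeline", "simulate_and_score", "PipelineResult"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All paths and stage parameters of one pipeline run."""

    gpr_dir: str = ""
    layout: str = ""
    manifest: str = ""
    fasta: str | None = None
    gmt: str | None = None
    outdir: str = "results"

    cv_threshold: float = 20.0
    ncf_r: float = 0.7
    loess_span: float = 0.7
    loess_iterations: int = 3
    loess_method: str = "fast"
    batch_protect: tuple = ("group", "age", "sex", "diabetes")
    psa_quantile: float = 0.95
    psa_fraction: float = 0.25
    alpha: float = 0.05
    adjust: str = "none"
    rho_min: float = 0.27
    r_threshold: float = 0.7
    identity_threshold: float = 28.0
    seed: int = 0  # used by the simulate subcommand only

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    matrix: object  # final AntigenMatrix (retained samples, post batch correction)
    manifest_retained: pd.DataFrame
    exclusions: pd.DataFrame
    group_counts: pd.DataFrame
    qc_report: qc.QCReport
    ncf_removed: list
    batch_model: object
    de: dict  # contrast name -> DifferentialResult table
    overlap: pd.DataFrame
    moca: pd.DataFrame | None
    crossreact: pd.DataFrame | None
    enrichment: dict | None
    report: dict


def _contrast_name(contrast) -> str:
    return f"{contrast[0]}_vs_{contrast[1]}"


def run_pipeline(cfg: RunConfig, write_outputs: bool = True) -> PipelineResult:
    layout = aio.read_layout(cfg.layout)
    layout.require_control_classes()
    manifest = aio.read_manifest(cfg.manifest)
    gpr_paths = sorted(Path(cfg.gpr_dir).glob("*.gpr"))
    if not gpr_paths:
        raise ValidationError(f"no .gpr files in {cfg.gpr_dir}")
    spots = pd.concat([aio.read_gpr(p, layout) for p in gpr_paths], ignore_index=True)
    extra = set(spots["sample_id"]) - set(manifest.index)
    if extra:
        raise ValidationError(f"GPR samples missing from manifest: {sorted(extra)[:5]}")
    return _run_from_spots(cfg, layout, manifest, spots,
                           write_outputs=write_outputs)


def _run_from_spots(cfg, layout, manifest, spots, truth=None, write_outputs=True):
    h = cfg.config_hash()
    outdir = Path(cfg.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    m, report = qc.spots_to_matrix(spots, layout, cv_threshold=cfg.cv_threshold)
    log.info("consensus matrix: %d features x %d samples", *m.values.shape)
    m = qc.control_scale(m, layout, report)

    # PSA detection and sample exclusion happen before any between-array
    # normalization: cyclic loess would absorb a polyspecific sample's broad
    # shift (it is exactly the per-sample trend loess removes), and PSA
    # samples distort the NCF correlations and the loess reference.
    analytes = layout.analyte_ids.intersection(m.antigen_ids)
    psa = qc.detect_psa(m.subset_antigens(analytes), quantile=cfg.psa_quantile,
                        fraction_threshold=cfg.psa_fraction,
                        batch=manifest["batch"])
    report.samples.loc[psa.index, ["psa_score", "psa_flag"]] = psa[
        ["psa_score", "psa_flag"]
    ]
    retained, exclusions, counts = qc.sample_accounting(manifest, report)
    for row in exclusions.itertuples(index=False):
        log.info("EXCLUDE sample=%s reason=%s", row.sample_id, row.reason)
    m = m.subset_samples(retained.index)

    m, removed = qc.negative_control_filter(m, layout, r_threshold=cfg.ncf_r)
    for aid in removed:
        log.info("EXCLUDE antigen=%s reason=ncf_correlated", aid)
    lcfg = LoessConfig(span=cfg.loess_span, iterations=cfg.loess_iterations,
                       method=cfg.loess_method)
    m = cyclic_loess(m, lcfg)
    m_final, batch_model = eb_batch_correct(m, manifest.loc[m.sample_ids],
                                            protect=tuple(cfg.batch_protect))

    de = {}
    for contrast in differential.CONTRASTS:
        name = _contrast_name(contrast)
        de[name] = differential.run_contrast(
            m_final, retained, contrast, alpha=cfg.alpha, adjust=cfg.adjust
        )
    overlap = differential.overlap_table(de)

    moca = clinical.correlate_with_moca(
        m_final, retained, rho_min=cfg.rho_min, alpha=cfg.alpha
    )

    xr = None
    if cfg.fasta:
        sequences = aio.read_fasta(cfg.fasta)
        frames = []
        for name, table in de.items():
            sig = list(table.index[table["significant"]])
            if len(sig) < 2:
                continue
            corr = crossreact.correlation_matrix(m_final, sig)
            screen = crossreact.crossreact_screen(
                corr, sequences, r_threshold=cfg.r_threshold,
                identity_threshold=cfg.identity_threshold,
            )
            if len(screen):
                screen.insert(0, "contrast", name)
                frames.append(screen)
        xr = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["contrast", "antigen_a", "antigen_b",
                                         "pearson_r", "identity_percent", "verdict"]))

    enrichment = None
    if cfg.gmt:
        sets = aio.read_gmt(cfg.gmt)
        universe = list(m_final.antigen_ids)
        enrichment = {}
        for name, table in de.items():
            query = [a for a in table.index[table["significant"]]]
            enrichment[name] = enrich.fisher_enrich(query, sets, universe,
                                                    fdr_alpha=cfg.alpha)

    report_dict = {
        "config_hash": h,
        "samples": {
            "total": int(len(manifest)),
            "psa_flagged": int((exclusions["reason"].isin(["psa", "both"])).sum()),
            "qc_failed": int((exclusions["reason"].isin(["qc_fail", "both"])).sum()),
            "retained": int(len(retained)),
            "per_group": counts.to_dict(orient="index"),
        },
        "antigens": {
            "panel": int(len(layout.analyte_ids)),
            "ncf_removed": int(len(removed)),
            "tested": int(m_final.values.shape[0]),
        },
        "contrasts": {
            name: {
                "significant": int(t["significant"].sum()),
                "up": int((t["significant"] & (t["direction"] == "up")).sum()),
                "down": int((t["significant"] & (t["direction"] == "down")).sum()),
            }
            for name, t in de.items()
        },
        "moca": {
            "tested": int(len(moca)),
            "passing": int(moca["passes_filter"].sum()),
            "negative": int((moca["passes_filter"] & (moca["sign"] == "negative")).sum()),
            "positive": int((moca["passes_filter"] & (moca["sign"] == "positive")).sum()),
        },
    }

    result = PipelineResult(
        matrix=m_final, manifest_retained=retained, exclusions=exclusions,
        group_counts=counts, qc_report=report, ncf_removed=removed,
        batch_model=batch_model, de=de, overlap=overlap, moca=moca,
        crossreact=xr, enrichment=enrichment, report=report_dict,
    )
    if write_outputs:
        _write_outputs(result, cfg, outdir, h)
    return result


def _write_outputs(res: PipelineResult, cfg: RunConfig, outdir: Path, h: str) -> None:
    def save(df: pd.DataFrame, name: str, index=True):
        p = outdir / name
        with open(p, "w") as fh:
            fh.write(f"# config_hash={h}\n")
            df.to_csv(fh, sep="\t", index=index)

    save(res.matrix.values.round(5), "normalized_matrix.tsv")
    save(res.exclusions, "exclusions.tsv", index=False)
    save(res.group_counts, "sample_accounting.tsv")
    save(res.qc_report.samples, "sample_qc.tsv")
    for name, t in res.de.items():
        save(t.round(6), f"differential_{name}.tsv")
        volcano = t[["log2fc", "p"]].copy()
        volcano["neg_log10_p"] = -np.log10(volcano.pop("p"))
        save(volcano.round(6), f"volcano_{name}.tsv")
    save(res.overlap, "overlap.tsv", index=False)
    if res.moca is not None:
        save(res.moca.round(6), "moca_correlation.tsv")
    if res.crossreact is not None:
        save(res.crossreact.round(6), "crossreactivity.tsv", index=False)
    if res.enrichment is not None:
        for name, t in res.enrichment.items():
            save(t.round(8), f"enrichment_{name}.tsv", index=False)
    if res.batch_model is not None:
        save(res.batch_model.summary().round(6), "batch_model.tsv", index=False)
    (outdir / "run_report.json").write_text(json.dumps(res.report, indent=2) + "\n")


def simulate_and_score(cfg: RunConfig, cohort_cfg=None, workdir=None):
    """Generate a synthetic cohort, run the full pipeline on its files,
    score recovery against the planted truth.

    Returns ``(PipelineResult, recovery table)``.
    """
    cohort_cfg = cohort_cfg or simulate.CohortConfig(seed=cfg.seed)
    cohort = simulate.generate_cohort(cohort_cfg)
    if workdir is not None:
        workdir = Path(workdir)
        simulate.write_cohort(cohort, workdir)
        run_cfg = RunConfig(**{**asdict(cfg),
                               "gpr_dir": str(workdir / "gpr"),
                               "layout": str(workdir / "layout.tsv"),
                               "manifest": str(workdir / "manifest.csv")})
        res = run_pipeline(run_cfg, write_outputs=bool(run_cfg.outdir))
    else:
        res = _run_from_spots(cfg, cohort.layout, cohort.manifest, cohort.spots,
                              write_outputs=False)
    contrast_map = {
        "dementia_vs_control": "dementia_vs_control",
        "dementia_vs_MCI": "dementia_vs_MCI",
        "MCI_vs_control": "MCI_vs_control",
    }
    de_for_scoring = {contrast_map[k]: v for k, v in res.de.items() if k in contrast_map}
    recovery = simulate.score_recovery(
        cohort.truth,
        de_results=de_for_scoring,
        ncf_removed=res.ncf_removed,
        ncf_universe=list(cohort.layout.analyte_ids),
        psa_table=res.qc_report.samples,
        batch_model=res.batch_model,
    )
    return res, recovery
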