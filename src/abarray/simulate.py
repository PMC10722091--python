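"""Synthetic autoantibody-array cohort generator with known ground truth.

Emulates the data-generating process every pipeline stage assumes, on the
scale of the motivating study: quadruplicate-spotted antigen panels (~600
analytes plus negative-control and Cy3-BSA features), three clinical groups
(control / MCI / dementia), two run-year batches, per-array scanner gain and
smooth intensity-dependent dye bias, planted group effects, nonspecific
antigens tracking the negative-control profile, polyspecific (PSA) samples,
MoCA scores drawn per group with optional antigen–MoCA rank couplings, and
spot-level replicate noise with occasional outlier spots.

Everything planted is returned in a :class:`SyntheticTruth` table so the
corresponding pipeline stage can be scored for recovery.  A single seed
drives the whole cohort; each component draws from its own deterministically
derived substream, so e.g. changing the number of PSA samples does not
perturb the planted differential antigens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AntigenMatrix, ArrayLayout, ValidationError
from . import io as aio

__all__ = ["CohortConfig", "SyntheticTruth", "Cohort", "generate_cohort",
           "write_cohort", "score_recovery"]

RFU_SATURATION = 65535  # 16-bit scanner

# substream codes (stable across releases; order must never change)
_STREAMS = {
    "layout": 1, "manifest": 2, "baseline": 3, "group_effects": 4,
    "batch": 5, "nonspecific": 6, "psa": 7, "moca": 8, "noise": 9,
    "spots": 10, "gain_bias": 11, "pairs": 12,
}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[component]])


@dataclass
class CohortConfig:
    """Cohort-level simulation parameters (defaults = study-scale conditions)."""

    seed: int  # mandatory, no default randomness
    n_antigens: int = 600
    n_negative_controls: int = 20
    n_cy3_bsa: int = 8
    n_igg_pos: int = 2
    replicates: int = 4

    # clean samples per group (post-QC target scale)
    group_sizes: dict = field(
        default_factory=lambda: {"control": 38, "MCI": 42, "dementia": 18}
    )
    psa_samples: int = 4
    qc_fail_samples: int = 1

    # planted differential reactivity (log2) — offsets of a group's mean
    n_de_dementia: int = 30   # dementia vs control
    n_de_mci: int = 20        # MCI vs control
    de_delta: float = 0.75    # 1.5 x the antigen-level noise SD

    # batches (run years); gamma applies to every antigen of the later batch
    batches: tuple = ("2021", "2022")
    batch_gamma: float = 0.4
    batch_gamma_sd: float = 0.05
    batch_delta2: float = 1.0  # residual-variance multiplier of the later batch

    # nonspecific antigens tracking the negative-control profile
    n_nonspecific: int = 15
    nonspecific_r: float = 0.9

    # polyspecific reactivity
    psa_shift: float = 1.5   # log2, = 3 x noise_sd
    psa_breadth: float = 0.6  # fraction of analytes shifted

    # noise structure (log2 scale unless noted)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.5     # per antigen x sample biological noise
    sample_sd: float = 0.2    # per-sample offset shared by analytes
    gain_sd: float = 0.25     # per-array scanner gain (removed by Cy3 scaling)
    dye_bias_amplitude: float = 0.3  # smooth intensity-dependent bias
    nonspecific_bg_sd: float = 0.4   # per-sample nonspecific background
    spot_sd: float = 0.08     # replicate spot noise
    outlier_fraction: float = 0.01   # spots shifted x5 raw to exercise the CV gate
    outlier_factor: float = 5.0
    flagged_fraction: float = 0.002  # spots the scanner flags bad (-100)
    bg_mean: float = 100.0    # raw RFU background level
    bg_sd: float = 10.0

    # MoCA model (means/sd per group on the study's Table-1 scale)
    moca_params: dict = field(
        default_factory=lambda: {
            "control": (28.9, 1.4), "MCI": (22.9, 6.6), "dementia": (11.6, 6.6)
        }
    )
    # (target Spearman rho) per coupled antigen; antigens auto-assigned
    moca_couplings: tuple = (-0.5, -0.5, 0.4)

    age_params: dict = field(
        default_factory=lambda: {
            "control": (66, 7), "MCI": (70, 8), "dementia": (75, 5)
        }
    )
    male_fraction: dict = field(
        default_factory=lambda: {"control": 0.64, "MCI": 0.55, "dementia": 0.64}
    )
    diabetes_prevalence: float = 0.30
    low_education_fraction: float = 0.20

    # perfectly (anti)correlated analyte pairs for cross-reactivity tests
    correlated_pairs: int = 0
    anticorrelated_pairs: int = 0

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if not 0 < self.nonspecific_r < 1:
            raise ValidationError("nonspecific_r must be in (0, 1): a target of "
                                  "1.0 is infeasible with nonzero noise")
        if self.replicates < 2:
            raise ValidationError("replicates must be >= 2")
        for v in (self.de_delta, self.noise_sd, self.sample_sd, self.spot_sd):
            if v < 0:
                raise ValidationError("effect sizes and SDs must be >= 0")
        n_special = (self.n_de_dementia + self.n_de_mci + self.n_nonspecific
                     + len(self.moca_couplings)
                     + 2 * (self.correlated_pairs + self.anticorrelated_pairs))
        if n_special > self.n_antigens:
            raise ValidationError("more planted antigens than analytes")


@dataclass
class SyntheticTruth:
    """Machine-readable record of everything planted in a cohort."""

    de: pd.DataFrame            # antigen_id, contrast, delta, direction
    batch: pd.DataFrame         # batch, gamma_mean, delta2; per-antigen gamma in attrs
    nonspecific: list           # antigen ids
    psa_samples: list           # sample ids
    qc_fail_samples: list
    moca_coupled: pd.DataFrame  # antigen_id, target_rho
    correlated_pairs: pd.DataFrame  # antigen_a, antigen_b, sign
    batch_gamma_per_antigen: pd.Series | None = None


@dataclass
class Cohort:
    layout: ArrayLayout
    manifest: pd.DataFrame      # validated, indexed by sample_id
    consensus: pd.DataFrame     # true per-cell log2 signal (pre spot noise), features x samples
    spots: pd.DataFrame         # full spot table (all samples)
    truth: SyntheticTruth
    config: CohortConfig

    def consensus_matrix(self, stage: str = "consensus",
                         analytes_only: bool = False) -> AntigenMatrix:
        """True consensus signal as an :class:`AntigenMatrix` at a given stage.

        This is the generator's matrix-level interface: it bypasses spot
        rendering and GPR round-tripping for tests of downstream stages.
        """
        vals = self.consensus
        if analytes_only:
            vals = vals.loc[self.layout.analyte_ids]
        valid = pd.DataFrame(True, index=vals.index, columns=vals.columns)
        return AntigenMatrix(vals.copy(), valid, stage=stage)


def generate_cohort(cfg: CohortConfig, render_spots: bool = True) -> Cohort:
    """Generate one cohort.

    ``render_spots=False`` skips the spot-level rendering (replicate noise,
    outliers, backgrounds, GPR rows) and leaves ``spots`` empty; the
    consensus signal is identical either way because every component draws
    from its own substream.  Use it for tests of downstream stages.
    """
    cfg.validate()
    seed = cfg.seed

    # ---- layout -----------------------------------------------------------
    analyte_ids = [f"AG{i + 1:04d}" for i in range(cfg.n_antigens)]
    neg_ids = [f"NEG{i + 1:03d}" for i in range(cfg.n_negative_controls)]
    cy3_ids = [f"CY3BSA{i + 1:02d}" for i in range(cfg.n_cy3_bsa)]
    igg_ids = [f"IGG{i + 1:02d}" for i in range(cfg.n_igg_pos)]
    classes = {a: "analyte" for a in analyte_ids}
    classes.update({a: "negative" for a in neg_ids})
    classes.update({a: "cy3_bsa" for a in cy3_ids})
    classes.update({a: "igg_pos" for a in igg_ids})
    layout = ArrayLayout.from_classes(classes, cfg.replicates)

    # ---- special antigen assignment (disjoint, deterministic) -------------
    rng_fx = _rng(seed, "group_effects")
    pool = list(analyte_ids)
    de_dem = pool[: cfg.n_de_dementia]
    pool = pool[cfg.n_de_dementia:]
    de_mci = pool[: cfg.n_de_mci]
    pool = pool[cfg.n_de_mci:]
    nonspecific = pool[: cfg.n_nonspecific]
    pool = pool[cfg.n_nonspecific:]
    moca_coupled = pool[: len(cfg.moca_couplings)]
    pool = pool[len(cfg.moca_couplings):]
    # twin pairs piggy-back on planted DE antigens where possible so that
    # both members reach the differential set the cross-reactivity screen sees
    corr_pairs = []
    de_pool = list(de_dem)
    for sign in [+1] * cfg.correlated_pairs + [-1] * cfg.anticorrelated_pairs:
        a = de_pool.pop(0) if de_pool else pool.pop(0)
        corr_pairs.append((a, pool.pop(0), sign))

    # ---- manifest ---------------------------------------------------------
    rng_m = _rng(seed, "manifest")
    groups_order = ("control", "MCI", "dementia")
    records = []
    extra = []  # (kind, group) for psa / qc_fail samples, spread over groups
    for i in range(cfg.psa_samples):
        extra.append(("psa", groups_order[i % 3]))
    for i in range(cfg.qc_fail_samples):
        extra.append(("qc_fail", groups_order[(i + 1) % 3]))
    roster = [("clean", g) for g in groups_order for _ in range(cfg.group_sizes[g])]
    roster += extra
    order = rng_m.permutation(len(roster))
    psa_ids, qcfail_ids = [], []
    for si, ri in enumerate(order):
        kind, g = roster[ri]
        sid = f"S{si + 1:03d}"
        if kind == "psa":
            psa_ids.append(sid)
        elif kind == "qc_fail":
            qcfail_ids.append(sid)
        mu, sd = cfg.moca_params[g]
        moca = int(np.clip(np.round(rng_m.normal(mu, sd)), 0, 30))
        amu, asd = cfg.age_params[g]
        records.append(
            {
                "sample_id": sid,
                "group": g,
                "age": float(np.round(rng_m.normal(amu, asd), 1)),
                "sex": "M" if rng_m.random() < cfg.male_fraction[g] else "F",
                "diabetes": bool(rng_m.random() < cfg.diabetes_prevalence),
                "batch": cfg.batches[si % len(cfg.batches)],
                "moca_raw": moca,
                "low_education": bool(rng_m.random() < cfg.low_education_fraction),
            }
        )
    manifest = pd.DataFrame(records).set_index("sample_id", drop=False)
    sample_ids = manifest.index
    n_samples = len(sample_ids)

    # ---- true log2 signal -------------------------------------------------
    rng_b = _rng(seed, "baseline")
    baseline = pd.Series(
        rng_b.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_antigens),
        index=analyte_ids,
    )
    neg_baseline = pd.Series(
        rng_b.normal(5.5, 0.3, cfg.n_negative_controls), index=neg_ids
    )
    cy3_baseline = pd.Series(rng_b.normal(12.0, 0.1, cfg.n_cy3_bsa), index=cy3_ids)
    igg_baseline = pd.Series(rng_b.normal(11.0, 0.2, cfg.n_igg_pos), index=igg_ids)

    rng_n = _rng(seed, "noise")
    sample_effect = rng_n.normal(0, cfg.sample_sd, n_samples)
    later_batch = (manifest["batch"] == cfg.batches[-1]).to_numpy()
    noise_scale = np.where(later_batch, np.sqrt(cfg.batch_delta2), 1.0)
    noise = rng_n.normal(0, cfg.noise_sd, (cfg.n_antigens, n_samples)) * noise_scale

    T = pd.DataFrame(
        baseline.to_numpy()[:, None] + sample_effect[None, :] + noise,
        index=analyte_ids, columns=sample_ids,
    )

    # planted group effects (random sign per antigen)
    de_rows = []
    is_mci = (manifest["group"] == "MCI").to_numpy()
    is_dem = (manifest["group"] == "dementia").to_numpy()
    for aid in de_dem:
        sign = 1.0 if rng_fx.random() < 0.5 else -1.0
        T.loc[aid, is_dem] += sign * cfg.de_delta
        de_rows.append({"antigen_id": aid, "contrast": "dementia_vs_control",
                        "delta": sign * cfg.de_delta,
                        "direction": "up" if sign > 0 else "down"})
        de_rows.append({"antigen_id": aid, "contrast": "dementia_vs_MCI",
                        "delta": sign * cfg.de_delta,
                        "direction": "up" if sign > 0 else "down"})
    for aid in de_mci:
        sign = 1.0 if rng_fx.random() < 0.5 else -1.0
        T.loc[aid, is_mci] += sign * cfg.de_delta
        de_rows.append({"antigen_id": aid, "contrast": "MCI_vs_control",
                        "delta": sign * cfg.de_delta,
                        "direction": "up" if sign > 0 else "down"})
        de_rows.append({"antigen_id": aid, "contrast": "dementia_vs_MCI",
                        "delta": -sign * cfg.de_delta,
                        "direction": "down" if sign > 0 else "up"})
    de_table = pd.DataFrame(de_rows, columns=["antigen_id", "contrast", "delta", "direction"])

    # MoCA-coupled antigens (rank coupling within MCI + dementia)
    rng_mc = _rng(seed, "moca")
    sigma_t = float(np.hypot(cfg.noise_sd, cfg.sample_sd))
    impaired = (manifest["group"].isin(("MCI", "dementia"))).to_numpy()
    moca_vals = manifest["moca_raw"].to_numpy(dtype=float)
    z = np.zeros(n_samples)
    if impaired.sum() >= 3 and np.std(moca_vals[impaired]) > 0:
        z[impaired] = (moca_vals[impaired] - moca_vals[impaired].mean()) / moca_vals[impaired].std()
    mc_rows = []
    for aid, rho in zip(moca_coupled, cfg.moca_couplings):
        eps = rng_mc.normal(0, 1, n_samples)
        signal = np.where(
            impaired, rho * z + np.sqrt(1 - rho**2) * eps, eps
        )
        T.loc[aid] = baseline[aid] + sigma_t * signal
        mc_rows.append({"antigen_id": aid, "target_rho": rho})
    moca_table = pd.DataFrame(mc_rows, columns=["antigen_id", "target_rho"])

    # nonspecific background and negative controls
    rng_ns = _rng(seed, "nonspecific")
    bg_profile = rng_ns.normal(0, cfg.nonspecific_bg_sd, n_samples)
    N = pd.DataFrame(
        neg_baseline.to_numpy()[:, None] + bg_profile[None, :]
        + rng_ns.normal(0, 0.15, (cfg.n_negative_controls, n_samples)),
        index=neg_ids, columns=sample_ids,
    )
    r = cfg.nonspecific_r
    eps_sd = cfg.nonspecific_bg_sd * np.sqrt(1.0 / r**2 - 1.0)
    for aid in nonspecific:
        T.loc[aid] = (
            baseline[aid] + bg_profile + rng_ns.normal(0, eps_sd, n_samples)
        )

    # correlated / anticorrelated twin pairs
    rng_p = _rng(seed, "pairs")
    pair_rows = []
    for a, b, sign in corr_pairs:
        twin = T.loc[a] - baseline[a]
        T.loc[b] = baseline[b] + sign * twin + rng_p.normal(0, 0.02, n_samples)
        pair_rows.append({"antigen_a": a, "antigen_b": b, "sign": sign})
    pairs_table = pd.DataFrame(pair_rows, columns=["antigen_a", "antigen_b", "sign"])

    # polyspecific samples: broad positive shift
    rng_psa = _rng(seed, "psa")
    for sid in psa_ids:
        hit = rng_psa.random(cfg.n_antigens) < cfg.psa_breadth
        T.loc[np.array(analyte_ids)[hit], sid] += cfg.psa_shift

    # batch location effect on every analyte and negative control
    rng_batch = _rng(seed, "batch")
    gamma = pd.Series(
        rng_batch.normal(cfg.batch_gamma, cfg.batch_gamma_sd, cfg.n_antigens),
        index=analyte_ids,
    )
    T.loc[:, later_batch] = T.loc[:, later_batch].add(gamma, axis=0)
    N.loc[:, later_batch] += cfg.batch_gamma
    batch_table = pd.DataFrame(
        {
            "batch": list(cfg.batches),
            "gamma_mean": [0.0] * (len(cfg.batches) - 1) + [cfg.batch_gamma],
            "delta2": [1.0] * (len(cfg.batches) - 1) + [cfg.batch_delta2],
        }
    )

    # controls
    C3 = pd.DataFrame(
        np.repeat(cy3_baseline.to_numpy()[:, None], n_samples, axis=1),
        index=cy3_ids, columns=sample_ids,
    )
    IG = pd.DataFrame(
        np.repeat(igg_baseline.to_numpy()[:, None], n_samples, axis=1),
        index=igg_ids, columns=sample_ids,
    )
    full = pd.concat([T, N, C3, IG])

    # per-array gain and smooth intensity-dependent dye bias
    rng_g = _rng(seed, "gain_bias")
    gain = rng_g.normal(0, cfg.gain_sd, n_samples)
    amp = rng_g.uniform(-cfg.dye_bias_amplitude, cfg.dye_bias_amplitude, n_samples)
    V = full.to_numpy() + gain[None, :]
    V = V + amp[None, :] * ((V - 8.0) / 4.0) ** 2
    consensus = pd.DataFrame(V, index=full.index, columns=sample_ids)

    truth = SyntheticTruth(
        de=de_table,
        batch=batch_table,
        nonspecific=list(nonspecific),
        psa_samples=list(psa_ids),
        qc_fail_samples=list(qcfail_ids),
        moca_coupled=moca_table,
        correlated_pairs=pairs_table,
        batch_gamma_per_antigen=gamma,
    )
    if not render_spots:
        empty = pd.DataFrame(columns=["sample_id", "antigen_id", "replicate_index",
                                      "fg_median", "bg_median", "flag", "valid"])
        return Cohort(layout=layout, manifest=manifest, consensus=consensus,
                      spots=empty, truth=truth, config=cfg)

    # ---- spot rendering ---------------------------------------------------
    rng_s = _rng(seed, "spots")
    R = cfg.replicates
    n_feat = len(full.index)
    spot_log2 = (
        consensus.to_numpy()[:, :, None]
        + rng_s.normal(0, cfg.spot_sd, (n_feat, n_samples, R))
    )
    outlier = rng_s.random((n_feat, n_samples, R)) < cfg.outlier_fraction
    spot_log2 = spot_log2 + outlier * np.log2(cfg.outlier_factor)
    raw = np.clip(np.round(2.0 ** spot_log2), 1, RFU_SATURATION)
    bg = np.clip(np.round(rng_s.normal(cfg.bg_mean, cfg.bg_sd, raw.shape)), 0, None)
    fg = np.clip(raw + bg, 0, RFU_SATURATION)
    flags = np.where(
        rng_s.random(raw.shape) < cfg.flagged_fraction, -100, 0
    )
    # qc-fail samples: every Cy3-BSA spot flagged bad
    cy3_rows = full.index.get_indexer(cy3_ids)
    qcf_cols = sample_ids.get_indexer(qcfail_ids)
    for c in qcf_cols:
        flags[cy3_rows, c, :] = -100

    feat_idx = np.repeat(np.arange(n_feat), n_samples * R)
    samp_idx = np.tile(np.repeat(np.arange(n_samples), R), n_feat)
    rep_idx = np.tile(np.arange(1, R + 1), n_feat * n_samples)
    spots = pd.DataFrame(
        {
            "sample_id": sample_ids.to_numpy()[samp_idx],
            "antigen_id": full.index.to_numpy()[feat_idx],
            "replicate_index": rep_idx,
            "fg_median": fg.reshape(-1),
            "bg_median": bg.reshape(-1),
            "flag": flags.reshape(-1),
        }
    )
    spots["valid"] = spots["flag"] >= 0
    spots = spots.sort_values(["sample_id", "antigen_id", "replicate_index"],
                              kind="mergesort").reset_index(drop=True)
    return Cohort(layout=layout, manifest=manifest, consensus=consensus,
                  spots=spots, truth=truth, config=cfg)


def write_cohort(cohort: Cohort, outdir) -> dict[str, Path]:
    """Write GPR files (one per sample), layout, manifest and truth tables."""
    if len(cohort.spots) == 0:
        raise ValidationError("cohort was generated with render_spots=False")
    outdir = Path(outdir)
    gpr_dir = outdir / "gpr"
    gpr_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sid, sub in cohort.spots.groupby("sample_id", sort=True):
        p = gpr_dir / f"{sid}.gpr"
        aio.write_gpr(p, sub, sample_id=str(sid))
        paths[str(sid)] = p
    aio.write_layout(outdir / "layout.tsv", cohort.layout)
    aio.write_manifest(outdir / "manifest.csv", cohort.manifest)
    t = cohort.truth
    t.de.to_csv(outdir / "truth_de.tsv", sep="\t", index=False)
    t.batch.to_csv(outdir / "truth_batch.tsv", sep="\t", index=False)
    t.moca_coupled.to_csv(outdir / "truth_moca.tsv", sep="\t", index=False)
    t.correlated_pairs.to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
    pd.Series(t.nonspecific, name="antigen_id").to_csv(
        outdir / "truth_nonspecific.tsv", sep="\t", index=False)
    pd.DataFrame({
        "sample_id": t.psa_samples + t.qc_fail_samples,
        "kind": ["psa"] * len(t.psa_samples) + ["qc_fail"] * len(t.qc_fail_samples),
    }).to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)
    paths["layout"] = outdir / "layout.tsv"
    paths["manifest"] = outdir / "manifest.csv"
    return paths


AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def synthetic_fasta(cohort: Cohort, min_len: int = 120, max_len: int = 400
                    ) -> dict[str, str]:
    """Synthetic protein sequences for every analyte (no real proteins).

    Random amino-acid strings; the members of each planted twin pair share
    one sequence, so the cross-reactivity screen can find a 100%-identity
    pair, while all other pairs are unrelated random sequences.
    """
    rng = _rng(cohort.config.seed, "layout")
    seqs: dict[str, str] = {}
    for aid in cohort.layout.analyte_ids:
        n = int(rng.integers(min_len, max_len + 1))
        seqs[aid] = "".join(rng.choice(AMINO_ACIDS, n))
    for row in cohort.truth.correlated_pairs.itertuples(index=False):
        seqs[row.antigen_b] = seqs[row.antigen_a]
    return seqs


def synthetic_gmt(cohort: Cohort, n_random_sets: int = 20,
                  set_size: int = 30) -> dict[str, set[str]]:
    """Synthetic gene sets over the analyte panel (no real annotation).

    ``n_random_sets`` sets of random panel members, plus one set built
    around the planted dementia-contrast antigens so over-representation is
    genuinely present.
    """
    rng = _rng(cohort.config.seed, "manifest")
    analytes = list(cohort.layout.analyte_ids)
    sets: dict[str, set[str]] = {}
    for i in range(n_random_sets):
        members = rng.choice(analytes, size=min(set_size, len(analytes)),
                             replace=False)
        sets[f"RANDOM_SET_{i + 1:02d}"] = set(members.tolist())
    de_dem = cohort.truth.de.loc[
        cohort.truth.de["contrast"] == "dementia_vs_control", "antigen_id"
    ].unique().tolist()
    if de_dem:
        filler = [a for a in analytes if a not in de_dem]
        pad = rng.choice(filler, size=max(set_size - len(de_dem), 5), replace=False)
        sets["PLANTED_DEMENTIA_SET"] = set(de_dem) | set(pad.tolist())
    return sets


def score_recovery(truth: SyntheticTruth,
                   de_results: dict[str, pd.DataFrame] | None = None,
                   ncf_removed: list | None = None,
                   ncf_universe: list | None = None,
                   psa_table: pd.DataFrame | None = None,
                   batch_model=None) -> pd.DataFrame:
    """Score pipeline outputs against planted truth.

    Returns a long-format metric table (metric, value, n).  Metrics are only
    emitted for the outputs supplied.
    """
    rows = []

    def add(metric, value, n):
        rows.append({"metric": metric, "value": float(value), "n": int(n)})

    if de_results is not None:
        for contrast, table in de_results.items():
            planted = truth.de[truth.de["contrast"] == contrast]
            planted = planted.set_index("antigen_id")
            sig = set(table.index[table["significant"]])
            if len(planted):
                found = [a for a in planted.index if a in sig]
                add(f"de_recall_{contrast}", len(found) / len(planted), len(planted))
                common = planted.index.intersection(table.index)
                err = (table.loc[common, "log2fc"] - planted.loc[common, "delta"]).abs()
                add(f"de_effect_mae_{contrast}", err.mean(), len(common))
            fp = [a for a in sig if a not in set(planted.index)]
            add(f"de_false_positives_{contrast}", len(fp), len(table))

    if ncf_removed is not None:
        removed = set(ncf_removed)
        planted = set(truth.nonspecific)
        tp = len(removed & planted)
        add("ncf_recall", tp / len(planted) if planted else 1.0, len(planted))
        add("ncf_precision", tp / len(removed) if removed else 1.0, len(removed))
        if ncf_universe is not None:
            negatives = set(ncf_universe) - planted
            add("ncf_false_removals", len(removed - planted), len(negatives))

    if psa_table is not None:
        planted = set(truth.psa_samples)
        flagged = set(psa_table.index[psa_table["psa_flag"]])
        pos = [s for s in psa_table.index if s in planted]
        neg = [s for s in psa_table.index if s not in planted]
        if pos:
            add("psa_sensitivity", len(planted & flagged) / len(pos), len(pos))
        if neg:
            add("psa_specificity", len(set(neg) - flagged) / len(neg), len(neg))

    if batch_model is not None and truth.batch_gamma_per_antigen is not None:
        later = truth.batch.iloc[-1]["batch"]
        est = batch_model.gamma_star.loc[later] * np.sqrt(batch_model.var_pooled)
        # estimated gammas are centered (weighted) across batches; compare shapes
        true_gamma = truth.batch_gamma_per_antigen.reindex(est.index)
        err = (est - est.mean()) - (true_gamma - true_gamma.mean())
        add("batch_gamma_rmse_centered", np.sqrt((err**2).mean()), len(est))

    return pd.DataFrame(rows, columns=["metric", "value", "n"])
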