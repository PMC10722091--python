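"""Spot-level quantitation and quality control.

Converts per-spot foreground/background medians into a per-sample antigen
consensus and applies the sample- and feature-level QC gates:

1. net intensity = foreground − background median, floored at 1 RFU;
2. replicate CV filter (quadruplicate spots; CV > 20% triggers iterative
   outlier removal down to a floor of two spots, else the cell is masked);
3. consensus = mean of surviving replicate net intensities, carried as log2;
4. Cy3-BSA control scaling across arrays;
5. negative-control filtration (NCF) of nonspecifically binding antigens;
6. polyspecific-reactivity (PSA) flagging and sample accounting.

CVs are computed on raw RFU with the n−1 standard deviation, the array
convention; everything downstream of the consensus is log2.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@contextmanager
def _quiet_nan():
    """Silence numpy's all-NaN slice warnings; empty cells are expected."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                message=".*(empty slice|All-NaN).*")
        with np.errstate(invalid="ignore", divide="ignore"):
            yield

from .core import AntigenMatrix, ArrayLayout, ValidationError

__all__ = [
    "net_intensity",
    "replicate_consensus",
    "spots_to_matrix",
    "control_scale",
    "negative_control_filter",
    "detect_psa",
    "sample_accounting",
    "QCReport",
]

NET_FLOOR = 1.0  # RFU; keeps log2 defined and marks at-background signal


def net_intensity(fg, bg, floor: float = NET_FLOOR):
    """Background-subtracted intensity, floored at ``floor`` RFU.

    Total on nonnegative inputs; scalar or array.
    """
    fg = np.asarray(fg, dtype=float)
    bg = np.asarray(bg, dtype=float)
    if (fg < 0).any() or (bg < 0).any():
        raise ValidationError("negative RFU input to net_intensity")
    out = np.maximum(fg - bg, floor)
    return out if out.ndim else float(out)


def _iterative_cv_filter(vals: np.ndarray, cv_threshold: float):
    """Vectorized CV gate over a (cells x replicates) array with NaN = invalid.

    While a cell's CV exceeds the threshold and more than two spots remain,
    the spot farthest from the cell median is removed and the CV recomputed.

    Returns (surviving values, cv after filtering, n_removed, masked).
    """
    v = vals.copy()
    n_removed = np.zeros(v.shape[0], dtype=int)
    while True:
        with _quiet_nan():
            n = np.sum(~np.isnan(v), axis=1)
            mean = np.nanmean(v, axis=1)
            sd = _nanstd1(v, n, mean)
            cv = np.where((n >= 2) & (mean > 0), 100.0 * sd / mean, np.nan)
        offending = (cv > cv_threshold) & (n > 2)
        if not offending.any():
            break
        with _quiet_nan():
            med = np.nanmedian(v[offending], axis=1)
        dist = np.abs(v[offending] - med[:, None])
        dist = np.where(np.isnan(dist), -np.inf, dist)
        worst = np.argmax(dist, axis=1)
        rows = np.nonzero(offending)[0]
        v[rows, worst] = np.nan
        n_removed[rows] += 1
    masked = np.isnan(cv) | (cv > cv_threshold)
    return v, cv, n_removed, masked


def _nanstd1(v, n, mean):
    sq = (v - mean[:, None]) ** 2
    ss = np.nansum(sq, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n > 1, np.sqrt(ss / np.maximum(n - 1, 1)), np.nan)


def replicate_consensus(net: np.ndarray, valid: np.ndarray | None = None,
                        cv_threshold: float = 20.0):
    """Consensus of one replicate set (raw-RFU net intensities).

    Returns ``(consensus, cv_percent, n_removed, masked)``; consensus is NaN
    when no valid spot exists.  A cell that still exceeds the CV threshold at
    two spots, or has fewer than two valid spots, is masked (consensus still
    reported when at least one spot survives).
    """
    net = np.asarray(net, dtype=float)
    v = net.copy()
    if valid is not None:
        v = np.where(np.asarray(valid, dtype=bool), v, np.nan)
    surv, cv, n_removed, masked = _iterative_cv_filter(v[None, :], cv_threshold)
    with _quiet_nan():
        cons = np.nanmean(surv, axis=1) if not np.isnan(surv).all() else np.array([np.nan])
    return float(cons[0]), float(cv[0]), int(n_removed[0]), bool(masked[0])


@dataclass
class QCReport:
    """Per-cell and per-sample QC bookkeeping accumulated along the pipeline."""

    cv_percent: pd.DataFrame  # antigen x sample
    n_spots_removed: pd.DataFrame
    masked: pd.DataFrame
    samples: pd.DataFrame  # index sample_id: psa_score, psa_flag, qc_fail, qc_fail_reason

    def fail_sample(self, sample_id: str, reason: str) -> None:
        self.samples.loc[sample_id, "qc_fail"] = True
        prev = self.samples.loc[sample_id, "qc_fail_reason"]
        self.samples.loc[sample_id, "qc_fail_reason"] = (
            reason if not prev else f"{prev};{reason}"
        )

    @classmethod
    def empty(cls, antigen_ids, sample_ids) -> "QCReport":
        shape = (len(antigen_ids), len(sample_ids))
        mk = lambda fill, dtype: pd.DataFrame(
            np.full(shape, fill, dtype=dtype), index=antigen_ids, columns=sample_ids
        )
        samples = pd.DataFrame(
            {
                "psa_score": np.nan,
                "psa_flag": False,
                "qc_fail": False,
                "qc_fail_reason": "",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        return cls(mk(np.nan, float), mk(0, int), mk(False, bool), samples)


def spots_to_matrix(spots: pd.DataFrame, layout: ArrayLayout,
                    cv_threshold: float = 20.0) -> tuple[AntigenMatrix, QCReport]:
    """Collapse a multi-sample spot table to a log2 consensus matrix.

    Net intensities are formed per spot, the replicate CV gate applied per
    (antigen, sample) cell, and the surviving spots averaged on the raw scale
    before log2 transform.  The returned matrix has stage ``consensus``.
    """
    spots = spots.copy()
    spots["net"] = net_intensity(spots["fg_median"], spots["bg_median"])
    spots.loc[~spots["valid"], "net"] = np.nan

    sample_ids = pd.Index(pd.unique(spots["sample_id"]), name="sample_id")
    antigen_ids = layout.antigen_ids
    max_rep = int(layout.table["n_replicates"].max())

    cube = np.full((len(antigen_ids), len(sample_ids), max_rep), np.nan)
    ai = pd.Index(antigen_ids).get_indexer(spots["antigen_id"])
    si = sample_ids.get_indexer(spots["sample_id"])
    ri = spots["replicate_index"].to_numpy(dtype=int) - 1
    if (ai < 0).any() or (si < 0).any() or (ri < 0).any() or (ri >= max_rep).any():
        raise ValidationError("spot table inconsistent with layout")
    dup = pd.MultiIndex.from_arrays([ai, si, ri]).duplicated()
    if dup.any():
        raise ValidationError("duplicate (antigen, sample, replicate) spot")
    cube[ai, si, ri] = spots["net"].to_numpy()

    flat = cube.reshape(-1, max_rep)
    surv, cv, n_removed, masked = _iterative_cv_filter(flat, cv_threshold)
    with _quiet_nan():
        cons = np.nanmean(surv, axis=1)
    shape = (len(antigen_ids), len(sample_ids))
    cons = cons.reshape(shape)
    values = pd.DataFrame(
        np.where(np.isnan(cons), 0.0, np.log2(np.where(np.isnan(cons) | (cons <= 0), 1.0, cons))),
        index=antigen_ids, columns=sample_ids,
    )
    valid = pd.DataFrame(~(np.isnan(cons) | masked.reshape(shape)),
                         index=antigen_ids, columns=sample_ids)
    report = QCReport.empty(antigen_ids, sample_ids)
    report.cv_percent.loc[:, :] = cv.reshape(shape)
    report.n_spots_removed.loc[:, :] = n_removed.reshape(shape)
    report.masked.loc[:, :] = (masked.reshape(shape)) | np.isnan(cons)
    return AntigenMatrix(values, valid, stage="consensus"), report


def control_scale(m: AntigenMatrix, layout: ArrayLayout,
                  report: QCReport | None = None) -> AntigenMatrix:
    """Align arrays on their Cy3-BSA controls.

    Each sample gets an additive log2 shift bringing its median Cy3-BSA value
    to the cohort grand median of those medians.  A sample with no valid
    Cy3-BSA cell is flagged ``qc_fail`` and left unshifted.
    """
    if m.stage != "consensus":
        raise ValidationError(f"control_scale expects stage consensus, got {m.stage}")
    cy3 = layout.cy3_bsa_ids
    if len(cy3) == 0:
        raise ValidationError("layout has no Cy3-BSA controls")
    sub = m.masked_values().loc[cy3]
    medians = sub.median(axis=0, skipna=True)
    grand = medians.median(skipna=True)
    shift = grand - medians
    no_ctrl = medians.isna()
    shift = shift.fillna(0.0)
    values = m.values.add(shift, axis=1)
    if report is not None:
        for s in m.sample_ids[no_ctrl]:
            report.fail_sample(s, "no_valid_cy3_bsa_control")
    return m.advance(values, "scaled")


def negative_control_filter(m: AntigenMatrix, layout: ArrayLayout,
                            r_threshold: float = 0.7):
    """Negative-control filtration (NCF).

    The reference profile is the per-sample mean of the negative-control
    features.  Every analyte whose Pearson correlation with that profile
    across samples exceeds ``r_threshold`` is excluded as nonspecific.  All
    control-class features are dropped from the analysis matrix as well —
    they are reference material, not analytes.

    Returns ``(filtered matrix at stage ncf, list of removed analyte ids)``.
    """
    if m.values.shape[1] < 3:
        raise ValidationError("NCF needs at least 3 samples")
    neg = layout.negative_control_ids.intersection(m.antigen_ids)
    if len(neg) == 0:
        raise ValidationError("no negative-control features present in matrix")
    masked = m.masked_values()
    ref = masked.loc[neg].mean(axis=0, skipna=True)
    analytes = layout.analyte_ids.intersection(m.antigen_ids)
    sub = masked.loc[analytes]
    # complete-pair Pearson r of each analyte against the reference profile
    r = sub.T.corrwith(ref)
    removed = analytes[(r > r_threshold).to_numpy(dtype=bool)]
    keep = analytes.difference(removed, sort=False)
    out = m.subset_antigens(keep)
    return (
        AntigenMatrix(out.values.copy(), out.valid.copy(), stage="ncf"),
        list(removed),
    )


def detect_psa(m: AntigenMatrix, quantile: float = 0.95,
               fraction_threshold: float = 0.25,
               batch: pd.Series | None = None) -> pd.DataFrame:
    """Flag polyspecific-antibody (PSA) reactivity.

    A sample's PSA score is the fraction of antigens on which it strictly
    exceeds the cohort-wide ``quantile`` value of that antigen; broad
    low-affinity binding inflates this breadth.  Samples with score above
    ``fraction_threshold`` are flagged.

    When ``batch`` (a per-sample series) is given, quantile references are
    computed within batch: detection runs before batch correction, and a
    run-year location shift would otherwise inflate every score in the
    shifted batch.
    """
    if m.values.shape[0] < 10:
        raise ValidationError("PSA detection needs at least 10 antigens")
    vals = m.masked_values().to_numpy()
    if batch is None:
        groups = [np.arange(vals.shape[1])]
    else:
        batch = batch.reindex(m.sample_ids)
        groups = [np.nonzero((batch == b).to_numpy())[0]
                  for b in pd.unique(batch.dropna())]
    score = np.full(vals.shape[1], np.nan)
    with _quiet_nan():
        for idx in groups:
            sub = vals[:, idx]
            q = np.nanquantile(sub, quantile, axis=1)
            exceed = sub > q[:, None]
            observed = ~np.isnan(sub)
            score[idx] = exceed.sum(axis=0) / np.maximum(observed.sum(axis=0), 1)
    return pd.DataFrame(
        {"psa_score": score, "psa_flag": score > fraction_threshold},
        index=m.sample_ids,
    )


def sample_accounting(manifest: pd.DataFrame, report: QCReport):
    """Apply PSA and QC exclusions; conserve counts.

    Returns ``(retained manifest, exclusion table, per-group counts)``.
    A sample flagged both PSA and qc_fail is excluded once with reason
    ``both``.
    """
    samples = report.samples.reindex(manifest.index)
    psa = samples["psa_flag"].fillna(False).astype(bool)
    qcf = samples["qc_fail"].fillna(False).astype(bool)
    reason = np.select(
        [psa & qcf, psa, qcf], ["both", "psa", "qc_fail"], default=""
    )
    excluded = manifest.index[psa | qcf]
    exclusion = pd.DataFrame(
        {
            "sample_id": excluded,
            "group": manifest.loc[excluded, "group"].to_numpy(),
            "reason": pd.Series(reason, index=manifest.index).loc[excluded].to_numpy(),
        }
    )
    retained = manifest.drop(index=excluded)
    counts = (
        pd.DataFrame(
            {
                "total": manifest.groupby("group").size(),
                "excluded": manifest.loc[excluded].groupby("group").size(),
            }
        )
        .fillna(0)
        .astype(int)
    )
    counts["retained"] = counts["total"] - counts["excluded"]
    assert len(retained) + len(exclusion) == len(manifest)
    return retained, exclusion, counts
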