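"""Covariate-adjusted differential autoantibody reactivity.

Per antigen, an ordinary least-squares fit of log2 reactivity on a design
containing the pairwise group contrast plus age (centered), sex and diabetes
indicators.  Residual variances are then shrunk across antigens toward a
common prior by empirical Bayes: the prior degrees of freedom ``d0`` and
prior variance ``s0²`` are estimated by moment-matching the distribution of
log residual variances (digamma/trigamma inversion), giving the moderated
t-statistic

    t̃_g = β̂_g / (se_g · s̃_g / s_g),   s̃²_g = (d0·s0² + df_g·s²_g)/(d0 + df_g)

on ``df_g + d0`` degrees of freedom.  As d0 → 0 this is the ordinary t; as
d0 → ∞ every antigen shares the pooled variance.

Significance defaults to unadjusted p < 0.05 with Benjamini–Hochberg FDR
reported alongside (a logged warning notes that the unadjusted threshold
ignores multiplicity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import AntigenMatrix, ValidationError

__all__ = [
    "build_design",
    "fit_linear_models",
    "moderate_variances",
    "call_differential",
    "run_contrast",
    "CONTRASTS",
    "overlap_table",
]

log = logging.getLogger(__name__)

#: the three pairwise clinical contrasts, (case, reference)
CONTRASTS = (
    ("dementia", "control"),
    ("dementia", "MCI"),
    ("MCI", "control"),
)

COVARIATES = ("age", "sex", "diabetes")


def build_design(manifest: pd.DataFrame, contrast: tuple[str, str],
                 covariates=COVARIATES) -> pd.DataFrame:
    """Design matrix for one pairwise contrast: intercept, case indicator,
    centered age, sex (M=1), diabetes (1=yes).  Rows restricted to the two
    groups involved."""
    case, ref = contrast
    sub = manifest[manifest["group"].isin((case, ref))]
    if sub["group"].nunique() < 2:
        raise ValidationError(f"contrast {contrast} needs samples of both groups")
    cols = {"intercept": np.ones(len(sub)), "group": (sub["group"] == case).astype(float)}
    if "age" in covariates:
        age = sub["age"].astype(float)
        cols["age"] = age - age.mean()
    if "sex" in covariates:
        cols["sex"] = (sub["sex"] == "M").astype(float)
    if "diabetes" in covariates:
        cols["diabetes"] = sub["diabetes"].astype(float)
    X = pd.DataFrame(cols, index=sub.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # drop constant covariate columns (e.g. all-male cohort) rather than fail
        keep = ["intercept", "group"]
        for c in X.columns:
            if c in keep:
                continue
            trial = X[keep + [c]]
            if np.linalg.matrix_rank(trial.to_numpy()) == trial.shape[1]:
                keep.append(c)
        dropped = [c for c in X.columns if c not in keep]
        log.warning("design rank-deficient; dropped covariate(s) %s", dropped)
        X = X[keep]
    return X


def fit_linear_models(m: AntigenMatrix, design: pd.DataFrame,
                      coef: str = "group") -> pd.DataFrame:
    """Per-antigen OLS of log2 reactivity on the design.

    Masked cells are dropped per antigen with degrees of freedom recomputed.
    Returns a DataFrame with columns ``coef`` (the contrast coefficient =
    log2 fold change), ``s2`` (residual variance), ``df``, ``se_unit``
    (contrast standard error per unit residual SD) and ``n_used``.
    Antigens with no residual degrees of freedom are skipped with a warning.
    """
    samples = design.index
    Y = m.masked_values()[samples].to_numpy(dtype=float).T  # n x G
    X = design.to_numpy(dtype=float)
    ci = design.columns.get_loc(coef)
    n, p = X.shape

    complete = np.isfinite(Y).all(axis=0)
    out = np.full((Y.shape[1], 5), np.nan)  # coef, s2, df, se_unit, n_used

    if complete.any():
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ Y[:, complete]
        resid = Y[:, complete] - X @ beta
        df = n - p
        s2 = (resid**2).sum(axis=0) / df
        idx = np.nonzero(complete)[0]
        out[idx, 0] = beta[ci]
        out[idx, 1] = s2
        out[idx, 2] = df
        out[idx, 3] = np.sqrt(XtX_inv[ci, ci])
        out[idx, 4] = n

    for g in np.nonzero(~complete)[0]:
        ok = np.isfinite(Y[:, g])
        Xg = X[ok]
        if ok.sum() <= p or np.linalg.matrix_rank(Xg) < p:
            log.warning(
                "antigen %s skipped: insufficient residual degrees of freedom",
                m.antigen_ids[g],
            )
            continue
        XtX_inv = np.linalg.inv(Xg.T @ Xg)
        beta = XtX_inv @ Xg.T @ Y[ok, g]
        resid = Y[ok, g] - Xg @ beta
        dfg = ok.sum() - p
        out[g] = [beta[ci], (resid**2).sum() / dfg, dfg,
                  np.sqrt(XtX_inv[ci, ci]), ok.sum()]

    fit = pd.DataFrame(
        out, index=m.antigen_ids, columns=["coef", "s2", "df", "se_unit", "n_used"]
    )
    return fit.dropna(subset=["coef"])


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(-dif / y) < 1e-8:
            break
    return y


def moderate_variances(s2: np.ndarray, df: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Estimate the variance prior (d0, s0²) and return shrunk variances.

    Moment-matching on z = log s²: E z = log s0² + ψ(df/2) − log(df/2)
    shifted by the prior term, Var z adds ψ′(d0/2); solving the trigamma
    equation gives d0, then s0².  If the excess variance of z is non-positive
    every antigen variance is identical in distribution and d0 = ∞ with
    s̃² = s0² (the mean-matched common variance).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if (s2 <= 0).any():
        s2 = np.maximum(s2, 1e-12)
    if len(s2) < 10:
        raise ValidationError("variance moderation needs >= 10 antigens")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = len(z)
    excess = ((e - e_mean) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0).mean()
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
        s2_tilde = np.full_like(s2, s0_2)
        return d0, s0_2, s2_tilde
    d0 = float(2.0 * _trigamma_inverse(np.array([excess]))[0])
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)
    return d0, s0_2, s2_tilde


def call_differential(fit: pd.DataFrame, d0: float, s2_tilde: np.ndarray,
                      alpha: float = 0.05, adjust: str = "none") -> pd.DataFrame:
    """Moderated t-tests and significance calls for one contrast.

    ``adjust`` is ``none`` (raw p < alpha, the study convention — a warning
    notes the multiplicity caveat) or ``BH``.  The BH-adjusted FDR is always
    reported in the ``fdr`` column.
    """
    if adjust not in ("none", "BH"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    s2_tilde = np.asarray(s2_tilde, dtype=float)
    se = fit["se_unit"].to_numpy() * np.sqrt(s2_tilde)
    t_mod = fit["coef"].to_numpy() / se
    df_total = fit["df"].to_numpy() + (0.0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    significant = (fdr < alpha) if adjust == "BH" else (p < alpha)
    if adjust == "none" and not getattr(call_differential, "_warned", False):
        log.warning(
            "significance uses the unadjusted p < %.3g threshold (the study "
            "convention); BH FDR is reported alongside in the 'fdr' column",
            alpha,
        )
        call_differential._warned = True
    out = pd.DataFrame(
        {
            "antigen_id": fit.index,
            "log2fc": fit["coef"].to_numpy(),
            "t_mod": t_mod,
            "p": p,
            "fdr": fdr,
            "direction": np.where(fit["coef"].to_numpy() > 0, "up", "down"),
            "significant": significant,
            "n_used": fit["n_used"].to_numpy(dtype=int),
        }
    ).set_index("antigen_id")
    return out.sort_values("p")


def run_contrast(m: AntigenMatrix, manifest: pd.DataFrame,
                 contrast: tuple[str, str], alpha: float = 0.05,
                 adjust: str = "none", covariates=COVARIATES) -> pd.DataFrame:
    """Fit, moderate and call one pairwise contrast end-to-end."""
    if m.stage != "batch_corrected":
        raise ValidationError(
            f"differential analysis expects stage batch_corrected, got {m.stage}"
        )
    design = build_design(manifest.loc[manifest.index.intersection(m.sample_ids)],
                          contrast, covariates)
    fit = fit_linear_models(m, design)
    d0, s0_2, s2_tilde = moderate_variances(fit["s2"].to_numpy(), fit["df"].to_numpy())
    return call_differential(fit, d0, s2_tilde, alpha=alpha, adjust=adjust)


def overlap_table(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Antigens significant in more than one contrast ("commonly dysregulated")."""
    sig = {name: set(t.index[t["significant"]]) for name, t in results.items()}
    all_ids = sorted(set().union(*sig.values())) if sig else []
    rows = []
    for aid in all_ids:
        hits = [name for name, s in sig.items() if aid in s]
        if len(hits) > 1:
            rows.append({"antigen_id": aid, "contrasts": ";".join(hits), "n_contrasts": len(hits)})
    return pd.DataFrame(rows, columns=["antigen_id", "contrasts", "n_contrasts"])
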