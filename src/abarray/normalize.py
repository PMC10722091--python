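"""Between-array normalization and run-year batch correction.

Two operations, both deterministic:

* :func:`cyclic_loess` — removes intensity-dependent (dye/scanner) bias. In
  the default ``fast`` variant each sample is loess-normalized against the
  cross-sample mean profile: M = sample − reference is regressed on
  A = (sample + reference)/2 with a degree-1 tricube-weighted local fit and
  the fitted trend subtracted, cycling over samples for a fixed number of
  iterations.  The ``pairs`` variant normalizes every sample pair and applies
  half the fitted trend to each, which is slower but makes no reference
  assumption.

* :func:`eb_batch_correct` — parametric empirical-Bayes location/scale batch
  adjustment (the ComBat model): per antigen the data are standardized under
  a design containing the protected biological covariates, per-batch additive
  (gamma) and multiplicative (delta²) effects are estimated, shrunk toward
  moment-matched normal / inverse-gamma priors by the iterative EB update,
  removed, and the standardization restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import AntigenMatrix, ValidationError

__all__ = ["LoessConfig", "BatchModel", "cyclic_loess", "eb_batch_correct"]


@dataclass(frozen=True)
class LoessConfig:
    span: float = 0.7
    iterations: int = 3
    method: str = "fast"  # or "pairs"

    def __post_init__(self):
        if not 0 < self.span <= 1:
            raise ValidationError("loess span must be in (0, 1]")
        if self.iterations < 1:
            raise ValidationError("loess iterations must be >= 1")
        if self.method not in ("fast", "pairs"):
            raise ValidationError(f"unknown loess method {self.method!r}")


def _loess_fit(M: np.ndarray, A: np.ndarray, span: float) -> np.ndarray:
    """Degree-1 tricube loess of M on A, evaluated at A."""
    if np.ptp(A) == 0:  # constant abscissa: fitted trend is the mean
        return np.full_like(M, M.mean())
    return lowess(M, A, frac=span, it=0, return_sorted=False)


def cyclic_loess(m: AntigenMatrix, cfg: LoessConfig = LoessConfig()) -> AntigenMatrix:
    """Cyclic loess normalization of a post-NCF log2 matrix."""
    if m.stage != "ncf":
        raise ValidationError(f"cyclic_loess expects stage ncf, got {m.stage}")
    X = m.masked_values().to_numpy(dtype=float).copy()
    n_ag, n_s = X.shape
    for j in range(n_s):
        if np.isfinite(X[:, j]).sum() < 10:
            raise ValidationError(
                f"sample {m.sample_ids[j]!r} has fewer than 10 valid antigens"
            )
    if cfg.method == "fast":
        for _ in range(cfg.iterations):
            ref = np.nanmean(X, axis=1)
            for j in range(n_s):
                obs = np.isfinite(X[:, j]) & np.isfinite(ref)
                if obs.sum() < 10:
                    raise ValidationError(
                        f"fewer than 10 shared valid antigens for sample "
                        f"{m.sample_ids[j]!r}"
                    )
                Mj = X[obs, j] - ref[obs]
                Aj = (X[obs, j] + ref[obs]) / 2.0
                X[obs, j] -= _loess_fit(Mj, Aj, cfg.span)
    else:  # pairs
        for _ in range(cfg.iterations):
            for j in range(n_s):
                for k in range(j + 1, n_s):
                    obs = np.isfinite(X[:, j]) & np.isfinite(X[:, k])
                    if obs.sum() < 10:
                        raise ValidationError(
                            "fewer than 10 shared valid antigens between "
                            f"samples {m.sample_ids[j]!r} and {m.sample_ids[k]!r}"
                        )
                    Mjk = X[obs, j] - X[obs, k]
                    Ajk = (X[obs, j] + X[obs, k]) / 2.0
                    fit = _loess_fit(Mjk, Ajk, cfg.span)
                    X[obs, j] -= fit / 2.0
                    X[obs, k] += fit / 2.0
    values = pd.DataFrame(
        np.where(np.isfinite(X), X, m.values.to_numpy()),
        index=m.antigen_ids, columns=m.sample_ids,
    )
    return m.advance(values, "loess")


@dataclass
class BatchModel:
    """Estimated and shrunk batch effects plus their EB hyperparameters."""

    batches: list[str]
    gamma_hat: pd.DataFrame  # batch x antigen, raw location effects (standardized scale)
    gamma_star: pd.DataFrame  # after EB shrinkage
    delta2_hat: pd.DataFrame  # raw scale effects
    delta2_star: pd.DataFrame
    gamma_bar: pd.Series = None  # per batch: prior mean of gamma
    tau2: pd.Series = None  # per batch: prior variance of gamma
    a_prior: pd.Series = None  # per batch: inverse-gamma shape
    b_prior: pd.Series = None  # per batch: inverse-gamma scale
    var_pooled: pd.Series = None  # per antigen

    def summary(self) -> pd.DataFrame:
        rows = []
        for b in self.batches:
            rows.append(
                {
                    "batch": b,
                    "gamma_star_mean": float(self.gamma_star.loc[b].mean()),
                    "gamma_star_sd": float(self.gamma_star.loc[b].std()),
                    "delta2_star_mean": float(self.delta2_star.loc[b].mean()),
                    "gamma_bar": float(self.gamma_bar[b]),
                    "tau2": float(self.tau2[b]),
                    "a_prior": float(self.a_prior[b]),
                    "b_prior": float(self.b_prior[b]),
                }
            )
        return pd.DataFrame(rows)


def _design_from_manifest(manifest: pd.DataFrame, protect) -> np.ndarray:
    cols = []
    if "group" in protect:
        groups = pd.get_dummies(manifest["group"], drop_first=True)
        cols.append(groups.to_numpy(dtype=float))
    if "age" in protect:
        age = manifest["age"].to_numpy(dtype=float)
        cols.append((age - age.mean())[:, None])
    if "sex" in protect:
        cols.append((manifest["sex"] == "M").to_numpy(dtype=float)[:, None])
    if "diabetes" in protect:
        cols.append(manifest["diabetes"].to_numpy(dtype=float)[:, None])
    if not cols:
        return np.empty((len(manifest), 0))
    C = np.hstack(cols)
    # constant covariates (e.g. a single-sex cohort) carry no information and
    # would only fake a rank deficiency against the batch intercepts
    keep = C.std(axis=0) > 0
    return C[:, keep]


def eb_batch_correct(
    m: AntigenMatrix,
    manifest: pd.DataFrame,
    protect=("group", "age", "sex", "diabetes"),
    conv: float = 1e-4,
    max_iter: int = 200,
) -> tuple[AntigenMatrix, BatchModel | None]:
    """Parametric empirical-Bayes batch correction of run-year effects.

    The protected covariates are kept in the standardization design so that
    biological group differences are not absorbed into the batch estimates.
    With a single batch the matrix is returned unchanged (stage still
    advanced).  A batch perfectly confounded with group raises an error.
    """
    if m.stage != "loess":
        raise ValidationError(f"eb_batch_correct expects stage loess, got {m.stage}")
    manifest = manifest.loc[m.sample_ids]
    batch = manifest["batch"].astype(str)
    batches = list(pd.unique(batch))
    if len(batches) == 1:
        return m.advance(m.values.copy(), "batch_corrected"), None
    sizes = batch.value_counts()
    if (sizes < 2).any():
        small = sizes.index[sizes < 2].tolist()
        raise ValidationError(f"batch(es) with fewer than 2 samples: {small}")

    B = pd.get_dummies(batch)[batches].to_numpy(dtype=float)  # n x n_batch
    C = _design_from_manifest(manifest, protect)  # n x p
    X = np.hstack([B, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # most common cause: a batch containing exactly one group level
        tab = pd.crosstab(batch, manifest["group"])
        raise ValidationError(
            "batch design is confounded with protected covariates "
            f"(rank deficient); batch x group table:\n{tab}"
        )

    Y = m.masked_values().to_numpy(dtype=float).T  # samples x antigens
    obs = np.isfinite(Y)
    if not obs.all():
        # complete-case per antigen would fragment the EB pooling; impute
        # missing cells at the antigen mean for estimation, restore mask after
        col_mean = np.nanmean(Y, axis=0)
        Y = np.where(obs, Y, col_mean[None, :])

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    n_batch = len(batches)
    n = Y.shape[0]
    batch_frac = (sizes[batches] / n).to_numpy()
    grand = batch_frac @ beta[:n_batch]  # weighted intercept per antigen
    resid = Y - X @ beta
    var_pooled = (resid**2).sum(axis=0) / n
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = grand[None, :] + C @ beta[n_batch:]
    Z = (Y - stand_mean) / np.sqrt(var_pooled)[None, :]

    gamma_hat = np.empty((n_batch, Y.shape[1]))
    delta2_hat = np.empty_like(gamma_hat)
    idx_per_batch = []
    for bi, b in enumerate(batches):
        idx = np.nonzero((batch == b).to_numpy())[0]
        idx_per_batch.append(idx)
        gamma_hat[bi] = Z[idx].mean(axis=0)
        delta2_hat[bi] = Z[idx].var(axis=0, ddof=1)
    delta2_hat = np.maximum(delta2_hat, 1e-12)

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    d_mean = delta2_hat.mean(axis=1)
    d_var = delta2_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = (2 * d_var + d_mean**2) / d_var
        b_prior = (d_mean * d_var + d_mean**3) / d_var

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    for bi in range(n_batch):
        idx = idx_per_batch[bi]
        n_b = len(idx)
        g, d2 = gamma_hat[bi].copy(), delta2_hat[bi].copy()
        if not np.isfinite(a_prior[bi]) or not np.isfinite(b_prior[bi]) or tau2[bi] <= 0:
            # degenerate prior (e.g. identical variances): no shrinkage
            gamma_star[bi], delta2_star[bi] = g, d2
            continue
        Zb = Z[idx]
        sum2_base = ((Zb - Zb.mean(axis=0)) ** 2).sum(axis=0)
        for _ in range(max_iter):
            g_new = (n_b * tau2[bi] * gamma_hat[bi] + d2 * gamma_bar[bi]) / (
                n_b * tau2[bi] + d2
            )
            sum2 = ((Zb - g_new[None, :]) ** 2).sum(axis=0)
            d2_new = (0.5 * sum2 + b_prior[bi]) / (n_b / 2.0 + a_prior[bi] - 1.0)
            change = max(
                np.max(np.abs(g_new - g) / (np.abs(g) + 1e-12)),
                np.max(np.abs(d2_new - d2) / (np.abs(d2) + 1e-12)),
            )
            g, d2 = g_new, d2_new
            if change < conv:
                break
        gamma_star[bi], delta2_star[bi] = g, d2

    Z_adj = Z.copy()
    for bi in range(n_batch):
        idx = idx_per_batch[bi]
        Z_adj[idx] = (Z[idx] - gamma_star[bi][None, :]) / np.sqrt(delta2_star[bi])[None, :]
    Y_adj = Z_adj * np.sqrt(var_pooled)[None, :] + stand_mean

    values = pd.DataFrame(Y_adj.T, index=m.antigen_ids, columns=m.sample_ids)
    # keep previously-masked cells at their original placeholder values
    values = values.where(m.valid, m.values)
    model = BatchModel(
        batches=batches,
        gamma_hat=pd.DataFrame(gamma_hat, index=batches, columns=m.antigen_ids),
        gamma_star=pd.DataFrame(gamma_star, index=batches, columns=m.antigen_ids),
        delta2_hat=pd.DataFrame(delta2_hat, index=batches, columns=m.antigen_ids),
        delta2_star=pd.DataFrame(delta2_star, index=batches, columns=m.antigen_ids),
        gamma_bar=pd.Series(gamma_bar, index=batches),
        tau2=pd.Series(tau2, index=batches),
        a_prior=pd.Series(a_prior, index=batches),
        b_prior=pd.Series(b_prior, index=batches),
        var_pooled=pd.Series(var_pooled, index=m.antigen_ids),
    )
    return m.advance(values, "batch_corrected"), model
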