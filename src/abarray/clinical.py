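"""Clinical-score association: MoCA utilities and Spearman screening.

The Montreal Cognitive Assessment (MoCA, 0–30) gets one added point for
participants with ≤ 6th-grade formal education (capped at 30); an adjusted
score ≤ 26 indicates cognitive impairment.  Autoantibody levels are screened
against MoCA by Spearman rank correlation across the MCI + dementia samples,
with mid-ranks for ties, a t-approximation p-value for n ≥ 10 and an exact
permutation p-value for small n.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .core import AntigenMatrix, ValidationError

__all__ = ["MocaScore", "moca_adjust", "spearman", "correlate_with_moca"]

EXACT_N_MAX = 9


@dataclass(frozen=True)
class MocaScore:
    raw: int
    adjusted: int
    impaired: bool


def moca_adjust(raw: int, low_education: bool) -> MocaScore:
    """Education-adjusted MoCA score and impairment call (adjusted ≤ 26)."""
    if not 0 <= raw <= 30:
        raise ValidationError(f"MoCA raw score {raw} outside [0, 30]")
    adjusted = min(raw + 1, 30) if low_education else raw
    return MocaScore(raw=int(raw), adjusted=int(adjusted), impaired=adjusted <= 26)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties.

    rho is the Pearson correlation of the mid-ranks.  The p-value uses the
    exact permutation distribution for n ≤ 9 and the t-approximation
    otherwise.  Requires ≥ 5 paired non-missing values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 5:
        raise ValidationError(f"spearman needs >= 5 paired values, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValidationError("spearman undefined for a constant argument")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_N_MAX:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        with np.errstate(divide="ignore"):
            t = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p over all orderings of one rank vector."""
    n = len(rx)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    count = 0
    total = 0
    ry_arr = np.array(ry_c)
    for perm in permutations(range(n)):
        r = float(rx_c @ ry_arr[list(perm)]) / denom
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def correlate_with_moca(
    m: AntigenMatrix,
    manifest: pd.DataFrame,
    rho_min: float = 0.27,
    alpha: float = 0.05,
    groups: tuple[str, ...] = ("MCI", "dementia"),
    adjust_education: bool = True,
) -> pd.DataFrame:
    """Spearman screen of every antigen against MoCA in the impaired groups.

    Returns one row per antigen (rho, p, n, passes_filter), sorted by rho;
    ``passes_filter`` requires |rho| ≥ rho_min and p < alpha.  Controls are
    excluded by default, as are samples with missing MoCA.
    """
    sub = manifest[manifest["group"].isin(groups) & manifest["moca_raw"].notna()]
    sub = sub.loc[sub.index.intersection(m.sample_ids)]
    if len(sub) < 5:
        raise ValidationError("fewer than 5 samples with MoCA in the selected groups")
    if adjust_education:
        moca = np.array(
            [
                moca_adjust(int(r), bool(e)).adjusted
                for r, e in zip(sub["moca_raw"], sub["low_education"])
            ],
            dtype=float,
        )
    else:
        moca = sub["moca_raw"].to_numpy(dtype=float)
    vals = m.masked_values()[sub.index]
    rows = []
    for aid, series in vals.iterrows():
        v = series.to_numpy(dtype=float)
        ok = np.isfinite(v)
        if ok.sum() < 5 or np.ptp(v[ok]) == 0:
            continue
        rho, p = spearman(v, moca)
        rows.append({"antigen_id": aid, "rho": rho, "p": p, "n": int(ok.sum())})
    out = pd.DataFrame(rows).set_index("antigen_id")
    out["passes_filter"] = (out["rho"].abs() >= rho_min) & (out["p"] < alpha)
    out["sign"] = np.where(out["rho"] < 0, "negative", "positive")
    return out.sort_values("rho")
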