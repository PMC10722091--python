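"""Over-representation analysis of differential-antigen protein sets.

One-sided Fisher exact (hypergeometric upper tail) test of a query antigen
set against user-supplied gene sets (GMT), Benjamini–Hochberg corrected
across sets.  The default universe is the post-NCF array panel, not the
proteome: the array's composition is the correct background for antigens
that could have been called differential.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ValidationError

__all__ = ["fisher_enrich", "bh_adjust", "panel_annotation_share"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrich(query, gene_sets: dict[str, set[str]], universe,
                  fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    ``query`` must be a subset of ``universe``; set members outside the
    universe are ignored (they could never be drawn).  Returns one row per
    set: k (hits), K (set size in universe), n (query size), N (universe
    size), p (one-sided upper tail), fdr; sorted by fdr then p.
    """
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise ValidationError(
            f"query antigens not in universe: {sorted(stray)[:10]}"
        )
    N, n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        members_u = members & universe
        K = len(members_u)
        k = len(members_u & query)
        if K == 0:
            continue
        # P(X >= k), X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["fdr"] < fdr_alpha
        out = out.sort_values(["fdr", "p"]).reset_index(drop=True)
    return out


def panel_annotation_share(n_annotated: int, n_panel: int) -> int:
    """Percent of panel proteins carrying an annotation, integer-rounded.

    E.g. 201 annotated of a 1,609-protein panel → 12 (%).
    """
    if not 0 <= n_annotated <= n_panel or n_panel <= 0:
        raise ValidationError("need 0 <= n_annotated <= n_panel, n_panel > 0")
    return int(round(100.0 * n_annotated / n_panel))
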