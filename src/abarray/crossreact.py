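"""Cross-reactivity screen for differential autoantibodies.

Two antibodies whose array signals are highly correlated may be a single
antibody species binding two antigens that share sequence.  The screen takes
the Pearson correlation matrix of the differential antigens, aligns every
pair above an ``r`` threshold with a Needleman–Wunsch global alignment
(BLOSUM62, gap open 10, extend 0.5) and reports percent identity over the
full alignment length (gap columns included).  Pairs at or above the
identity threshold are verdicted ``possible_crossreactivity``; correlated
pairs of unrelated sequence are ``likely_biological``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .core import AntigenMatrix, ValidationError

__all__ = ["correlation_matrix", "global_align_identity", "crossreact_screen"]


def correlation_matrix(m: AntigenMatrix, antigens) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix of the given antigens across samples."""
    antigens = [a for a in antigens if a in m.antigen_ids]
    if len(antigens) < 2:
        raise ValidationError("correlation matrix needs >= 2 antigens")
    vals = m.masked_values().loc[antigens]
    corr = vals.T.corr(method="pearson")
    return corr


def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align_identity(seq_a: str, seq_b: str, matrix: str = "BLOSUM62",
                          gap_open: float = 10.0, gap_extend: float = 0.5,
                          denominator: str = "alignment") -> float:
    """Percent identity of a global pairwise protein alignment.

    ``denominator`` is ``alignment`` (full alignment length, gaps included —
    the stricter convention, default) or ``shorter`` (length of the shorter
    sequence).  Non-amino-acid characters raise an error.
    """
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alphabet = set(str(aligner.substitution_matrix.alphabet)) - {"*"}
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValidationError(f"{name} is empty")
        bad = set(seq.upper()) - alphabet
        if bad:
            raise ValidationError(f"{name} contains non-amino-acid characters: {sorted(bad)}")
    if denominator not in ("alignment", "shorter"):
        raise ValidationError(f"unknown identity denominator {denominator!r}")
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    identities = aln.counts().identities
    if denominator == "alignment":
        denom = aln.length
    else:
        denom = min(len(seq_a), len(seq_b))
    return 100.0 * identities / denom


def crossreact_screen(corr: pd.DataFrame, sequences: dict[str, str],
                      r_threshold: float = 0.7, identity_threshold: float = 28.0,
                      **align_kwargs) -> pd.DataFrame:
    """Align every unordered antigen pair with correlation above threshold.

    Only pairs exceeding ``r_threshold`` are ever aligned.  Pairs lacking a
    sequence are reported with NaN identity and verdict ``no_sequence``.
    """
    if not corr.index.equals(corr.columns):
        raise ValidationError("correlation matrix must be square and labeled")
    rows = []
    ids = list(corr.index)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            r = float(corr.at[a, b])
            if not r > r_threshold:
                continue
            if a in sequences and b in sequences:
                ident = global_align_identity(sequences[a], sequences[b], **align_kwargs)
                verdict = (
                    "possible_crossreactivity"
                    if ident >= identity_threshold
                    else "likely_biological"
                )
            else:
                ident, verdict = np.nan, "no_sequence"
            rows.append(
                {
                    "antigen_a": a,
                    "antigen_b": b,
                    "pearson_r": r,
                    "identity_percent": ident,
                    "verdict": verdict,
                }
            )
    return pd.DataFrame(
        rows, columns=["antigen_a", "antigen_b", "pearson_r", "identity_percent", "verdict"]
    )
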