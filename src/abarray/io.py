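"""Readers and writers for the external formats the pipeline touches.

* GPR — GenePix-results dialect: free-form ``key=value`` header lines
  (optionally ATF-style, quoted) followed by a tab-delimited spot table.
  Column names vary across scanner-software versions, so the required set is
  configurable via :class:`GprColumns`.
* GAL-style layout — tab-delimited antigen_id / control class / replicate
  count.
* Sample manifest — CSV.
* Protein FASTA — via Biopython.
* GMT gene sets — tab-delimited name, description, members.

All writers are bit-stable: identical input produces identical bytes.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    CONTROL_CLASSES,
    ArrayLayout,
    FormatError,
    ValidationError,
    validate_manifest,
)

__all__ = [
    "GprColumns",
    "read_gpr",
    "write_gpr",
    "read_layout",
    "write_layout",
    "read_manifest",
    "write_manifest",
    "read_fasta",
    "write_fasta",
    "read_gmt",
    "write_gmt",
]

SPOT_COLUMNS = ("sample_id", "antigen_id", "replicate_index", "fg_median", "bg_median", "flag")


@dataclass(frozen=True)
class GprColumns:
    """Column names of the spot table inside a GPR file."""

    id: str = "ID"
    fg: str = "F532 Median"
    bg: str = "B532 Median"
    flag: str = "Flags"

    @property
    def required(self) -> tuple[str, ...]:
        return (self.id, self.fg, self.bg, self.flag)


def _read_text(path) -> str:
    data = Path(path).read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def read_gpr(path, layout: ArrayLayout, columns: GprColumns = GprColumns(),
             sample_id: str | None = None) -> pd.DataFrame:
    """Read one GPR file into a spot table (one row per printed spot).

    Header lines are consumed until the column-name row (the first line whose
    tab-split fields contain every required column).  Spots with a negative
    scanner flag are marked invalid but retained; antigen ids absent from the
    layout are rejected.  ``sample_id`` defaults to a ``Sample=`` header entry
    or the file stem.
    """
    text = _read_text(path)
    lines = text.splitlines()
    header_meta: dict[str, str] = {}
    table_start = None
    for i, line in enumerate(lines):
        fields = [f.strip().strip('"') for f in line.rstrip("\n").split("\t")]
        if all(c in fields for c in columns.required):
            table_start = i
            break
        for f in fields:
            if "=" in f:
                k, _, v = f.partition("=")
                header_meta[k.strip().strip('"')] = v.strip().strip('"')
    if table_start is None:
        missing = columns.required
        raise FormatError(
            f"{path}: no column-name row with required columns {list(missing)} found"
        )
    body = "\n".join(lines[table_start:])
    df = pd.read_csv(_io.StringIO(body), sep="\t")
    df.columns = [str(c).strip().strip('"') for c in df.columns]
    for col in columns.required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    if sample_id is None:
        sample_id = header_meta.get("Sample", Path(path).stem)

    out = pd.DataFrame(
        {
            "sample_id": sample_id,
            "antigen_id": df[columns.id].astype(str).str.strip(),
            "fg_median": pd.to_numeric(df[columns.fg], errors="raise"),
            "bg_median": pd.to_numeric(df[columns.bg], errors="raise"),
            "flag": pd.to_numeric(df[columns.flag], errors="raise").astype(int),
        }
    )
    unknown = set(out["antigen_id"]) - set(layout.antigen_ids)
    if unknown:
        raise FormatError(f"{path}: antigen ids not in layout: {sorted(unknown)[:5]}")
    if (out["fg_median"] < 0).any() or (out["bg_median"] < 0).any():
        raise ValidationError(f"{path}: negative RFU value")

    # replicate index by order of appearance within each antigen
    out["replicate_index"] = out.groupby("antigen_id").cumcount() + 1
    counts = out.groupby("antigen_id").size()
    expected = layout.table["n_replicates"]
    mismatch = counts.reindex(expected.index).fillna(0).astype(int) != expected
    if mismatch.any():
        bad = expected.index[mismatch].tolist()
        raise FormatError(
            f"{path}: replicate count mismatch vs layout for: {bad[:5]}"
        )
    # GenePix convention: negative flags mark bad/absent spots
    out["valid"] = out["flag"] >= 0
    return out[["sample_id", "antigen_id", "replicate_index", "fg_median", "bg_median", "flag", "valid"]]


def write_gpr(path, spots: pd.DataFrame, columns: GprColumns = GprColumns(),
              sample_id: str | None = None, meta: dict[str, str] | None = None) -> None:
    """Write a spot table for one sample as a GPR-dialect file."""
    if sample_id is None:
        ids = spots["sample_id"].unique()
        if len(ids) != 1:
            raise ValueError("write_gpr expects spots of exactly one sample")
        sample_id = str(ids[0])
    header = {"Type": "GenePix Results 3", "Sample": sample_id}
    header.update(meta or {})
    lines = ["ATF\t1.0", f"{len(header)}\t{4}"]
    lines += [f'"{k}={v}"' for k, v in header.items()]
    lines.append("\t".join([columns.id, columns.fg, columns.bg, columns.flag]))
    for row in spots.itertuples(index=False):
        lines.append(
            f"{row.antigen_id}\t{_fmt(row.fg_median)}\t{_fmt(row.bg_median)}\t{int(row.flag)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _fmt(x) -> str:
    f = float(x)
    return str(int(f)) if f == int(f) else repr(f)


# ---------------------------------------------------------------------------
# GAL-style layout


def read_layout(path) -> ArrayLayout:
    """Read a GAL-style layout: antigen_id, control_class, n_replicates."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("antigen_id", "control_class", "n_replicates"):
        if col not in df.columns:
            raise FormatError(f"{path}: layout missing column {col!r}")
    bad = ~df["control_class"].isin(CONTROL_CLASSES)
    if bad.any():
        raise FormatError(
            f"{path}: unknown control class(es) {df.loc[bad, 'control_class'].unique().tolist()}"
        )
    classes = dict(zip(df["antigen_id"].astype(str), df["control_class"]))
    if len(classes) != len(df):
        raise ValidationError(f"{path}: duplicate antigen ids in layout")
    reps = dict(zip(df["antigen_id"].astype(str), df["n_replicates"].astype(int)))
    return ArrayLayout.from_classes(classes, reps)


def write_layout(path, layout: ArrayLayout) -> None:
    lines = ["antigen_id\tcontrol_class\tn_replicates"]
    for aid in layout.antigen_ids:
        lines.append(
            f"{aid}\t{layout.control_class(aid)}\t{layout.n_replicates_of(aid)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Manifest


def read_manifest(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: manifest file is empty") from None
    return validate_manifest(df)


def write_manifest(path, manifest: pd.DataFrame) -> None:
    cols = ["sample_id", "group", "age", "sex", "diabetes", "batch", "moca_raw", "low_education"]
    out = manifest.reset_index(drop=True)[cols]
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences keyed by record id; sequences uppercased."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets; empty sets are skipped with a warning."""
    sets: dict[str, set[str]] = {}
    for line in _read_text(path).splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}: GMT line with fewer than 2 fields: {line!r}")
        name = fields[0]
        members = {m for m in fields[2:] if m.strip()}
        if not members:
            warnings.warn(f"GMT set {name!r} has no members; skipped", stacklevel=2)
            continue
        if name in sets:
            raise ValidationError(f"{path}: duplicate gene-set name {name!r}")
        sets[name] = members
    return sets


def write_gmt(path, sets: dict[str, set[str]], descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, members in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
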