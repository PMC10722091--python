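"""Core data model for autoantibody protein-microarray analysis.

The pipeline operates on three containers:

* :class:`ArrayLayout` — the printed content of one array: which features are
  analytes, buffer-only negative controls, Cy3-BSA scaling controls or
  biotinylated-IgG positive controls, and how many technical replicate spots
  each feature has.
* :class:`SampleManifest`-validated clinical table (kept as a DataFrame).
* :class:`AntigenMatrix` — antigens x samples matrix of log2 net intensities
  carrying a validity mask and a provenance ``stage`` tag that can only move
  forward through the processing order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "GROUPS",
    "CONTROL_CLASSES",
    "ArrayLayout",
    "AntigenMatrix",
    "validate_manifest",
    "ValidationError",
    "FormatError",
]

#: processing stages in their mandatory order
STAGES = ("net", "consensus", "scaled", "ncf", "loess", "batch_corrected")

GROUPS = ("control", "MCI", "dementia")

CONTROL_CLASSES = ("analyte", "negative", "cy3_bsa", "igg_pos")

MANIFEST_COLUMNS = (
    "sample_id",
    "group",
    "age",
    "sex",
    "diabetes",
    "batch",
    "moca_raw",
    "low_education",
)


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class ArrayLayout:
    """Feature annotation of one array design.

    ``table`` is indexed by antigen id with boolean columns
    ``is_negative_control``, ``is_cy3_bsa_control``, ``is_igg_positive_control``
    and integer ``n_replicates``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate antigen ids in layout: {dups[:5]}")
        if (t["n_replicates"] < 2).any():
            bad = t.index[t["n_replicates"] < 2].tolist()
            raise ValidationError(f"n_replicates < 2 for: {bad[:5]}")
        flags = t[["is_negative_control", "is_cy3_bsa_control", "is_igg_positive_control"]]
        if (flags.sum(axis=1) > 1).any():
            raise ValidationError("a feature may belong to at most one control class")

    # -- accessors ---------------------------------------------------------
    @property
    def antigen_ids(self) -> pd.Index:
        return self.table.index

    @property
    def analyte_ids(self) -> pd.Index:
        t = self.table
        mask = ~(
            t["is_negative_control"]
            | t["is_cy3_bsa_control"]
            | t["is_igg_positive_control"]
        )
        return t.index[mask]

    @property
    def negative_control_ids(self) -> pd.Index:
        return self.table.index[self.table["is_negative_control"]]

    @property
    def cy3_bsa_ids(self) -> pd.Index:
        return self.table.index[self.table["is_cy3_bsa_control"]]

    @property
    def igg_positive_ids(self) -> pd.Index:
        return self.table.index[self.table["is_igg_positive_control"]]

    def n_replicates_of(self, antigen_id: str) -> int:
        return int(self.table.at[antigen_id, "n_replicates"])

    @property
    def n_spots_per_array(self) -> int:
        return int(self.table["n_replicates"].sum())

    def control_class(self, antigen_id: str) -> str:
        row = self.table.loc[antigen_id]
        if row["is_negative_control"]:
            return "negative"
        if row["is_cy3_bsa_control"]:
            return "cy3_bsa"
        if row["is_igg_positive_control"]:
            return "igg_pos"
        return "analyte"

    def require_control_classes(self) -> None:
        """The full pipeline needs at least one negative and one Cy3-BSA feature."""
        if len(self.negative_control_ids) == 0:
            raise ValidationError("layout has no negative-control features")
        if len(self.cy3_bsa_ids) == 0:
            raise ValidationError("layout has no Cy3-BSA control features")

    @classmethod
    def from_classes(
        cls, classes: dict[str, str], n_replicates: int | dict[str, int] = 4
    ) -> "ArrayLayout":
        """Build a layout from an ``antigen_id -> control_class`` mapping."""
        ids = list(classes)
        if isinstance(n_replicates, int):
            reps = [n_replicates] * len(ids)
        else:
            reps = [n_replicates[a] for a in ids]
        for a, c in classes.items():
            if c not in CONTROL_CLASSES:
                raise ValidationError(f"unknown control class {c!r} for {a}")
        table = pd.DataFrame(
            {
                "is_negative_control": [classes[a] == "negative" for a in ids],
                "is_cy3_bsa_control": [classes[a] == "cy3_bsa" for a in ids],
                "is_igg_positive_control": [classes[a] == "igg_pos" for a in ids],
                "n_replicates": reps,
            },
            index=pd.Index(ids, name="antigen_id"),
        )
        return cls(table)


@dataclass
class AntigenMatrix:
    """Antigens x samples matrix of log2 intensities with validity mask.

    ``stage`` records provenance and may only advance along :data:`STAGES`.
    Values are required to be finite wherever ``valid`` is True.
    """

    values: pd.DataFrame
    valid: pd.DataFrame
    stage: str = "net"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if not self.values.index.equals(self.valid.index) or not self.values.columns.equals(
            self.valid.columns
        ):
            raise ValidationError("values and valid mask must share index/columns")
        vals = self.values.to_numpy(dtype=float)
        mask = self.valid.to_numpy(dtype=bool)
        if not np.isfinite(vals[mask]).all():
            raise ValidationError("non-finite value in a valid cell")

    @property
    def antigen_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def masked_values(self) -> pd.DataFrame:
        """Values with invalid cells set to NaN."""
        return self.values.where(self.valid)

    def advance(self, new_values: pd.DataFrame, stage: str,
                new_valid: pd.DataFrame | None = None) -> "AntigenMatrix":
        """Return a successor matrix; the stage must move forward."""
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise ValidationError(
                f"stage transition {self.stage!r} -> {stage!r} is not forward"
            )
        valid = self.valid if new_valid is None else new_valid
        valid = valid.loc[new_values.index, new_values.columns]
        return AntigenMatrix(new_values, valid.copy(), stage)

    def subset_antigens(self, ids) -> "AntigenMatrix":
        return replace(
            self, values=self.values.loc[ids], valid=self.valid.loc[ids]
        )

    def subset_samples(self, ids) -> "AntigenMatrix":
        return replace(
            self, values=self.values[list(ids)], valid=self.valid[list(ids)]
        )


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample manifest and coerce its column types.

    Required columns: sample_id, group (control/MCI/dementia), age, sex (F/M),
    diabetes (bool), batch, moca_raw (0-30 or missing), low_education (bool).
    Raises :class:`ValidationError` listing every offending row.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing required column(s): {missing}")
    if len(df) == 0:
        raise ValidationError("manifest is empty")
    df = df.copy()
    problems: list[str] = []
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        problems.append(f"duplicate sample ids: {dups}")
    bad_group = ~df["group"].isin(GROUPS)
    for i in df.index[bad_group]:
        problems.append(f"row {i}: unknown group {df.at[i, 'group']!r}")
    bad_sex = ~df["sex"].isin(("F", "M"))
    for i in df.index[bad_sex]:
        problems.append(f"row {i}: unknown sex {df.at[i, 'sex']!r}")
    moca = pd.to_numeric(df["moca_raw"], errors="coerce")
    out_of_range = moca.notna() & ((moca < 0) | (moca > 30))
    for i in df.index[out_of_range]:
        problems.append(f"row {i}: MoCA {df.at[i, 'moca_raw']} outside [0, 30]")
    # a non-numeric non-empty entry is also an error
    raw_present = df["moca_raw"].notna() & (df["moca_raw"].astype(str).str.strip() != "")
    unparsed = raw_present & moca.isna()
    for i in df.index[unparsed]:
        problems.append(f"row {i}: MoCA {df.at[i, 'moca_raw']!r} not a number")
    if problems:
        raise ValidationError("manifest validation failed: " + "; ".join(problems))
    df["moca_raw"] = moca
    for col in ("diabetes", "low_education"):
        if df[col].dtype != bool:
            df[col] = (
                df[col]
                .astype(str)
                .str.strip()
                .str.lower()
                .map({"true": True, "1": True, "false": False, "0": False})
            )
            if df[col].isna().any():
                raise ValidationError(f"manifest column {col} not boolean-coded")
            df[col] = df[col].astype(bool)
    df["age"] = pd.to_numeric(df["age"])
    df["batch"] = df["batch"].astype(str)
    return df.set_index("sample_id", drop=False)
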