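"""Readers and writers for the tabular artifacts of a plate-based screen.

All tables are RFC-4180 CSV, UTF-8, header required, nulls encoded as empty
fields.  Writers use a fixed column order and format floats to 6 significant
digits so that re-running a pipeline reproduces files byte-for-byte.

Well coordinates are 0-based ``(row, col)`` with ``(0, 0)`` the top-left well
(``A1`` in plate-reader notation); :func:`well_name` / :func:`well_index`
convert between the two conventions.
"""

from __future__ import annotations

import string

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "WELL_TYPES",
    "WELL_COLUMNS",
    "well_name",
    "well_index",
    "read_well_table",
    "write_well_table",
    "validate_well_table",
    "read_library",
    "write_library",
    "read_annotations",
    "write_annotations",
    "annotation_sets",
    "read_promiscuity",
    "write_promiscuity",
    "read_dose_table",
    "write_dose_table",
]


class SchemaError(ValueError):
    """A table violates its schema; the message names the offending row/column."""


WELL_TYPES = frozenset({"neutral", "positive", "compound", "empty"})

WELL_COLUMNS = [
    "plate_id",
    "row",
    "col",
    "well_type",
    "compound_id",
    "concentration_uM",
    "raw_signal",
    "replicate_id",
]

DOSE_COLUMNS = ["compound_id", "assay_context", "concentration_uM", "response", "viability"]

_FLOAT_FMT = "%.6g"


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> plate-reader well name, e.g. (0, 0) -> 'A1'."""
    if row < 0 or col < 0:
        raise ValueError(f"negative well index ({row}, {col})")
    letters = string.ascii_uppercase
    if row < 26:
        prefix = letters[row]
    else:  # 1536-well plates use AA..AF for rows 26..31
        prefix = letters[row // 26 - 1] + letters[row % 26]
    return f"{prefix}{col + 1}"


def well_index(name: str) -> tuple[int, int]:
    """Plate-reader well name -> 0-based (row, col), e.g. 'P24' -> (15, 23)."""
    name = name.strip().upper()
    i = 0
    while i < len(name) and name[i].isalpha():
        i += 1
    if i == 0 or i > 2 or not name[i:].isdigit() or int(name[i:]) < 1:
        raise ValueError(f"malformed well name {name!r}")
    row = 0
    for ch in name[:i]:
        row = row * 26 + (ord(ch) - ord("A") + 1)
    return row - 1, int(name[i:]) - 1


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def validate_well_table(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` if any record violates the well-table contract."""
    _require_columns(df, WELL_COLUMNS, "well table")
    bad_type = ~df["well_type"].isin(WELL_TYPES)
    if bad_type.any():
        i = int(np.flatnonzero(bad_type.to_numpy())[0])
        raise SchemaError(
            f"well table row {i}: unknown well_type {df['well_type'].iloc[i]!r}"
        )
    sig = pd.to_numeric(df["raw_signal"], errors="coerce")
    if sig.isna().any():
        i = int(np.flatnonzero(sig.isna().to_numpy())[0])
        raise SchemaError(f"well table row {i}: non-numeric raw_signal")
    if (sig < 0).any():
        i = int(np.flatnonzero((sig < 0).to_numpy())[0])
        raise SchemaError(f"well table row {i}: negative raw_signal {sig.iloc[i]}")
    is_compound = df["well_type"] == "compound"
    has_id = df["compound_id"].notna() & (df["compound_id"].astype(str) != "")
    orphan = is_compound & ~has_id
    if orphan.any():
        i = int(np.flatnonzero(orphan.to_numpy())[0])
        raise SchemaError(f"well table row {i}: compound well lacks compound_id")
    labelled_control = ~is_compound & has_id
    if labelled_control.any():
        i = int(np.flatnonzero(labelled_control.to_numpy())[0])
        raise SchemaError(
            f"well table row {i}: {df['well_type'].iloc[i]} well carries a compound_id"
        )


def _canonical_wells(df: pd.DataFrame) -> pd.DataFrame:
    out = df.loc[:, WELL_COLUMNS].copy()
    out["plate_id"] = out["plate_id"].astype(str)
    out["replicate_id"] = out["replicate_id"].astype(str)
    out["row"] = out["row"].astype(np.int64)
    out["col"] = out["col"].astype(np.int64)
    out["raw_signal"] = out["raw_signal"].astype(float)
    out["concentration_uM"] = pd.to_numeric(out["concentration_uM"], errors="coerce")
    out["compound_id"] = out["compound_id"].where(
        out["compound_id"].notna() & (out["compound_id"].astype(str) != ""), None
    )
    return out.reset_index(drop=True)


def read_well_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plate_id": str, "replicate_id": str, "compound_id": str})
    validate_well_table(df)
    return _canonical_wells(df)


def write_well_table(df: pd.DataFrame, path) -> None:
    validate_well_table(df)
    _canonical_wells(df).to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="")


LIBRARY_COLUMNS = ["compound_id", "pubchem_cid", "screen_concentration_uM"]


def read_library(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"compound_id": str})
    _require_columns(df, ["compound_id"], "library table")
    if df["compound_id"].duplicated().any():
        i = int(np.flatnonzero(df["compound_id"].duplicated().to_numpy())[0])
        raise SchemaError(f"library row {i}: duplicate compound_id {df['compound_id'].iloc[i]!r}")
    return df


def write_library(df: pd.DataFrame, path) -> None:
    cols = [c for c in LIBRARY_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.loc[:, cols].to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="")


def read_annotations(path, library: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a long-format term -> member table (columns ``term, compound_id``).

    Duplicate (term, compound) pairs are rejected; if ``library`` is given,
    members absent from it are rejected too.
    """
    df = pd.read_csv(path, dtype={"term": str, "compound_id": str})
    _require_columns(df, ["term", "compound_id"], "annotation table")
    dup = df.duplicated(subset=["term", "compound_id"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise SchemaError(
            f"annotation row {i}: duplicate pair "
            f"({df['term'].iloc[i]!r}, {df['compound_id'].iloc[i]!r})"
        )
    if library is not None:
        known = set(library["compound_id"])
        unknown = ~df["compound_id"].isin(known)
        if unknown.any():
            i = int(np.flatnonzero(unknown.to_numpy())[0])
            raise SchemaError(
                f"annotation row {i}: member {df['compound_id'].iloc[i]!r} not in library"
            )
    return df.reset_index(drop=True)


def write_annotations(df: pd.DataFrame, path) -> None:
    df.loc[:, ["term", "compound_id"]].to_csv(path, index=False)


def annotation_sets(df: pd.DataFrame) -> dict[str, list[str]]:
    """Long-format annotation table -> {term: [member compound ids]}."""
    return {t: sorted(g["compound_id"]) for t, g in df.groupby("term", sort=True)}


PROMISCUITY_COLUMNS = ["compound_id", "n_assays_tested", "n_assays_hit"]


def read_promiscuity(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"compound_id": str})
    _require_columns(df, PROMISCUITY_COLUMNS, "promiscuity table")
    for c in ("n_assays_tested", "n_assays_hit"):
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any() or (vals < 0).any() or (vals != vals.round()).any():
            i = int(
                np.flatnonzero(
                    (vals.isna() | (vals < 0) | (vals != vals.round())).to_numpy()
                )[0]
            )
            raise SchemaError(f"promiscuity row {i}: {c} must be a non-negative integer")
        df[c] = vals.astype(np.int64)
    over = df["n_assays_hit"] > df["n_assays_tested"]
    if over.any():
        i = int(np.flatnonzero(over.to_numpy())[0])
        raise SchemaError(
            f"promiscuity row {i}: n_assays_hit {df['n_assays_hit'].iloc[i]} exceeds "
            f"n_assays_tested {df['n_assays_tested'].iloc[i]}"
        )
    return df.loc[:, PROMISCUITY_COLUMNS].reset_index(drop=True)


def write_promiscuity(df: pd.DataFrame, path) -> None:
    df.loc[:, PROMISCUITY_COLUMNS].to_csv(path, index=False)


def read_dose_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"compound_id": str, "assay_context": str})
    _require_columns(df, ["compound_id", "concentration_uM", "response"], "dose table")
    if "assay_context" not in df.columns:
        df["assay_context"] = "default"
    if "viability" not in df.columns:
        df["viability"] = np.nan
    conc = pd.to_numeric(df["concentration_uM"], errors="coerce")
    bad = conc.isna() | (conc <= 0)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"dose table row {i}: non-positive concentration_uM")
    return df.loc[:, DOSE_COLUMNS].reset_index(drop=True)


def write_dose_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in DOSE_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="")
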