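"""On-disk formats for tables, sample sheets and simulation truth.

TSV is the canonical matrix format (CSV is accepted on read; the delimiter
is inferred from the extension). Peptide tables carry ``peptide_id`` as the
first column and ``protein_id`` as the second; protein tables carry
``protein_id`` first; the remaining columns are sample ids. Blank cells are
read back as missing values (NaN), *not* as zero — the fold-change pairing
logic treats the two differently.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .synthio import SimTruth

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_truth",
]

SHEET_COLUMNS = ["sample_id", "group", "cohort", "replicate", "dfi_days"]


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a peptide or protein abundance matrix.

    Parameters
    ----------
    path : str or Path
        TSV (default) or CSV file with a header row.
    kind : {"peptide", "protein"}
        Table flavour; controls the expected id columns.

    Raises :class:`DataError` on duplicate ids or negative abundances, with
    the offending rows named. Blank cells become NaN (absent), never zero.
    """
    if kind not in ("peptide", "protein"):
        raise DataError(f"kind must be 'peptide' or 'protein', got {kind!r}")
    df = pd.read_csv(path, sep=_sep(path))
    id_col = "peptide_id" if kind == "peptide" else "protein_id"
    if df.columns[0] != id_col:
        raise DataError(
            f"{kind} table must start with a {id_col!r} column, found {df.columns[0]!r}"
        )
    if kind == "peptide" and (len(df.columns) < 2 or df.columns[1] != "protein_id"):
        raise DataError("peptide table must carry protein_id as its second column")
    dup = df[id_col][df[id_col].duplicated()]
    if len(dup):
        raise DataError(f"duplicate {id_col}(s): {sorted(set(dup))}")
    df = df.set_index(id_col)
    df.index = df.index.astype(str)
    value_cols = [c for c in df.columns if c != "protein_id"]
    for c in value_cols:
        df[c] = pd.to_numeric(df[c], errors="raise")
    vals = df[value_cols].to_numpy(dtype=float)
    if np.any(vals < 0):
        rows = df.index[np.any(vals < 0, axis=1)].tolist()
        raise DataError(f"negative abundance in row(s) {rows}")
    return df


def write_matrix(tbl: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix as TSV/CSV; missing values become blank cells."""
    tbl.to_csv(path, sep=_sep(path), na_rep="")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet CSV; requires sample_id and group columns."""
    df = pd.read_csv(path)
    missing = {"sample_id", "group"} - set(df.columns)
    if missing:
        raise DataError(f"sample sheet lacks required column(s): {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise DataError(f"duplicate sample_id(s): {sorted(set(dup))}")
    for col in SHEET_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[SHEET_COLUMNS]


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Serialize a simulation truth record as JSON."""
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2))
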