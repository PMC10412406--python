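"""Readers and writers for delimited expression matrices and survival tables.

Expression files are TSV or CSV (delimiter chosen from the extension) with a
header row of feature IDs and a first column of sample IDs; empty cells or the
token ``NA`` denote missing values. Survival tables have the columns
``sample_id``, ``observed_time``, ``event``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .data import OmicsMatrix, SurvivalOutcome

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_survival_table",
    "write_survival_table",
]

MISSING_TOKENS = ("", "NA", "NaN", "nan")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(
    path: str | Path, omics_label: str = "gene", transpose: bool = False
) -> OmicsMatrix:
    """Read a samples x features expression matrix from TSV/CSV.

    Parameters
    ----------
    path : path
        Delimited text file; ``.csv`` is comma-separated, anything else tab.
    omics_label : str
        Label stored on the returned :class:`OmicsMatrix`.
    transpose : bool
        Set for files that store features in rows and samples in columns.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if len(rows) < 2 or len(rows[0]) < 2:
        raise ValueError(f"{path}: expected a header row and at least one data row")
    header = [c.strip() for c in rows[0][1:]]
    row_ids: list[str] = []
    values = np.empty((len(rows) - 1, len(header)), dtype=float)
    for r, row in enumerate(rows[1:], start=1):
        if len(row) != len(header) + 1:
            raise ValueError(f"{path}: row {r + 1} has {len(row)} fields, expected {len(header) + 1}")
        row_ids.append(row[0].strip())
        for c, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell in MISSING_TOKENS:
                values[r - 1, c] = np.nan
            else:
                try:
                    values[r - 1, c] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at data row {r}, column "
                        f"{header[c]!r}"
                    ) from None
    if transpose:
        values = values.T
        row_ids, header = header, row_ids
    # OmicsMatrix enforces id uniqueness and shape invariants
    return OmicsMatrix(values, sample_ids=row_ids, feature_ids=header, omics_label=omics_label)


def write_expression_matrix(X: OmicsMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.feature_ids)
    df.to_csv(path, sep=_sep_for(path), na_rep="NA", index_label="sample_id")


def read_survival_table(path: str | Path) -> SurvivalOutcome:
    """Read a survival table with columns sample_id, observed_time, event."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"sample_id", "observed_time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df["observed_time"].isna().any() or df["event"].isna().any():
        raise ValueError(f"{path}: missing values in observed_time/event are not allowed")
    return SurvivalOutcome(
        time=df["observed_time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(),
        sample_ids=df["sample_id"].astype(str).tolist(),
    )


def write_survival_table(outcome: SurvivalOutcome, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "sample_id": outcome.sample_ids,
            "observed_time": outcome.time,
            "event": outcome.event,
        }
    ).to_csv(path, sep=_sep_for(path), index=False)
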