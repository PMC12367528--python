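"""Delimited-text table I/O.

All pipeline artifacts are plain delimited text with a header row; subject-level
tables carry a ``subject_id`` key column. Floats are written with 12 significant
digits so that write -> read round-trips are stable to 1e-12 relative error and
repeated runs produce byte-identical files.
"""

from __future__ import annotations

import os

import pandas as pd

from .errors import DataError

FLOAT_FORMAT = "%.12g"


def _detect_sep(path: str) -> str:
    """Choose between tab and comma by inspecting the header line."""
    with open(path, "r") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    # single-column file: delimiter irrelevant
    return "\t"


def read_table(
    path: str,
    required_columns: list[str] | None = None,
    sep: str | None = None,
    subject_key: str | None = None,
) -> pd.DataFrame:
    """Read a delimited table, auto-detecting tab vs comma unless ``sep`` is given.

    Parameters
    ----------
    path:
        File to read.
    required_columns:
        Columns that must be present; missing ones raise :class:`DataError`.
    sep:
        Explicit delimiter; overrides auto-detection.
    subject_key:
        If given, this column must exist and contain unique values.
    """
    if sep is None:
        sep = _detect_sep(path)
    table = pd.read_csv(path, sep=sep)
    if required_columns:
        missing = [c for c in required_columns if c not in table.columns]
        if missing:
            raise DataError(f"{path}: missing required columns {missing}")
    if subject_key is not None:
        if subject_key not in table.columns:
            raise DataError(f"{path}: missing subject key column {subject_key!r}")
        dup = table[subject_key][table[subject_key].duplicated()]
        if len(dup) > 0:
            raise DataError(
                f"{path}: duplicated subject ids {sorted(set(dup))[:5]}"
            )
    return table


def write_table(table: pd.DataFrame, path: str, sep: str = "\t") -> None:
    """Write ``table`` as delimited text (no index column)."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    table.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)
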