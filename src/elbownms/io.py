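"""Time-series file I/O: CSV and OpenSim-style .sto/.mot tables.

Both dialects carry a leading ``time`` column.  CSV is a plain header
row plus comma-separated values.  The storage (.sto) / motion (.mot)
dialect carries free-form header lines terminated by ``endheader``,
then a tab-delimited table whose first column is ``time``.  Floats are
written with 17 significant digits so a write-read round trip is
bit-exact.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_timeseries", "write_timeseries", "TimeSeriesFormatError"]

_FLOAT_FMT = "%.17g"


class TimeSeriesFormatError(ValueError):
    """Malformed or unrecognized time-series file."""


def _validate(table: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    if table.columns.empty or table.columns[0] != "time":
        raise TimeSeriesFormatError(
            f"{path}: first column must be 'time' "
            "(CSV header row or .sto column-name line)"
        )
    if table.isna().any().any():
        raise TimeSeriesFormatError(f"{path}: ragged rows or non-numeric cells")
    t = table["time"].to_numpy(dtype=float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise TimeSeriesFormatError(f"{path}: time column must be strictly increasing")
    return table


def _read_sto(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    header: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.strip().lower() == "endheader":
                break
            header.append(line.rstrip("\n"))
        else:
            raise TimeSeriesFormatError(f"{path}: no 'endheader' line found")
        body = fh.read()
    table = pd.read_csv(_io.StringIO(body), sep="\t", float_precision="round_trip")
    return table, header


def read_timeseries(
    path: str | Path, dialect: str | None = None
) -> tuple[pd.DataFrame, dict]:
    """Read a time-series table; returns ``(table, metadata)``.

    ``dialect`` is 'csv' or 'sto'; by default it is inferred from the
    file suffix (.sto/.mot -> sto, .csv -> csv).  Metadata holds the
    preserved .sto header lines, if any.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        if suffix in (".sto", ".mot"):
            dialect = "sto"
        elif suffix == ".csv":
            dialect = "csv"
        else:
            raise TimeSeriesFormatError(
                f"{path}: unknown dialect for suffix '{suffix}'; expected "
                ".csv (comma-separated, 'time' first) or .sto/.mot "
                "(header lines, 'endheader', tab-delimited)"
            )
    if dialect == "csv":
        table = pd.read_csv(path, float_precision="round_trip")
        meta: dict = {}
    elif dialect == "sto":
        table, header = _read_sto(path)
        meta = {"header": header}
    else:
        raise TimeSeriesFormatError(f"unknown dialect {dialect!r}")
    return _validate(table, path), meta


def write_timeseries(
    table: pd.DataFrame,
    path: str | Path,
    dialect: str | None = None,
    header: list[str] | None = None,
) -> None:
    """Write a time-series table as CSV or .sto/.mot.

    The .sto dialect writes ``header`` lines (default: name and shape)
    followed by ``endheader`` and the tab-delimited table.
    """
    path = Path(path)
    _validate(table, path)
    if dialect is None:
        dialect = "sto" if path.suffix.lower() in (".sto", ".mot") else "csv"
    if dialect == "csv":
        table.to_csv(path, index=False, float_format=_FLOAT_FMT)
        return
    if dialect != "sto":
        raise TimeSeriesFormatError(f"unknown dialect {dialect!r}")
    lines = header if header is not None else [
        path.stem,
        f"nRows={len(table)}",
        f"nColumns={table.shape[1]}",
    ]
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
        fh.write("endheader\n")
    table.to_csv(path, index=False, sep="\t", float_format=_FLOAT_FMT, mode="a")
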