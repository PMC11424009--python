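"""Readers/writers for motion-storage text formats (.sto/.mot) and CSV.

The storage dialect is: free-form header lines (``key=value`` or a bare
name) terminated by ``endheader``, then a tab/whitespace-delimited column
header row whose first column is ``time``, then the numeric matrix.  Angles
can be flagged ``inDegrees=yes`` and converted to radians on request.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MotionTable", "read_motion_file", "write_motion_file"]


@dataclass
class MotionTable:
    """A named time-series table: first column is time, s."""

    name: str
    columns: tuple
    data: np.ndarray                   # (n_rows, n_cols)
    in_degrees: bool = False
    header: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.columns) != self.data.shape[1]:
            raise ValueError("column count does not match data width")
        if self.columns[0] != "time":
            raise ValueError("first column must be 'time'")
        if np.any(np.diff(self.data[:, 0]) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("missing or non-finite cells")

    @property
    def time(self):
        return self.data[:, 0]

    def column(self, name):
        return self.data[:, self.columns.index(name)]

    def to_radians(self) -> "MotionTable":
        if not self.in_degrees:
            return self
        d = self.data.copy()
        d[:, 1:] = np.deg2rad(d[:, 1:])
        return MotionTable(self.name, self.columns, d, False, dict(self.header))


class MotionParseError(ValueError):
    def __init__(self, path, line, msg):
        super().__init__(f"{path}:{line}: {msg}")
        self.line = line


def _infer_dialect(path):
    suffix = Path(path).suffix.lower()
    return {"csv": "csv", ".csv": "csv"}.get(suffix, "sto")


def read_motion_file(path, dialect: str | None = None,
                     to_radians: bool = False) -> MotionTable:
    """Parse a .sto/.mot storage file or a CSV into a MotionTable."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "csv":
        df = pd.read_csv(path)
        return MotionTable(path.stem, tuple(df.columns), df.to_numpy())

    lines = path.read_text().splitlines()
    header = {}
    name = path.stem
    i = 0
    end = None
    for i, raw in enumerate(lines):
        s = raw.strip()
        if s.lower() == "endheader":
            end = i
            break
        if "=" in s:
            k, _, v = s.partition("=")
            header[k.strip()] = v.strip()
        elif s and not header:
            name = s
    if end is None:
        raise MotionParseError(path, len(lines), "no 'endheader' line found")
    cols = tuple(lines[end + 1].split())
    if not cols:
        raise MotionParseError(path, end + 2, "missing column header row")
    rows = []
    for j, raw in enumerate(lines[end + 2:], start=end + 3):
        s = raw.strip()
        if not s:
            continue
        parts = s.split()
        if len(parts) != len(cols):
            raise MotionParseError(
                path, j, f"expected {len(cols)} values, got {len(parts)}")
        try:
            rows.append([float(v) for v in parts])
        except ValueError:
            raise MotionParseError(path, j, f"non-numeric value in {parts}")
    if not rows:
        raise MotionParseError(path, end + 3, "no data rows")
    data = np.array(rows)
    declared = header.get("nColumns")
    if declared is not None and int(declared) != len(cols):
        raise MotionParseError(
            path, end + 1, f"header declares {declared} columns, found {len(cols)}")
    declared = header.get("nRows")
    if declared is not None and int(declared) != data.shape[0]:
        raise MotionParseError(
            path, end + 1, f"header declares {declared} rows, found {data.shape[0]}")
    in_deg = header.get("inDegrees", "no").lower() == "yes"
    try:
        table = MotionTable(name, cols, data, in_deg, header)
    except ValueError as err:
        raise MotionParseError(path, end + 3, str(err))
    return table.to_radians() if to_radians else table


def write_motion_file(table: MotionTable, path, comments=()):
    """Write a MotionTable in the storage dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{table.name}\n")
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write(f"version=1\n")
        fh.write(f"nRows={table.data.shape[0]}\n")
        fh.write(f"nColumns={table.data.shape[1]}\n")
        fh.write(f"inDegrees={'yes' if table.in_degrees else 'no'}\n")
        for k, v in table.header.items():
            if k not in ("version", "nRows", "nColumns", "inDegrees"):
                fh.write(f"{k}={v}\n")
        fh.write("endheader\n")
        fh.write("\t".join(table.columns) + "\n")
        for row in table.data:
            fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")
    return path
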