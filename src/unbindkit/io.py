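"""Tabular I/O: time-series tables and PLUMED-dialect COLVAR/HILLS files.

Every stage of the pipeline exchanges data as :class:`TimeSeriesTable`
objects — named real-valued columns on a strictly increasing time axis with
a per-column unit registry and free-form provenance metadata.  On disk the
tables use the whitespace COLVAR dialect (``#! FIELDS time col1 col2 ...``)
so they can be inspected with standard plumed-ecosystem tooling, or plain
CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesTable",
    "ColvarFormatError",
    "read_colvar",
    "write_colvar",
    "read_csv_table",
    "write_csv_table",
    "read_hills",
    "write_hills",
]


class ColvarFormatError(ValueError):
    """Raised when a COLVAR-style file violates the dialect contract."""


@dataclass
class TimeSeriesTable:
    """Named real-valued columns over a strictly increasing time axis.

    Parameters
    ----------
    times:
        Frame time stamps, strictly increasing.
    data:
        Column name -> 1-D array, all of the same length as ``times``.
    units:
        Unit string per column (``"time"`` included).  Columns without an
        explicit entry default to arbitrary units ``"a.u."``.
    meta:
        Provenance metadata (seed, stage name, parameters...).
    """

    times: np.ndarray
    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if len(self.data) != self.times.size:
            raise ValueError(
                f"column length {len(self.data)} != number of times {self.times.size}"
            )
        dt = np.diff(self.times)
        if dt.size and not np.all(dt > 0):
            bad = int(np.argmin(dt > 0)) + 1
            raise ValueError(f"times not strictly increasing at frame {bad}")
        self.units = {"time": self.units.get("time", "ps"), **self.units}
        for col in self.data.columns:
            self.units.setdefault(str(col), "a.u.")

    # -- convenience ------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def columns(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def values(self, names: list[str] | None = None) -> np.ndarray:
        cols = names if names is not None else self.columns
        return self.data[cols].to_numpy()

    @classmethod
    def from_arrays(
        cls,
        times: np.ndarray,
        columns: Mapping[str, np.ndarray],
        units: Mapping[str, str] | None = None,
        meta: Mapping | None = None,
    ) -> "TimeSeriesTable":
        return cls(
            times=np.asarray(times, float),
            data=pd.DataFrame({k: np.asarray(v, float) for k, v in columns.items()}),
            units=dict(units or {}),
            meta=dict(meta or {}),
        )


# -- COLVAR dialect -------------------------------------------------------

def _parse_header(lines: list[str], path: str) -> tuple[list[str], dict[str, str], int]:
    """Return (fields, units, first data-line index)."""
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise ColvarFormatError(f"{path}:1: missing '#! FIELDS' header")
    fields = lines[0].split()[2:]
    if not fields or fields[0] != "time":
        raise ColvarFormatError(f"{path}:1: first field must be 'time'")
    units: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i].startswith("#!"):
        toks = lines[i].split()
        # "#! SET unit_<col> <unit>" carries the unit registry
        if len(toks) >= 4 and toks[1] == "SET" and toks[2].startswith("unit_"):
            units[toks[2][5:]] = toks[3]
        i += 1
    return fields, units, i


def read_colvar(path: str | Path) -> TimeSeriesTable:
    """Read a COLVAR-style whitespace table.

    The file must begin with ``#! FIELDS time col...``; additional ``#! SET
    unit_<col> <unit>`` lines populate the unit registry.  Ragged rows,
    non-numeric entries and non-monotone time stamps are rejected with the
    offending line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    fields, units, start = _parse_header(lines, str(path))
    rows: list[list[float]] = []
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip() or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) != len(fields):
            raise ColvarFormatError(
                f"{path}:{ln}: expected {len(fields)} columns, got {len(toks)}"
            )
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise ColvarFormatError(f"{path}:{ln}: non-numeric entry") from exc
    arr = np.asarray(rows, dtype=float).reshape(len(rows), len(fields))
    times = arr[:, 0]
    if times.size > 1:
        dt = np.diff(times)
        if not np.all(dt > 0):
            bad = int(np.argmin(dt > 0)) + 1 + start + 1
            raise ColvarFormatError(f"{path}:{bad}: non-monotone time stamp")
    data = {f: arr[:, j] for j, f in enumerate(fields) if j > 0}
    return TimeSeriesTable.from_arrays(times, data, units=units, meta={"source": str(path)})


def write_colvar(table: TimeSeriesTable, path: str | Path) -> None:
    """Write a table in the COLVAR dialect (round-trips finite values exactly)."""
    path = Path(path)
    cols = table.columns
    with open(path, "w") as fh:
        fh.write("#! FIELDS time " + " ".join(cols) + "\n")
        for name in ["time", *cols]:
            fh.write(f"#! SET unit_{name} {table.units.get(name, 'a.u.')}\n")
        mat = np.column_stack([table.times, table.values()])
        for row in mat:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_csv_table(path: str | Path, time_column: str = "time") -> TimeSeriesTable:
    df = pd.read_csv(path)
    if time_column not in df.columns:
        raise ColvarFormatError(f"{path}: missing '{time_column}' column")
    times = df[time_column].to_numpy(float)
    data = {c: df[c].to_numpy(float) for c in df.columns if c != time_column}
    return TimeSeriesTable.from_arrays(times, data, meta={"source": str(path)})


def write_csv_table(table: TimeSeriesTable, path: str | Path) -> None:
    df = table.data.copy()
    df.insert(0, "time", table.times)
    df.to_csv(path, index=False)


# -- HILLS dialect --------------------------------------------------------

def write_hills(
    hill_log: np.ndarray, cv_names: list[str], path: str | Path
) -> None:
    """Write a metadynamics hill log as a PLUMED-HILLS-style table.

    ``hill_log`` rows are (time, center..., height).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#! FIELDS time " + " ".join(cv_names) + " height\n")
        for row in np.atleast_2d(np.asarray(hill_log, float)):
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_hills(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a HILLS-style table back as (array, cv_names)."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise ColvarFormatError(f"{path}:1: missing '#! FIELDS' header")
    fields = lines[0].split()[2:]
    if fields[0] != "time" or fields[-1] != "height":
        raise ColvarFormatError(f"{path}:1: hills fields must be time ... height")
    rows = [
        [float(t) for t in line.split()]
        for line in lines[1:]
        if line.strip() and not line.startswith("#")
    ]
    return np.asarray(rows, float).reshape(len(rows), len(fields)), fields[1:-1]
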