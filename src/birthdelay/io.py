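"""CSV schedule input/output, configuration files and run manifests.

Rate tables are plain CSVs with header ``age,rate`` (ages in years,
strictly increasing; rates per year).  On input they are linearly
interpolated onto the model grid and zero-extended beyond the tabulated
age range.  Floats are written with 10 significant digits so repeated
runs produce byte-identical files.
"""

from __future__ import annotations

import csv
import json
import platform
from pathlib import Path

import numpy as np
import yaml

from .grids import AgeGrid
from .rates import RateSchedule

__all__ = [
    "read_rate_csv",
    "read_counts_csv",
    "write_rate_csv",
    "read_config",
    "write_manifest",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.10g"


def _read_table(path, grid: AgeGrid | None, header: tuple[str, str]) -> RateSchedule:
    path = Path(path)
    ages: list[float] = []
    rates: list[float] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            head = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if [c.strip().lower() for c in head] != list(header):
            raise ValueError(
                f"{path}: expected header '{header[0]},{header[1]}', got {head!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(row)}")
            try:
                age, rate = float(row[0]), float(row[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric row {row!r}") from None
            if rate < 0:
                raise ValueError(f"{path}:{lineno}: negative {header[1]} {rate}")
            ages.append(age)
            rates.append(rate)
    if not ages:
        raise ValueError(f"{path}: no data rows")
    a = np.asarray(ages)
    if np.any(np.diff(a) <= 0):
        raise ValueError(f"{path}: ages must be strictly increasing")
    grid = grid or AgeGrid()
    vals = np.interp(grid.nodes, a, np.asarray(rates), left=0.0, right=0.0)
    # zero-extend beyond the tabulated range (np.interp holds endpoints)
    vals[(grid.nodes < a[0]) | (grid.nodes > a[-1])] = 0.0
    return RateSchedule(grid, vals)


def read_rate_csv(path, grid: AgeGrid | None = None) -> RateSchedule:
    """Read an ``age,rate`` CSV onto the model grid (zero outside the table)."""
    return _read_table(path, grid, ("age", "rate"))


def read_counts_csv(path, grid: AgeGrid | None = None) -> RateSchedule:
    """Read an ``age,count`` CSV (an age pyramid) onto the model grid."""
    return _read_table(path, grid, ("age", "count"))


def write_rate_csv(path, schedule: RateSchedule, value_name: str = "rate") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["age", value_name])
        for age, val in zip(schedule.grid.nodes, schedule.values):
            writer.writerow([FLOAT_FORMAT % age, FLOAT_FORMAT % val])


def read_config(path) -> dict:
    """Key-value configuration file (YAML subset: ``key: value`` lines)."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of key: value pairs")
    return cfg


def write_manifest(path, params: dict) -> None:
    """Write a JSON manifest (parameters + versions) next to run outputs."""
    import birthdelay

    meta = {
        "parameters": params,
        "versions": {
            "birthdelay": birthdelay.__version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
    }
    with Path(path).open("w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
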