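"""Plate CSV dialect and result writers shared by synthetic and real data.

Every kinetic/melt assay is represented by two files:

* a **wide data CSV** whose first column is the independent axis (``time_s``
  for kinetic assays, ``temperature_c`` for melts) followed by one column per
  well, and
* a **plate map CSV** with columns ``well, condition, role, dose_a, dose_b,
  replicate`` describing what each well contains.

Roles come from a closed vocabulary: ``sample`` (the condition under study),
``buffer`` (0% reference for dye release), ``detergent_max`` (1% CHAPS, 100%
reference), ``ligand_only`` (free labeled peptide control) and
``vehicle_protein`` (protein + vehicle control).

Vendor exports (Gen5, NanoTemper, ViiA7) vary too much to parse directly;
converting them to this dialect is a one-liner in pandas and keeps one code
path for simulated and measured plates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, PlateMapError

ROLES = frozenset(
    {"sample", "buffer", "detergent_max", "ligand_only", "vehicle_protein"}
)

PLATE_MAP_COLUMNS = ["well", "condition", "role", "dose_a", "dose_b", "replicate"]
PEAKLIST_COLUMNS = ["residue_number", "residue_name", "h_ppm", "n_ppm", "assigned"]

#: Keys every fit-report JSON must carry so results are traceable.
REPORT_KEYS = frozenset({"tool", "version", "seed", "config", "inputs", "results"})


@dataclass
class PlateMap:
    """Well-to-condition mapping for one plate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_MAP_COLUMNS if c not in self.table.columns]
        if missing:
            raise PlateMapError(f"plate map missing columns: {missing}")
        self.table = self.table[PLATE_MAP_COLUMNS].reset_index(drop=True)
        bad_roles = set(self.table["role"]) - ROLES
        if bad_roles:
            raise PlateMapError(
                f"unknown roles {sorted(bad_roles)}; allowed: {sorted(ROLES)}"
            )
        if self.table["well"].duplicated().any():
            dupes = self.table.loc[self.table["well"].duplicated(), "well"].tolist()
            raise PlateMapError(f"duplicate well ids in plate map: {dupes}")

    @property
    def wells(self) -> list[str]:
        return self.table["well"].tolist()

    def wells_for_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise PlateMapError(f"unknown role {role!r}")
        return self.table.loc[self.table["role"] == role, "well"].tolist()

    def wells_for_condition(self, condition: str) -> list[str]:
        return self.table.loc[self.table["condition"] == condition, "well"].tolist()

    def conditions(self, role: str | None = None) -> list[str]:
        t = self.table if role is None else self.table[self.table["role"] == role]
        return list(dict.fromkeys(t["condition"]))

    @classmethod
    def read_csv(cls, path: str | Path) -> "PlateMap":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class Plate:
    """One plate of traces on a shared independent axis.

    ``signals`` columns are well ids; its index is the axis (seconds or °C).
    """

    signals: pd.DataFrame
    plate_map: PlateMap
    axis_name: str = "time_s"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        axis = self.signals.index.to_numpy(dtype=float)
        if axis.size < 2 or np.any(np.diff(axis) <= 0):
            raise DataError(f"{self.axis_name} axis must be strictly increasing")
        unmapped = [w for w in self.signals.columns if w not in set(self.plate_map.wells)]
        if unmapped:
            raise PlateMapError(f"data wells not in plate map: {unmapped}")

    @property
    def axis(self) -> np.ndarray:
        return self.signals.index.to_numpy(dtype=float)

    def well(self, well_id: str) -> np.ndarray:
        return self.signals[well_id].to_numpy(dtype=float)

    def condition_mean(self, condition: str) -> np.ndarray:
        """Mean signal across the replicate wells of one condition."""
        wells = self.plate_map.wells_for_condition(condition)
        if not wells:
            raise PlateMapError(f"condition {condition!r} has no wells")
        return self.signals[wells].mean(axis=1).to_numpy(dtype=float)


def read_plate(
    data_csv: str | Path, plate_map_csv: str | Path, axis_name: str | None = None
) -> Plate:
    """Read a wide data CSV plus its plate map into a :class:`Plate`.

    The first column of the data CSV is the axis; its header is recorded
    (``time_s`` / ``temperature_c``) unless overridden.
    """
    df = pd.read_csv(data_csv)
    if df.shape[1] < 2:
        raise DataError(f"{data_csv}: expected an axis column plus >=1 well column")
    axis_col = df.columns[0]
    df = df.set_index(axis_col)
    # order-independent parse: wells sorted for a canonical layout
    df = df[sorted(df.columns)]
    pm = PlateMap.read_csv(plate_map_csv)
    return Plate(signals=df, plate_map=pm, axis_name=axis_name or axis_col)


def write_plate(plate: Plate, data_csv: str | Path, plate_map_csv: str | Path) -> None:
    out = plate.signals[sorted(plate.signals.columns)].copy()
    out.index.name = plate.axis_name
    out.to_csv(data_csv)
    plate.plate_map.write_csv(plate_map_csv)


def read_peaklist(path: str | Path) -> pd.DataFrame:
    """Read an HSQC peak list CSV (residue_number, residue_name, h_ppm, n_ppm[, assigned])."""
    df = pd.read_csv(path)
    missing = [c for c in PEAKLIST_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise DataError(f"{path}: peak list missing columns {missing}")
    if "assigned" not in df.columns:
        df["assigned"] = ~(df["h_ppm"].isna() | df["n_ppm"].isna())
    df["assigned"] = df["assigned"].astype(bool)
    if df["residue_number"].duplicated().any():
        raise DataError(f"{path}: duplicate residue numbers")
    return df[PEAKLIST_COLUMNS].reset_index(drop=True)


def write_peaklist(df: pd.DataFrame, path: str | Path) -> None:
    df[PEAKLIST_COLUMNS].to_csv(path, index=False)


def read_endpoint_table(path: str | Path) -> pd.DataFrame:
    """Tidy endpoint table: condition, dose_a, dose_b, endpoint_percent."""
    df = pd.read_csv(path)
    required = ["dose_a", "dose_b", "endpoint_percent"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: endpoint table missing columns {missing}")
    return df


def validate_report(report: Mapping) -> None:
    missing = REPORT_KEYS - set(report)
    if missing:
        raise DataError(f"report missing keys: {sorted(missing)}")


def _json_default(obj):
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(
    out_dir: str | Path,
    tables: Mapping[str, pd.DataFrame] | None = None,
    reports: Mapping[str, Mapping] | None = None,
) -> list[Path]:
    """Write tidy CSV tables and JSON fit reports with deterministic layout.

    Reports must carry full provenance (tool, version, seed, config, inputs,
    results); keys are sorted so identical inputs give byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in (tables or {}).items():
        p = out / f"{name}.csv"
        table.to_csv(p, index=False)
        written.append(p)
    for name, report in (reports or {}).items():
        validate_report(report)
        p = out / f"{name}.json"
        p.write_text(
            json.dumps(report, sort_keys=True, indent=2, default=_json_default) + "\n"
        )
        written.append(p)
    return written
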