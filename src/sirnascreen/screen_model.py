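"""Domain types and delimited-text I/O for arrayed 96-well screens.

Coordinate conventions used throughout the package: rows are the
letters A-H and columns the integers 1-12, both as printed on physical
plates.  Compact well strings such as ``"B07"`` or ``"b7"`` are accepted
wherever a well is named.  Plate maps and measurement tables are plain
CSV or TSV (delimiter auto-detected per file); all outputs are TSV.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScreenConfig
from .errors import MeasurementError, PlateMapError, ScreenError

__all__ = [
    "ROWS",
    "WellRole",
    "WellAddress",
    "PlateLayout",
    "read_plate_map",
    "read_measurements",
    "match_layout",
    "write_table",
    "read_table",
    "layouts_to_frame",
]

#: plate rows in order, top to bottom
ROWS: str = "ABCDEFGH"
N_COLUMNS: int = 12

_WELL_RE = re.compile(r"^([A-Ha-h])\s*0?(\d{1,2})$")


class WellRole(str, Enum):
    """What a well contains: a library oligo, a control, or nothing."""

    LIBRARY = "library"
    CONTROL_NT = "control_nt"
    CONTROL_POS = "control_pos"
    EMPTY = "empty"


@dataclass(frozen=True, order=True)
class WellAddress:
    """A single well, addressed by plate, row letter and column number."""

    plate_id: str
    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise PlateMapError(f"row must be one of {ROWS}, got {self.row!r}")
        if not 1 <= int(self.column) <= N_COLUMNS:
            raise PlateMapError(
                f"column must be 1..{N_COLUMNS}, got {self.column!r}"
            )

    @classmethod
    def parse(cls, plate_id: str, well: str) -> "WellAddress":
        """Parse a compact well string such as ``"B07"`` (case-insensitive)."""
        m = _WELL_RE.match(str(well).strip())
        if m is None:
            raise PlateMapError(f"malformed well string: {well!r}")
        return cls(str(plate_id), m.group(1).upper(), int(m.group(2)))

    @property
    def well(self) -> str:
        """Zero-padded compact form, e.g. ``"B07"``."""
        return f"{self.row}{self.column:02d}"


@dataclass
class PlateLayout:
    """Well -> (role, oligo) map for one plate.

    ``wells`` maps ``(row, column)`` to ``(WellRole, oligo_id)``;
    ``oligo_id`` is ``None`` except for library wells.
    """

    plate_id: str
    wells: dict[tuple[str, int], tuple[WellRole, str | None]]

    def role_of(self, row: str, column: int) -> WellRole:
        return self.wells[(row, int(column))][0]

    def nt_wells(self) -> list[tuple[str, int]]:
        """NT-control well coordinates in row order."""
        return sorted(
            k for k, (role, _) in self.wells.items() if role is WellRole.CONTROL_NT
        )

    def validate(self, config: ScreenConfig) -> None:
        """Check the control-column invariants for this layout."""
        nt = 0
        for (row, col), (role, oligo) in self.wells.items():
            if role in (WellRole.CONTROL_NT, WellRole.CONTROL_POS):
                if col != config.control_column:
                    raise PlateMapError(
                        f"plate {self.plate_id}: control well {row}{col:02d} "
                        f"outside control column {config.control_column}"
                    )
                nt += role is WellRole.CONTROL_NT
            elif role is WellRole.LIBRARY and not oligo:
                raise PlateMapError(
                    f"plate {self.plate_id}: library well {row}{col:02d} "
                    "has no oligo_id"
                )
        if nt < 1:
            raise PlateMapError(
                f"plate {self.plate_id}: no non-targeting control wells"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.plate_id, r, c, role.value, oligo)
            for (r, c), (role, oligo) in sorted(self.wells.items())
        ]
        return pd.DataFrame(
            rows, columns=["plate_id", "row", "column", "role", "oligo_id"]
        )


def layouts_to_frame(layouts) -> pd.DataFrame:
    """Concatenate PlateLayout objects (or pass a frame through)."""
    if isinstance(layouts, pd.DataFrame):
        return layouts
    if isinstance(layouts, PlateLayout):
        layouts = {layouts.plate_id: layouts}
    return pd.concat(
        [p.to_frame() for p in layouts.values()], ignore_index=True
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O


def _sniff_sep(path: str | Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_delimited(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScreenError(f"{path}: missing required columns {missing}")
    return df


def _parse_coordinates(df: pd.DataFrame, where: str, err) -> pd.DataFrame:
    """Normalize row/column columns in place; raise on malformed values."""
    rows = df["row"].str.strip().str.upper()
    bad = ~rows.isin(list(ROWS))
    if bad.any():
        raise err(f"{where}: malformed row value(s): "
                  f"{sorted(df.loc[bad, 'row'].unique())[:5]}")
    cols = pd.to_numeric(df["column"], errors="coerce")
    bad = cols.isna() | (cols < 1) | (cols > N_COLUMNS) | (cols % 1 != 0)
    if bad.any():
        raise err(f"{where}: malformed column value(s): "
                  f"{sorted(df.loc[bad, 'column'].unique())[:5]}")
    out = df.copy()
    out["row"] = rows
    out["column"] = cols.astype(int)
    return out


def read_plate_map(
    path: str | Path, config: ScreenConfig | None = None
) -> tuple[dict[str, PlateLayout], pd.DataFrame]:
    """Read a plate map into validated layouts plus library annotation.

    The file must carry the header columns ``plate_id, row, column, role,
    oligo_id, gene_symbol, accession`` (gene_symbol/accession may be blank
    on control and empty wells).  Returns ``(layouts, annotation)`` where
    annotation has one deduplicated row per oligo.

    Raises
    ------
    PlateMapError
        On duplicate wells (named in the message), unknown roles,
        malformed coordinates, library wells without an oligo id, or
        conflicting gene annotation for one oligo.
    """
    config = config or ScreenConfig()
    df = _read_delimited(
        path,
        ["plate_id", "row", "column", "role", "oligo_id", "gene_symbol", "accession"],
    )
    df = _parse_coordinates(df, str(path), PlateMapError)

    valid_roles = {r.value for r in WellRole}
    bad_roles = sorted(set(df["role"]) - valid_roles)
    if bad_roles:
        raise PlateMapError(f"{path}: unknown well role(s): {bad_roles}")

    dup = df.duplicated(subset=["plate_id", "row", "column"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise PlateMapError(
            f"{path}: duplicate well {first['plate_id']} "
            f"{first['row']}{int(first['column']):02d}"
        )

    lib = df["role"] == WellRole.LIBRARY.value
    no_oligo = lib & (df["oligo_id"].str.strip() == "")
    if no_oligo.any():
        first = df[no_oligo].iloc[0]
        raise PlateMapError(
            f"{path}: library well {first['plate_id']} "
            f"{first['row']}{int(first['column']):02d} has no oligo_id"
        )

    layouts: dict[str, PlateLayout] = {}
    for plate_id, grp in df.groupby("plate_id", sort=True):
        wells = {
            (r.row, int(r.column)): (
                WellRole(r.role),
                r.oligo_id if r.role == WellRole.LIBRARY.value else None,
            )
            for r in grp.itertuples()
        }
        layout = PlateLayout(str(plate_id), wells)
        layout.validate(config)
        layouts[str(plate_id)] = layout

    ann = (
        df.loc[lib, ["oligo_id", "gene_symbol", "accession"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    conflict = ann["oligo_id"].duplicated(keep=False)
    if conflict.any():
        raise PlateMapError(
            f"{path}: conflicting annotation for oligo(s) "
            f"{sorted(ann.loc[conflict, 'oligo_id'].unique())[:5]}"
        )
    return layouts, ann


def read_measurements(
    path: str | Path, layouts: dict[str, PlateLayout] | pd.DataFrame | None = None
) -> pd.DataFrame:
    """Read a raw FI measurement table.

    Expected header: ``plate_id, row, column, cell_line, replicate, FI``.
    If ``layouts`` is given, every measurement must join to a layout well;
    orphan wells are reported in the raised error rather than dropped.

    Raises
    ------
    MeasurementError
        On non-numeric or negative FI, malformed coordinates, duplicate
        (well, cell_line, replicate) records, or orphan wells.
    """
    df = _read_delimited(
        path, ["plate_id", "row", "column", "cell_line", "replicate", "FI"]
    )
    df = _parse_coordinates(df, str(path), MeasurementError)

    fi = pd.to_numeric(df["FI"], errors="coerce")
    if fi.isna().any():
        bad = df.loc[fi.isna(), "FI"].iloc[0]
        raise MeasurementError(f"{path}: non-numeric FI value {bad!r}")
    if (fi < 0).any():
        bad = fi[fi < 0].iloc[0]
        raise MeasurementError(f"{path}: negative FI value {bad}")
    rep = pd.to_numeric(df["replicate"], errors="coerce")
    if rep.isna().any() or (rep < 1).any():
        raise MeasurementError(f"{path}: replicate must be an integer >= 1")
    df = df.assign(FI=fi.astype(float), replicate=rep.astype(int))

    key = ["plate_id", "row", "column", "cell_line", "replicate"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise MeasurementError(
            f"{path}: duplicate measurement for {first['plate_id']} "
            f"{first['row']}{int(first['column']):02d} "
            f"{first['cell_line']} rep {first['replicate']}"
        )

    if layouts is not None:
        matched, orphans = match_layout(df, layouts)
        if len(orphans):
            wells = [
                f"{r.plate_id} {r.row}{int(r.column):02d}"
                for r in orphans.head(5).itertuples()
            ]
            raise MeasurementError(
                f"{path}: {len(orphans)} measurement(s) on wells absent from "
                f"the plate map, e.g. {wells}"
            )
        return matched
    return df.reset_index(drop=True)


def match_layout(
    measurements: pd.DataFrame, layouts
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join measurements to layout roles.

    Returns ``(matched, orphans)``: matched rows gain ``role`` and
    ``oligo_id`` columns; orphans are measurement rows with no layout well.
    """
    layout_df = layouts_to_frame(layouts)
    merged = measurements.merge(
        layout_df, on=["plate_id", "row", "column"], how="left", validate="m:1"
    )
    orphan_mask = merged["role"].isna()
    return (
        merged[~orphan_mask].reset_index(drop=True),
        merged[orphan_mask].reset_index(drop=True),
    )


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular result as TSV with a stable column order.

    Real-valued columns are written with 6 significant digits, which the
    matching :func:`read_table` round-trips; text fields round-trip
    bit-identically.  An empty frame yields a header-only file.
    """
    records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
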