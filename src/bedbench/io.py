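"""Delimited-text readers and writers for the three input schemas.

Schemas (UTF-8 CSV with a header row):

* regions — ``region_id,year,population,deaths,occupied_bed_days,
  same_day_admissions,available_beds``; optional cells are left empty, not
  written as zero.
* subgroup panel — long form ``region_id,group,population,deaths`` plus a
  per-region totals file ``region_id,total_occupied_bed_days``.
* monthly deaths — long form ``area_id,month,deaths`` with YYYY-MM months.

Floats are written with 12 significant digits, enough for a write/read
round trip to reproduce generated values to full working precision.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import InvalidInputError, ParseError, RegionRecord
from .decomposition import SubgroupPanelRow
from .volatility import MonthlyDeathSeries

__all__ = [
    "read_regions_csv",
    "write_regions_csv",
    "read_subgroup_panel_csv",
    "write_subgroup_panel_csv",
    "read_monthly_deaths_csv",
    "write_monthly_deaths_csv",
]

FLOAT_FORMAT = "%.12g"

REGION_COLUMNS = [
    "region_id", "year", "population", "deaths",
    "occupied_bed_days", "same_day_admissions", "available_beds",
]


def _read_frame(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    return frame


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_regions_csv(path: str | Path) -> list[RegionRecord]:
    """Read region-year records, collecting row-level errors.

    A file with any invalid row raises :class:`ParseError` whose
    ``row_errors`` lists every offending row and reason, so a malformed
    upload can be fixed in one pass.
    """
    frame = _read_frame(path, ["region_id", "year", "population", "deaths"])
    records: list[RegionRecord] = []
    errors: list[str] = []
    for i, row in frame.iterrows():
        try:
            records.append(
                RegionRecord(
                    region_id=str(row["region_id"]),
                    year=str(row["year"]),
                    population=float(row["population"]),
                    deaths=float(row["deaths"]),
                    occupied_bed_days=_opt(row.get("occupied_bed_days")),
                    same_day_admissions=_opt(row.get("same_day_admissions"))
                    or 0.0,
                    available_beds=_opt(row.get("available_beds")),
                )
            )
        except (InvalidInputError, TypeError, ValueError) as exc:
            errors.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if errors:
        raise ParseError(
            f"{path}: {len(errors)} invalid row(s)", row_errors=errors
        )
    return records


def write_regions_csv(records: Sequence[RegionRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "year": r.year,
                "population": r.population,
                "deaths": r.deaths,
                "occupied_bed_days": r.occupied_bed_days,
                "same_day_admissions": r.same_day_admissions,
                "available_beds": r.available_beds,
            }
            for r in records
        ],
        columns=REGION_COLUMNS,
    )
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_subgroup_panel_csv(
    panel_path: str | Path, totals_path: str | Path
) -> list[SubgroupPanelRow]:
    """Assemble panel rows from the long-form group file plus totals file.

    Group order within each region follows first appearance in the panel
    file and must be identical across regions.
    """
    panel = _read_frame(panel_path, ["region_id", "group", "population", "deaths"])
    totals = _read_frame(totals_path, ["region_id", "total_occupied_bed_days"])
    totals_map = dict(
        zip(totals["region_id"].astype(str),
            totals["total_occupied_bed_days"].astype(float))
    )
    rows: list[SubgroupPanelRow] = []
    errors: list[str] = []
    for region_id, grp in panel.groupby("region_id", sort=False):
        rid = str(region_id)
        if rid not in totals_map:
            errors.append(f"region {rid!r}: no total_occupied_bed_days entry")
            continue
        try:
            rows.append(
                SubgroupPanelRow(
                    region_id=rid,
                    groups=tuple(str(g) for g in grp["group"]),
                    populations=tuple(float(p) for p in grp["population"]),
                    deaths=tuple(float(d) for d in grp["deaths"]),
                    total_occupied_bed_days=totals_map[rid],
                )
            )
        except (InvalidInputError, ValueError) as exc:
            errors.append(f"region {rid!r}: {exc}")
    if errors:
        raise ParseError(
            f"{panel_path}: {len(errors)} invalid region(s)", row_errors=errors
        )
    if not rows:
        raise ParseError(f"{panel_path}: no regions found")
    return rows


def write_subgroup_panel_csv(
    rows: Sequence[SubgroupPanelRow],
    panel_path: str | Path,
    totals_path: str | Path,
) -> None:
    long = pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "group": g,
                "population": p,
                "deaths": d,
            }
            for r in rows
            for g, p, d in zip(r.groups, r.populations, r.deaths)
        ],
        columns=["region_id", "group", "population", "deaths"],
    )
    long.to_csv(panel_path, index=False, float_format=FLOAT_FORMAT)
    totals = pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "total_occupied_bed_days": r.total_occupied_bed_days,
            }
            for r in rows
        ],
        columns=["region_id", "total_occupied_bed_days"],
    )
    totals.to_csv(totals_path, index=False, float_format=FLOAT_FORMAT)


def read_monthly_deaths_csv(path: str | Path) -> list[MonthlyDeathSeries]:
    """Read long-form monthly death series, one per area."""
    frame = _read_frame(path, ["area_id", "month", "deaths"])
    out: list[MonthlyDeathSeries] = []
    errors: list[str] = []
    for area_id, grp in frame.groupby("area_id", sort=False):
        try:
            out.append(
                MonthlyDeathSeries(
                    area_id=str(area_id),
                    months=tuple(str(m) for m in grp["month"]),
                    deaths=tuple(float(d) for d in grp["deaths"]),
                )
            )
        except (InvalidInputError, ValueError) as exc:
            errors.append(f"area {area_id!r}: {exc}")
    if errors:
        raise ParseError(
            f"{path}: {len(errors)} invalid area(s)", row_errors=errors
        )
    if not out:
        raise ParseError(f"{path}: no areas found")
    return out


def write_monthly_deaths_csv(
    collection: Sequence[MonthlyDeathSeries], path: str | Path
) -> None:
    frame = pd.DataFrame(
        [
            {"area_id": s.area_id, "month": m, "deaths": d}
            for s in collection
            for m, d in zip(s.months, s.deaths)
        ],
        columns=["area_id", "month", "deaths"],
    )
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
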