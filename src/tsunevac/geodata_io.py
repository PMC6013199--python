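"""Reading and writing the pipeline's external formats.

Sites (recipients, visiting-nurse stations, welfare shelters) travel as CSV
with planar-metre coordinates; evacuation-timing results travel as CSV in
the case-study table's column order.  The printed input table of the Kochi
case study ships with the package so the whole pipeline can run without any
GIS download.

All coordinates are planar metres in a projected CRS.  Geographic (lon/lat)
input is rejected rather than silently mis-measured; project it first.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "SiteRecord",
    "CaseStudyRow",
    "FormatError",
    "SITE_ROLES",
    "RESULT_COLUMNS",
    "NA_TOKEN",
    "read_sites",
    "write_sites",
    "load_kochi_table",
    "write_results",
    "read_results",
]

NA_TOKEN = "n/a"
SITE_ROLES = ("recipient", "station", "shelter")

#: Result-table columns, mirroring the printed case-study layout:
#: identity and hazard attributes, then the station leg, transfer, shelter
#: leg, total, tsunami arrival, margin, and the delayed-escape flag.
RESULT_COLUMNS = (
    "id",
    "seismic_intensity",
    "max_inundation_m",
    "d_station_m",
    "t_nurse_min",
    "t_transfer_min",
    "d_shelter_m",
    "t_walk_min",
    "t_total_min",
    "t_arrival_min",
    "margin_min",
    "delayed",
)


class FormatError(ValueError):
    """An input file violates the documented CSV/GeoJSON contract."""


@dataclass(frozen=True)
class SiteRecord:
    """A recipient, visiting-nurse station, or welfare evacuation shelter.

    ``x``/``y`` are planar metres.  ``attributes`` carries descriptive
    columns (seismic-intensity band, inundation band, ...) verbatim; the
    model never computes on them.
    """

    id: str
    role: str
    x: float
    y: float
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in SITE_ROLES:
            raise ValueError(f"unknown site role {self.role!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"site {self.id!r}: non-finite coordinates")

    @property
    def location(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class CaseStudyRow:
    """One recipient of the packaged Kochi case-study input table.

    ``arrival_min`` is the predicted time for a 30-cm tsunami flow to reach
    the recipient's assigned welfare shelter; ``None`` marks residents whose
    shelter lies outside every arrival zone.
    """

    recipient_id: str
    d_station: float
    d_shelter: float
    arrival_min: float | None
    max_level_band: str = ""
    seismic_intensity: str = ""

    def __post_init__(self) -> None:
        if self.d_station < 0 or self.d_shelter < 0:
            raise ValueError(f"recipient {self.recipient_id!r}: negative distance")
        if self.arrival_min is not None and not self.arrival_min > 0:
            raise ValueError(f"recipient {self.recipient_id!r}: arrival must be > 0")


def _parse_number(text: str, *, where: str) -> float:
    """Parse a decimal number, tolerating thousands separators ("1,748")."""
    cleaned = text.strip().replace(",", "")
    try:
        return float(cleaned)
    except ValueError:
        raise FormatError(f"{where}: non-numeric value {text!r}") from None


def read_sites(path: str | Path, role: str) -> list[SiteRecord]:
    """Read a site CSV (columns ``id,x,y`` plus free attribute columns).

    A ``role`` column, if present, must match the requested role on every
    row; otherwise the requested role is assigned.  Row order is preserved
    and attribute columns are kept verbatim.
    """
    if role not in SITE_ROLES:
        raise ValueError(f"unknown site role {role!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        missing = {"id", "x", "y"} - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
        attr_cols = [c for c in reader.fieldnames if c not in ("id", "x", "y", "role")]
        records: list[SiteRecord] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):
            rid = (row["id"] or "").strip()
            if not rid:
                raise FormatError(f"{path} row {i}: missing id")
            if rid in seen:
                raise FormatError(f"{path} row {i}: duplicate id {rid!r}")
            seen.add(rid)
            row_role = (row.get("role") or role).strip()
            if row_role != role:
                raise FormatError(
                    f"{path} row {i}: role {row_role!r} does not match requested {role!r}"
                )
            x = _parse_number(row["x"], where=f"{path} row {i} (id {rid!r}) column x")
            y = _parse_number(row["y"], where=f"{path} row {i} (id {rid!r}) column y")
            attrs = {c: (row.get(c) or "") for c in attr_cols}
            records.append(SiteRecord(id=rid, role=role, x=x, y=y, attributes=attrs))
    return records


def write_sites(path: str | Path, sites: Iterable[SiteRecord]) -> None:
    """Write sites to CSV in the format :func:`read_sites` consumes."""
    sites = list(sites)
    attr_cols: list[str] = []
    for s in sites:
        for c in s.attributes:
            if c not in attr_cols:
                attr_cols.append(c)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "role", "x", "y", *attr_cols])
        for s in sites:
            writer.writerow(
                [s.id, s.role, repr(s.x), repr(s.y)]
                + [s.attributes.get(c, "") for c in attr_cols]
            )


def load_kochi_table() -> list[CaseStudyRow]:
    """Load the packaged Kochi case-study input table (21 recipients).

    The table transcribes, per recipient living in the predicted inundation
    area: network distance from the nearest visiting-nurse station, network
    distance to the assigned welfare shelter, the 30-cm tsunami arrival time
    at that shelter (``None`` for the four residents outside the arrival
    field), and the descriptive hazard bands.
    """
    text = (
        resources.files("tsunevac").joinpath("data/kochi_case_study.csv").read_text("utf-8")
    )
    rows: list[CaseStudyRow] = []
    for i, row in enumerate(csv.DictReader(text.splitlines()), start=2):
        arrival_text = row["arrival_min"].strip()
        arrival = (
            None
            if arrival_text == NA_TOKEN
            else _parse_number(arrival_text, where=f"case-study row {i}")
        )
        rows.append(
            CaseStudyRow(
                recipient_id=row["id"].strip(),
                d_station=_parse_number(row["d_station_m"], where=f"case-study row {i}"),
                d_shelter=_parse_number(row["d_shelter_m"], where=f"case-study row {i}"),
                arrival_min=arrival,
                max_level_band=row["max_inundation_m"].strip(),
                seismic_intensity=row["seismic_intensity"].strip(),
            )
        )
    return rows


def _fmt(value: float | None, decimals: int) -> str:
    from .rounding import round_half_away

    if value is None:
        return NA_TOKEN
    return f"{round_half_away(value, decimals):.{decimals}f}"


def write_results(path: str | Path, rows: Iterable["object"]) -> None:
    """Write evacuation-timing rows as CSV in the case-study column order.

    ``rows`` are :class:`tsunevac.planner.EvacuationTiming` (or anything
    with the same attributes).  Times are written at 0.1-minute display
    precision, distances at metre precision; undefined arrival/margin/flag
    cells are rendered as the literal token ``n/a``.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for r in rows:
            delayed = getattr(r, "delayed", None)
            writer.writerow(
                [
                    r.recipient_id,
                    getattr(r, "seismic_intensity", ""),
                    getattr(r, "max_level_band", ""),
                    _fmt(r.d_station, 0),
                    _fmt(r.t_nurse, 1),
                    _fmt(r.t_transfer, 1),
                    _fmt(r.d_shelter, 0),
                    _fmt(r.t_walk, 1),
                    _fmt(r.t_total, 1),
                    _fmt(r.t_arrival, 0),
                    _fmt(r.margin, 1),
                    NA_TOKEN if delayed is None else str(bool(delayed)),
                ]
            )


def read_results(path: str | Path) -> list[dict]:
    """Read a results CSV back into plain dicts (numbers parsed, n/a -> None)."""
    path = Path(path)
    numeric = {
        "d_station_m",
        "t_nurse_min",
        "t_transfer_min",
        "d_shelter_m",
        "t_walk_min",
        "t_total_min",
        "t_arrival_min",
        "margin_min",
    }
    out: list[dict] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != RESULT_COLUMNS:
            raise FormatError(f"{path}: expected columns {RESULT_COLUMNS}")
        for i, row in enumerate(reader, start=2):
            parsed: dict = {}
            for key, value in row.items():
                if key in numeric:
                    parsed[key] = (
                        None
                        if value.strip() == NA_TOKEN
                        else _parse_number(value, where=f"{path} row {i} column {key}")
                    )
                elif key == "delayed":
                    parsed[key] = None if value.strip() == NA_TOKEN else value == "True"
                else:
                    parsed[key] = value
            out.append(parsed)
    return out
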