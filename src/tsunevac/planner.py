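"""Facility assignment and the evacuation time budget.

The model: when the earthquake strikes, a visiting nurse drives from the
network-nearest nursing station to the recipient's home (360 m/min base
speed), transfers the recipient from bed to wheelchair (4.9 min base), and
pushes the wheelchair to the network-nearest welfare evacuation shelter not
sited in a level-3 inundation zone (33.3 m/min base walking speed).  The
margin is the 30-cm tsunami arrival time at the shelter minus that total; a
non-positive margin means the shelter floods before the evacuation
completes — a delayed escape.

Base parameter values come from published surveys of the study region:
average urban car travel speed, measured nurse-assisted transfer time, and
the measured walking speed of someone escorting a person with impaired
mobility just before a tsunami.  Note the walking speed is 33.3 m/min
exactly (the value the case-study table is computed with), not the rounded
1.88 km/h quoted alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .geodata_io import SiteRecord
from .hazard_fields import HazardFields, arrival_time_at, flood_level_at
from .road_network import RoadGraph, shortest_path_lengths, snap_site
from .rounding import round_half_away

__all__ = [
    "ModelParameters",
    "EvacuationPlan",
    "EvacuationTiming",
    "UnassignableError",
    "assign_station",
    "assign_shelter",
    "compute_timing",
    "classify_delayed",
    "plan_evacuations",
]

BARRED_SHELTER_LEVEL = 3  # level-3 zones are too dangerous to walk into


@dataclass(frozen=True)
class ModelParameters:
    """The three time-budget parameters, in metres/minute and minutes."""

    nurse_speed: float = 360.0  # nurse's car, station -> home
    walk_speed: float = 33.3  # wheelchair push, home -> shelter
    transfer_time: float = 4.9  # bed -> wheelchair

    def __post_init__(self) -> None:
        for name in ("nurse_speed", "walk_speed", "transfer_time"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def scaled(
        self, f_nurse_speed: float = 1.0, f_walk_speed: float = 1.0, f_transfer: float = 1.0
    ) -> "ModelParameters":
        return replace(
            self,
            nurse_speed=self.nurse_speed * f_nurse_speed,
            walk_speed=self.walk_speed * f_walk_speed,
            transfer_time=self.transfer_time * f_transfer,
        )


@dataclass(frozen=True)
class EvacuationPlan:
    """Station and shelter assigned to one recipient, with route distances."""

    recipient_id: str
    station_id: str | None
    shelter_id: str | None
    d_station: float | None
    d_shelter: float | None

    @property
    def assigned(self) -> bool:
        return self.shelter_id is not None and self.station_id is not None


@dataclass(frozen=True)
class EvacuationTiming:
    """One row of the evacuation time budget, all at full precision.

    ``margin`` and ``delayed`` are undefined (None) when no 30-cm arrival
    time is predicted for the shelter.  ``delayed`` here uses the base-case
    convention (strictly negative margin); sensitivity tables reclassify at
    integer display granularity via :func:`classify_delayed`.
    """

    recipient_id: str
    d_station: float
    d_shelter: float
    t_nurse: float
    t_transfer: float
    t_walk: float
    t_total: float
    t_arrival: float | None
    margin: float | None
    delayed: bool | None
    seismic_intensity: str = ""
    max_level_band: str = ""


class UnassignableError(RuntimeError):
    """No facility is reachable/eligible for the named recipient."""

    def __init__(self, recipient_id: str, message: str):
        self.recipient_id = recipient_id
        super().__init__(message)


def _nearest_by_network(
    recipient: SiteRecord,
    candidates: Sequence[SiteRecord],
    graph: RoadGraph,
) -> tuple[str, float] | None:
    """(candidate id, network distance) minimising distance; ties -> lowest id."""
    lengths = shortest_path_lengths(graph, snap_site(graph, recipient.location))
    best: tuple[float, str] | None = None
    for site in candidates:
        d = lengths.get(snap_site(graph, site.location))
        if d is None:
            continue
        key = (d, site.id)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[1], best[0]


def assign_station(
    recipient: SiteRecord, stations: Sequence[SiteRecord], graph: RoadGraph
) -> tuple[str, float]:
    """Nearest visiting-nurse station by network distance (ties by id)."""
    if not stations:
        raise ValueError("at least one station is required")
    result = _nearest_by_network(recipient, stations, graph)
    if result is None:
        raise UnassignableError(
            recipient.id, f"no station reachable from recipient {recipient.id!r}"
        )
    return result


def assign_shelter(
    recipient: SiteRecord,
    shelters: Sequence[SiteRecord],
    graph: RoadGraph,
    fields: HazardFields,
) -> tuple[str, float] | None:
    """Nearest eligible welfare shelter by network distance.

    Shelters in a level-3 inundation zone are excluded from candidacy
    entirely — a recipient is sent to the nearest shelter at level 1, 2 or
    outside the inundation area.  Returns ``None`` ("unassignable") when
    every shelter is barred or unreachable.
    """
    if not shelters:
        raise ValueError("at least one shelter is required")
    eligible = [
        s
        for s in shelters
        if flood_level_at(fields, s.location) != BARRED_SHELTER_LEVEL
    ]
    if not eligible:
        return None
    return _nearest_by_network(recipient, eligible, graph)


def compute_timing(
    d_station: float,
    d_shelter: float,
    t_arrival: float | None,
    params: ModelParameters = ModelParameters(),
    *,
    recipient_id: str = "",
    seismic_intensity: str = "",
    max_level_band: str = "",
) -> EvacuationTiming:
    """Evacuation time budget for one recipient, at full precision.

    t_nurse = d_station / nurse_speed; t_walk = d_shelter / walk_speed;
    t_total = t_nurse + transfer + t_walk; margin = t_arrival - t_total.
    Rounding happens only at display.
    """
    if d_station < 0 or d_shelter < 0:
        raise ValueError("distances must be non-negative")
    t_nurse = d_station / params.nurse_speed
    t_walk = d_shelter / params.walk_speed
    t_total = t_nurse + params.transfer_time + t_walk
    margin = None if t_arrival is None else t_arrival - t_total
    return EvacuationTiming(
        recipient_id=recipient_id,
        d_station=float(d_station),
        d_shelter=float(d_shelter),
        t_nurse=t_nurse,
        t_transfer=params.transfer_time,
        t_walk=t_walk,
        t_total=t_total,
        t_arrival=t_arrival,
        margin=margin,
        delayed=None if margin is None else margin < 0,
        seismic_intensity=seismic_intensity,
        max_level_band=max_level_band,
    )


def classify_delayed(
    timing: EvacuationTiming, granularity: str | None = None
) -> bool | None:
    """Delayed-escape classification.

    ``granularity=None`` (base case): delayed iff the full-precision margin
    is strictly negative.  ``granularity="integer"`` (sensitivity tables):
    delayed iff the margin rounded to whole minutes is <= 0 — a displayed
    zero counts as delayed.  Undefined margin -> None.
    """
    if timing.margin is None:
        return None
    if granularity is None:
        return timing.margin < 0
    if granularity == "integer":
        return round_half_away(timing.margin, 0) <= 0
    raise ValueError(f"unknown granularity {granularity!r}")


def plan_evacuations(
    recipients: Sequence[SiteRecord],
    stations: Sequence[SiteRecord],
    shelters: Sequence[SiteRecord],
    graph: RoadGraph,
    fields: HazardFields,
    params: ModelParameters = ModelParameters(),
) -> tuple[list[EvacuationPlan], list[EvacuationTiming]]:
    """Run assignment + timing for every recipient.

    Unassignable recipients produce a plan row with ``None`` facility ids
    and no timing row; the run continues.  The arrival deadline is the
    30-cm arrival time at the *assigned shelter's* location.
    """
    plans: list[EvacuationPlan] = []
    timings: list[EvacuationTiming] = []
    shelter_by_id = {s.id: s for s in shelters}
    for rec in recipients:
        station_id, d_station = assign_station(rec, stations, graph)
        assignment = assign_shelter(rec, shelters, graph, fields)
        if assignment is None:
            plans.append(EvacuationPlan(rec.id, station_id, None, d_station, None))
            continue
        shelter_id, d_shelter = assignment
        plans.append(EvacuationPlan(rec.id, station_id, shelter_id, d_station, d_shelter))
        t_arrival = arrival_time_at(fields, shelter_by_id[shelter_id].location)
        timings.append(
            compute_timing(
                d_station,
                d_shelter,
                t_arrival,
                params,
                recipient_id=rec.id,
                seismic_intensity=rec.attributes.get("seismic_intensity", ""),
                max_level_band=rec.attributes.get("max_inundation_m", ""),
            )
        )
    return plans, timings
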