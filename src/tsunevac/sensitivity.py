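"""One-way and multi-way sensitivity analysis of the evacuation margin.

Four parameters drive the margin: nurse travel speed, bed-to-wheelchair
transfer time, walking (wheelchair) speed, and the tsunami arrival time.
Each is varied to 0.5x and 2.0x its base value — one at a time (one-way)
and in all 16 lower/upper combinations (multi-way, scenarios A-P).

Directionality is parameter-specific: for a *speed*, the adverse end is
slow (x0.5); for a *time budget component* (transfer) adverse is long
(x2.0); for the *deadline* (arrival) adverse is short (x0.5).  Scenario A
is all-adverse, P all-favourable.

Margins in these tables are displayed as whole minutes and a displayed
zero counts as a delayed escape (rounded margin <= 0).  Delayed-escape
percentages are taken over all recipients living in the inundation area,
including those with no predicted arrival time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .geodata_io import CaseStudyRow
from .planner import ModelParameters, compute_timing
from .rounding import round_half_away

__all__ = [
    "ScenarioFactors",
    "SensitivityReport",
    "PARAMETER_NAMES",
    "SCENARIO_LABELS",
    "scenario_grid",
    "apply_factors",
    "one_way",
    "multi_way",
    "count_delayed",
]

PARAMETER_NAMES = ("nurse_speed", "transfer_time", "walk_speed", "arrival_time")

SCENARIO_LABELS = tuple("ABCDEFGHIJKLMNOP")


@dataclass(frozen=True)
class ScenarioFactors:
    """Multipliers applied to the four parameters (base 1.0 each)."""

    f_nurse_speed: float = 1.0
    f_transfer: float = 1.0
    f_walk_speed: float = 1.0
    f_arrival: float = 1.0

    def __post_init__(self) -> None:
        for name in ("f_nurse_speed", "f_transfer", "f_walk_speed", "f_arrival"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def scenario_grid() -> dict[str, ScenarioFactors]:
    """The 16 multi-way scenarios A-P in table order.

    Nesting, outermost to innermost: nurse speed (slow 0.5, fast 2.0);
    transfer time (long 2.0, short 0.5); walk speed (slow 0.5, fast 2.0);
    arrival time (short 0.5, long 2.0).  Hence A = (0.5, 2.0, 0.5, 0.5)
    is the worst case and P = (2.0, 0.5, 2.0, 2.0) the best.
    """
    combos = itertools.product((0.5, 2.0), (2.0, 0.5), (0.5, 2.0), (0.5, 2.0))
    return {
        label: ScenarioFactors(*factors)
        for label, factors in zip(SCENARIO_LABELS, combos)
    }


def apply_factors(
    params: ModelParameters, arrival: float | None, factors: ScenarioFactors
) -> tuple[ModelParameters, float | None]:
    """Scale parameters and the arrival deadline by their factors.

    An undefined arrival stays undefined: residents outside the arrival
    field are outside it in every scenario.
    """
    scaled = params.scaled(
        f_nurse_speed=factors.f_nurse_speed,
        f_walk_speed=factors.f_walk_speed,
        f_transfer=factors.f_transfer,
    )
    return scaled, None if arrival is None else arrival * factors.f_arrival


@dataclass(frozen=True)
class SensitivityReport:
    """Margins and delayed counts for one scenario.

    ``margins`` maps recipient id to the *display* margin in whole minutes
    (half away from zero), ``None`` for recipients outside the arrival
    field.  ``denominator`` is the number of recipients the percentage is
    taken over (everyone in the inundation area).
    """

    scenario: str
    factors: ScenarioFactors
    margins: Mapping[str, float | None]
    exact_margins: Mapping[str, float | None]
    delayed_count: int
    delayed_pct: float
    denominator: int


def _run_scenario(
    rows: Sequence[CaseStudyRow],
    params: ModelParameters,
    factors: ScenarioFactors,
    scenario: str,
) -> SensitivityReport:
    margins: dict[str, float | None] = {}
    exact: dict[str, float | None] = {}
    for row in rows:
        scaled, arrival = apply_factors(params, row.arrival_min, factors)
        timing = compute_timing(
            row.d_station, row.d_shelter, arrival, scaled, recipient_id=row.recipient_id
        )
        exact[row.recipient_id] = timing.margin
        margins[row.recipient_id] = (
            None if timing.margin is None else round_half_away(timing.margin, 0)
        )
    count, pct = count_delayed(margins.values(), denominator=len(rows))
    return SensitivityReport(
        scenario=scenario,
        factors=factors,
        margins=margins,
        exact_margins=exact,
        delayed_count=count,
        delayed_pct=pct,
        denominator=len(rows),
    )


def one_way(
    rows: Sequence[CaseStudyRow],
    params: ModelParameters,
    parameter: str,
    factor: float,
) -> SensitivityReport:
    """Vary one named parameter by ``factor``, holding the others at base."""
    if not rows:
        raise ValueError("at least one recipient row is required")
    if parameter not in PARAMETER_NAMES:
        raise ValueError(
            f"unknown parameter {parameter!r}; expected one of {PARAMETER_NAMES}"
        )
    kwargs = {
        "nurse_speed": "f_nurse_speed",
        "transfer_time": "f_transfer",
        "walk_speed": "f_walk_speed",
        "arrival_time": "f_arrival",
    }
    factors = ScenarioFactors(**{kwargs[parameter]: factor})
    return _run_scenario(rows, params, factors, scenario=f"{parameter} x{factor:g}")


def multi_way(
    rows: Sequence[CaseStudyRow], params: ModelParameters = ModelParameters()
) -> dict[str, SensitivityReport]:
    """All 16 lower/upper combinations of the four parameters (A-P)."""
    if not rows:
        raise ValueError("at least one recipient row is required")
    return {
        label: _run_scenario(rows, params, factors, scenario=label)
        for label, factors in scenario_grid().items()
    }


def count_delayed(
    display_margins: Iterable[float | None], denominator: int | None = None
) -> tuple[int, float]:
    """Delayed count and percentage from display margins.

    Delayed: defined margin <= 0 at display granularity.  The percentage
    denominator defaults to the number of margins supplied (defined or
    not); pass ``denominator`` to fix it explicitly.  Rounded to 0.1.
    """
    margins = list(display_margins)
    if denominator is None:
        denominator = len(margins)
    count = sum(1 for m in margins if m is not None and m <= 0)
    pct = 0.0 if denominator == 0 else round_half_away(100.0 * count / denominator, 1)
    return count, pct
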