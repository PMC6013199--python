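"""Published display values of the Kochi case study, and reproduction checks.

These are the values as printed in the published study report: the base
time-budget table (nurse leg, walk leg, total, margin, all at 0.1-minute
display precision), the one-way delayed counts, and the multi-way
worst/best-case (A/P) margins and counts.

Eight of the printed base margins disagree with the stated margin formula
(arrival minus total) by 1-22.5 minutes; only the nine arithmetically
consistent rows are checked against recomputed margins.  The published
headline of eight base-case delayed escapes is likewise not recoverable
from the formula (which yields seven) and is not checked.  See
docs/methods.md for the analysis.
"""

from __future__ import annotations

from typing import Sequence

from .geodata_io import CaseStudyRow
from .planner import ModelParameters, compute_timing
from .sensitivity import multi_way, one_way

__all__ = [
    "BASE_TABLE_PRINTED",
    "CONSISTENT_MARGIN_IDS",
    "ONE_WAY_PRINTED_COUNTS",
    "MULTI_WAY_PRINTED_COUNTS",
    "MULTI_WAY_PRINTED_MARGINS_AP",
    "check_reproduction",
]

#: id -> (t_nurse, t_walk, t_total, arrival, margin); None where printed "n/a".
BASE_TABLE_PRINTED: dict[str, tuple[float, float, float, float | None, float | None]] = {
    "3": (1.7, 56.8, 63.4, None, None),
    "8": (2.3, 63.8, 71.0, None, None),
    "14": (2.6, 62.9, 70.5, None, None),
    "22": (7.5, 136.4, 148.8, 60, -101.9),
    "27": (3.7, 42.6, 51.2, 60, 7.8),
    "48": (4.9, 40.1, 49.9, 60, 10.1),
    "11": (5.1, 63.4, 73.3, 60, -13.3),
    "18": (2.2, 8.0, 15.1, 50, 34.9),
    "19": (5.7, 61.1, 71.7, 50, -21.7),
    "21": (5.1, 99.8, 109.8, 35, -87.3),
    "29": (2.3, 50.5, 57.7, None, None),
    "30": (3.5, 81.8, 90.2, 35, -67.7),
    "32": (1.8, 19.7, 26.3, 50, 23.7),
    "39": (2.7, 26.0, 33.6, 60, 25.5),
    "46": (2.2, 55.0, 62.0, 60, -4.3),
    "47": (3.1, 14.5, 22.5, 60, 37.5),
    "51": (3.2, 117.4, 125.5, 35, -104.8),
    "5": (2.1, 27.4, 34.4, 50, 15.6),
    "34": (0.2, 15.7, 20.7, 50, 29.3),
    "49": (1.6, 32.3, 38.8, 50, 11.2),
    "50": (5.8, 10.0, 20.7, 35, -8.2),
}

#: The rows whose printed margin equals arrival minus total at display precision.
CONSISTENT_MARGIN_IDS = ("48", "11", "18", "19", "32", "47", "5", "34", "49")

#: (parameter, factor) -> printed delayed count (denominator 21).
ONE_WAY_PRINTED_COUNTS: dict[tuple[str, float], int] = {
    ("nurse_speed", 0.5): 7,
    ("nurse_speed", 2.0): 7,
    ("transfer_time", 2.0): 7,
    ("transfer_time", 0.5): 7,
    ("walk_speed", 0.5): 12,
    ("walk_speed", 2.0): 4,
    ("arrival_time", 0.5): 14,
    ("arrival_time", 2.0): 4,
}

#: scenario label -> printed delayed count.
MULTI_WAY_PRINTED_COUNTS: dict[str, int] = {
    "A": 17, "B": 7, "C": 12, "D": 2, "E": 16, "F": 6, "G": 10, "H": 0,
    "I": 17, "J": 7, "K": 12, "L": 1, "M": 16, "N": 6, "O": 7, "P": 0,
}

#: id -> (scenario A margin, scenario P margin) as printed, whole minutes.
MULTI_WAY_PRINTED_MARGINS_AP: dict[str, tuple[int, int]] = {
    "22": (-268, 46),
    "27": (-72, 94),
    "48": (-70, 95),
    "11": (-117, 83),
    "18": (-5, 92),
    "19": (-118, 64),
    "21": (-202, 15),
    "30": (-163, 25),
    "32": (-28, 87),
    "39": (-37, 103),
    "46": (-94, 89),
    "47": (-15, 109),
    "51": (-233, 7),
    "5": (-44, 83),
    "34": (-16, 90),
    "49": (-53, 81),
    "50": (-24, 60),
}


def check_reproduction(
    rows: Sequence[CaseStudyRow], params: ModelParameters = ModelParameters()
) -> list[tuple[str, bool, str]]:
    """Recompute the case-study tables and compare with the printed values.

    Returns (check name, passed, detail) triples.  Time columns are
    compared at +/-0.05 min (the display precision); counts and integer
    margins exactly.
    """
    checks: list[tuple[str, bool, str]] = []
    timings = {
        r.recipient_id: compute_timing(
            r.d_station, r.d_shelter, r.arrival_min, params,
            recipient_id=r.recipient_id,
        )
        for r in rows
    }

    bad_cols = [
        rid
        for rid, (p_nurse, p_walk, p_total, _, _) in BASE_TABLE_PRINTED.items()
        if rid in timings
        and not (
            abs(timings[rid].t_nurse - p_nurse) <= 0.05
            and abs(timings[rid].t_walk - p_walk) <= 0.05
            and abs(timings[rid].t_total - p_total) <= 0.05
        )
    ]
    checks.append(
        (
            "base time columns, all recipients",
            not bad_cols,
            "all within 0.05 min" if not bad_cols else f"off for ids {bad_cols}",
        )
    )

    bad_margins = [
        rid
        for rid in CONSISTENT_MARGIN_IDS
        if abs(timings[rid].margin - BASE_TABLE_PRINTED[rid][4]) > 0.05
    ]
    checks.append(
        (
            "base margins, consistent rows",
            not bad_margins,
            "all within 0.05 min" if not bad_margins else f"off for ids {bad_margins}",
        )
    )

    bad_counts = []
    for (parameter, factor), printed in ONE_WAY_PRINTED_COUNTS.items():
        got = one_way(rows, params, parameter, factor).delayed_count
        if got != printed:
            bad_counts.append(f"{parameter} x{factor:g}: {got} != {printed}")
    checks.append(
        (
            "one-way delayed counts",
            not bad_counts,
            "all 8 columns match" if not bad_counts else "; ".join(bad_counts),
        )
    )

    reports = multi_way(rows, params)
    bad_multi = [
        f"{label}: {reports[label].delayed_count} != {printed}"
        for label, printed in MULTI_WAY_PRINTED_COUNTS.items()
        if reports[label].delayed_count != printed
    ]
    checks.append(
        (
            "multi-way delayed counts A-P",
            not bad_multi,
            "all 16 scenarios match" if not bad_multi else "; ".join(bad_multi),
        )
    )

    bad_ap = [
        rid
        for rid, (m_a, m_p) in MULTI_WAY_PRINTED_MARGINS_AP.items()
        if reports["A"].margins[rid] != m_a or reports["P"].margins[rid] != m_p
    ]
    checks.append(
        (
            "worst/best-case margins (A, P)",
            not bad_ap,
            "all match" if not bad_ap else f"off for ids {bad_ap}",
        )
    )
    return checks
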