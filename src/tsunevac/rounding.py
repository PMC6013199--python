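"""Display rounding.

All model arithmetic runs at full float precision; rounding happens only
when a value is displayed or classified at display granularity.  The
convention is round-half-away-from-zero (so 7.45 -> 7.5 and -7.45 -> -7.5),
which is the rule the case-study tables follow, not banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away"]


def round_half_away(value: float, decimals: int = 0) -> float:
    """Round ``value`` to ``decimals`` places, ties away from zero.

    Operates on the shortest decimal representation of the float, so values
    that print as exact halves (e.g. ``0.5``, ``44.75``) round away from
    zero regardless of their binary representation.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
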