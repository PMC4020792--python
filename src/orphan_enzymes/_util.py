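"""Shared helpers: half-up rounding and percentage arithmetic."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as printed summary tables do.

    Python's builtin ``round`` is banker's rounding, which disagrees with
    hand-tabulated percentages on exact halves (e.g. 0.125 -> 0.12).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, denominator: int, decimals: int = 2) -> float:
    """100 * count / denominator, half-up rounded."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round_half_up(100.0 * count / denominator, decimals)
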