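"""Rounding and presentation helpers shared by summaries and reports.

Percentages throughout the package are reported the way sequencing
bookkeeping tables conventionally print them: ``100 * part / total``
rounded half-up (not banker's rounding) to a fixed number of decimals.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round ``value`` half-up to ``decimals`` places (0.125 -> 0.13)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percentage(part: float, total: float, decimals: int = 2) -> float:
    """``100 * part / total`` rounded half-up, computed in exact decimal.

    Raises ``ZeroDivisionError`` for ``total == 0`` — an undefined rate is
    an error, not a 0.
    """
    if total == 0:
        raise ZeroDivisionError("percentage undefined for total == 0")
    quantum = Decimal(1).scaleb(-decimals)
    frac = Decimal(100) * Decimal(repr(part)) / Decimal(repr(total))
    return float(frac.quantize(quantum, rounding=ROUND_HALF_UP))


def thousands(n: int) -> str:
    """Format an integer with comma thousands separators (12,009,135)."""
    return f"{int(n):,}"
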