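"""Small shared helpers (rounding, percentages)."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ndigits decimals (banker-free)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_pct(numerator: int, denominator: int, ndigits: int = 1) -> str:
    """Percentage string rounded half-up, e.g. format_pct(328, 608) == '53.9%'."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    pct = round_half_up(100.0 * numerator / denominator, ndigits)
    return f"{pct:.{ndigits}f}%"


def pct_value(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage as a number on the 0-100 scale, rounded half-up."""
    return round_half_up(100.0 * numerator / denominator, ndigits)
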