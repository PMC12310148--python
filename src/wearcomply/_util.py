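"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half-up (0.5 always away from zero toward +inf for positives).

    Python's built-in ``round`` is banker's rounding; reported percentages use
    the conventional half-up rule (86.665 -> 86.67).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
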