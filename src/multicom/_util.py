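"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (``2.5 -> 3``, ``-2.5 -> -3``).

    Python's built-in ``round`` uses banker's rounding; reported percentages
    and summary values use conventional half-up rounding instead.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage rounded half-up; denominator must be positive."""
    if denominator <= 0:
        raise ValueError("percentage of an empty denominator is undefined")
    return round_half_up(100.0 * numerator / denominator, ndigits)
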