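"""Half-up rounding helpers.

Python's built-in ``round`` uses banker's rounding; reported percentages and
means in this package follow the half-up convention instead, so 0.25 -> 0.3
at one decimal and 1174.5 -> 1175 at integer precision. Comparisons against
thresholds are always made on unrounded values; rounding is purely a
reporting step.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` half away from zero at ``ndigits`` decimals."""
    quantum = Decimal(1).scaleb(-ndigits)
    result = float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
    return result


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
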