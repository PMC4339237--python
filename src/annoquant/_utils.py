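"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def percent(numer: int | float, denom: int | float) -> float:
    """Percentage at 0.01 precision, rounded half-up."""
    if denom == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    value = Decimal(str(numer)) * 100 / Decimal(str(denom))
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
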