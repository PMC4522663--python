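"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed summary tables),
    unlike Python's banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage at fixed precision; 0/0 is reported as 0.0."""
    if denominator == 0:
        return 0.0
    return round_half_away(100.0 * numerator / denominator, ndigits)
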