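"""Small shared helpers for report arithmetic."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention used in printed percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, denominator: int, decimals: int = 1) -> float:
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * count / denominator, decimals)
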