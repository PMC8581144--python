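"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (half-up), matching printed-table rounding.

    Python's builtin ``round`` uses banker's rounding; published tables round
    2.285 -> 2.29, so percentages and sizes go through this helper instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
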