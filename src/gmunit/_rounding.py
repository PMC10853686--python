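"""Decimal rounding with half-away-from-zero ties.

Every printed quantity in the GM pipeline (predicted difficulties at two
decimals, anchor constants at two decimals, GM units as integers) is
rounded half away from zero. Values reaching this helper are sums and
products of short decimals, so binary floating-point fuzz is shaved off
with six guard digits before the tie rule is applied.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero."""
    d = Decimal(repr(float(x)))
    d = d.quantize(Decimal(1).scaleb(-(ndigits + 6)), rounding=ROUND_HALF_EVEN)
    return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))
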