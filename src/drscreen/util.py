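"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round *x* half away from zero to *ndigits* decimals.

    Monetary values and rates are rounded this way only at presentation;
    internal arithmetic is kept unrounded.  ``round()`` is unsuitable here
    because banker's rounding sends 0.125 to 0.12.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
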