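"""Shared numeric helpers."""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as yield tables are conventionally printed.

    numpy/python round to even; published percentages (e.g. 22/61 -> 36.1)
    follow the half-up convention, so all externally reported numbers go
    through here.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent_change(v_from: float, v_to: float, ndigits: int | None = 1) -> float:
    """Signed percent change from ``v_from`` to ``v_to``.

    Scale-free: multiplying both values by a constant leaves it unchanged.
    ``ndigits=None`` skips reporting-precision rounding.
    """
    if v_from == 0:
        raise ZeroDivisionError("percent change from a zero base is undefined")
    pct = (v_to - v_from) / v_from * 100.0
    return pct if ndigits is None else round_half_up(pct, ndigits)


def percent_difference(projected: float, actual: float, ndigits: int | None = 1) -> float:
    """Signed percent difference of a projection vs the actual value.

    Convention: (projected - actual) / actual x 100, so a positive value means
    the projection overshoots.
    """
    return percent_change(actual, projected, ndigits)
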