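"""Exact decimal currency arithmetic.

All monetary quantities in this package are carried as :class:`decimal.Decimal`
and rounded to cents (half-up) only at reporting boundaries.  Floats are
converted through their shortest ``repr`` so that e.g. ``0.45`` becomes the
exact decimal ``0.45`` rather than its binary approximation.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

__all__ = ["D", "cents", "money"]

_CENT = Decimal("0.01")


def D(value) -> Decimal:
    """Convert a number to an exact Decimal (floats go via ``repr``)."""
    if isinstance(value, Decimal):
        return value
    if isinstance(value, float):
        return Decimal(repr(value))
    return Decimal(value)


def cents(value) -> Decimal:
    """Round a monetary amount to cents, half-up."""
    return D(value).quantize(_CENT, rounding=ROUND_HALF_UP)


def money(value) -> str:
    """Render an amount with thousands separators and two decimals."""
    return f"${cents(value):,.2f}"
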