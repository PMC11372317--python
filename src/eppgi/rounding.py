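"""Display rounding shared by the frequency tables and metric reports."""

from __future__ import annotations

from fractions import Fraction
from typing import Optional


def round_half_up(value: Fraction, digits: int = 2) -> float:
    """Round an exact rational half-up to ``digits`` decimals."""
    scaled = value * Fraction(10) ** digits
    floor, rem = divmod(scaled.numerator, scaled.denominator)
    if Fraction(rem, scaled.denominator) >= Fraction(1, 2):
        floor += 1
    return floor / 10**digits


def percentage(numerator: int, denominator: int, digits: int = 2) -> Optional[float]:
    """Exact-rational percentage rounded half-up to ``digits`` decimals.

    Returns None when the denominator is zero (undefined, never 0.00).
    """
    if denominator == 0:
        return None
    return round_half_up(Fraction(numerator, denominator) * 100, digits)
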