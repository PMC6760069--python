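"""Decimal rounding helpers.

Reported quantities follow fixed conventions: copies/µl to 3 decimals and
mass concentrations to 2 decimals, rounding half away from zero; the limit
of detection alone rounds upward (ceiling), being the smallest *reportable*
concentration.  Python's built-in round() is banker's rounding, hence these
helpers go through decimal.
"""

from __future__ import annotations

from decimal import ROUND_CEILING, ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "round_ceiling"]


def _quantum(ndigits: int) -> Decimal:
    return Decimal(1).scaleb(-ndigits)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round to `ndigits` decimals, ties away from zero (0.005 -> 0.01)."""
    return float(Decimal(repr(x)).quantize(_quantum(ndigits), rounding=ROUND_HALF_UP))


def round_ceiling(x: float, ndigits: int = 2) -> float:
    """Round up to `ndigits` decimals (0.00511 -> 0.01)."""
    return float(Decimal(repr(x)).quantize(_quantum(ndigits), rounding=ROUND_CEILING))
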