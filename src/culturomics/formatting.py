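"""Percent formatting used by the report layer.

Whole percents are formed by truncation (686/2881 reports as 23%, not
24%); one-decimal percents use round-half-even.  Both rules apply only to
human-readable reports — machine-readable outputs always carry the raw
fractions.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_FLOOR, ROUND_HALF_EVEN


def percent_truncated(fraction: float) -> int:
    """Whole percent of a fraction, truncated toward zero-decimal floor."""
    return int(
        (Decimal(repr(fraction)) * 100).quantize(Decimal("1"), rounding=ROUND_FLOOR)
    )


def percent_one_decimal(fraction: float) -> float:
    """One-decimal percent of a fraction, round-half-even."""
    return float(
        (Decimal(repr(fraction)) * 100).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_EVEN
        )
    )
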