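"""Shared numeric helpers."""

from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Used everywhere a blob area is converted to a bird count so that
    .5 boundaries behave predictably (2.5 -> 3, not banker's 2).
    """
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def round_decimals_half_away(x: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals, halves away from zero."""
    scale = 10.0**ndigits
    return round_half_away(x * scale) / scale
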