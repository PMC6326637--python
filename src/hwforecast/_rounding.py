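"""Half-up rounding used for report tables.

Internal state is real-valued throughout the pipeline; integers (census
tables) and one-decimal values (flow tables) appear only at render time.
Python's built-in ``round`` is banker's rounding, so report rendering uses
decimal half-up instead.
"""
from __future__ import annotations

import decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` half away from zero at ``ndigits`` decimal places."""
    if ndigits < 0:
        raise ValueError("ndigits must be >= 0")
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)
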