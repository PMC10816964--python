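"""Decimal rounding helpers.

Published accuracy tables in this domain are produced by statistical software
that rounds ties away from zero (e.g. 528/128 = 4.125 is printed as 4.13 and
54/96 = 56.25% as 56.3%).  Python's built-in ``round`` is banker's rounding,
so all formatting for comparison against printed values goes through here.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round ``x`` to ``decimals`` places with ties going away from zero."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return x
    quantum = Decimal(1).scaleb(-decimals)
    # repr() gives the shortest decimal string that round-trips the float,
    # which avoids spurious binary artefacts like 4.124999999999999.
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def signif(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures, ties away from zero."""
    if x is None or x == 0 or (isinstance(x, float) and math.isnan(x)):
        return x
    magnitude = math.floor(math.log10(abs(x)))
    return round_half_away(x, digits - 1 - magnitude)


def decimals_of(printed: str) -> int:
    """Number of decimal places shown in a printed cell like '85.7' or '97'."""
    s = printed.strip().rstrip("%")
    if "." in s:
        return len(s.split(".", 1)[1])
    return 0


def fmt_fixed(x: float, decimals: int) -> str:
    return f"{round_half_away(x, decimals):.{decimals}f}"


def fmt_signif(x: float, digits: int = 3) -> str:
    """Format with ``digits`` significant figures, trimming trailing zeros
    only for integer-valued results (matching '9' or '3.5' style cells)."""
    if x is None:
        return ""
    v = signif(x, digits)
    if v == int(v):
        return str(int(v))
    return repr(v)
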