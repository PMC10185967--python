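"""Half-up decimal rounding for reported percentages.

Python's built-in ``round`` is banker's rounding; published epidemiology
tables round half away from zero, so 30.45 prints as 30.5 (not 30.4).
Internal statistics keep full precision; this helper lives only in the
formatting/report layer.
"""

from __future__ import annotations

import decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)
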