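"""Small numeric conventions used throughout the package.

Conventions, stated once:

* medians use linear interpolation at even counts;
* interquartile ranges use linearly interpolated 25th/75th percentiles
  (numpy's default, "type 7");
* reported figures round half-up (ties away from zero), matching how the
  survey tables print 2-decimal ratios and integer percentages.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np

__all__ = ["median", "iqr", "round_half_up"]


def median(values: Sequence) -> float:
    if len(values) == 0:
        raise ValueError("median of empty sequence")
    return float(np.median(np.asarray(values, dtype=float)))


def iqr(values: Sequence) -> tuple[float, float]:
    """(25th, 75th) percentile with linear interpolation."""
    if len(values) == 0:
        raise ValueError("iqr of empty sequence")
    lo, hi = np.percentile(np.asarray(values, dtype=float), [25, 75])
    return float(lo), float(hi)


def round_half_up(value, ndigits: int = 0):
    """Round with ties going away from zero (so 0.5 -> 1, -0.5 -> -1).

    Returns an int when ``ndigits <= 0``, else a float.
    """
    dec = value if isinstance(value, Decimal) else Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-ndigits)
    out = dec.quantize(quantum, rounding=ROUND_HALF_UP)
    return int(out) if ndigits <= 0 else float(out)
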