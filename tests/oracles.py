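"""Independent brute-force oracles used to cross-check the engines.

Deliberately naive: sort-based medians and quantiles recomputed from raw
values, never sharing code with the package.
"""

from __future__ import annotations

import math


def sorted_median(values):
    s = sorted(values)
    n = len(s)
    if n == 0:
        raise ValueError("empty")
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def type7_quantile(values, q):
    s = sorted(values)
    h = (len(s) - 1) * q
    f = math.floor(h)
    c = min(f + 1, len(s) - 1)
    return s[f] + (h - f) * (s[c] - s[f])


def brute_force_mpr(outlet_price_lists, irp_times_fx):
    """Median MPR recomputed from raw per-outlet price lists."""
    outlet_medians = [sorted_median(prices) for prices in outlet_price_lists]
    ratios = [m / irp_times_fx for m in outlet_medians]
    return sorted_median(ratios)
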