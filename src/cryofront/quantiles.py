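"""Shared quantile rule.

Both the pore-property tables and the dispersion statistics quote Q1/Q3;
they must agree bit-for-bit, so the rule lives in exactly one place.  The
convention is the linear-interpolation rule on order statistics (NumPy's
``method="linear"``): the p-quantile sits at fractional position
``(n - 1) * p`` of the sorted sample.
"""

from __future__ import annotations

import numpy as np


def quantile(values, q):
    """Linear-interpolation sample quantile(s) of *values* at *q* in [0, 1]."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("quantile of empty data")
    return np.quantile(arr, q, method="linear")


def quartiles(values):
    """Return ``(Q1, Q3)`` -- the 25th and 75th percentiles."""
    q1, q3 = quantile(values, [0.25, 0.75])
    return float(q1), float(q3)
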