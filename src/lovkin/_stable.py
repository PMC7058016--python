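"""Numerically stable divided differences of the exponential.

The sequential first-order (Bateman) populations and the singlet-oxygen
phosphorescence profile are, up to prefactors, first and second divided
differences of exp evaluated at the (negative) rate-time products.  Writing
them that way replaces the catastrophically cancelling textbook forms
``(e^a - e^b)/(a - b)`` with ``expm1``-based kernels that stay accurate through
arbitrarily close (and exactly coincident) exponents.
"""

from __future__ import annotations

import numpy as np

__all__ = ["expdd1", "expdd2"]

# Absolute spread (in units of k*t, i.e. dimensionless exponent) below which
# all three nodes are treated as confluent.  At 1e-7 the Taylor branch error is
# O(spread^2) ~ 1e-14 while the recursive branch would lose ~9 digits.
_CONFLUENT_SPREAD = 1e-7


def _phi(h):
    """(e^h - 1)/h with the h -> 0 limit 1, elementwise; expects h <= 0."""
    h = np.asarray(h, dtype=float)
    small = np.abs(h) < 1e-300
    safe = np.where(small, 1.0, h)
    return np.where(small, 1.0, np.expm1(safe) / safe)


def expdd1(a, b):
    """First divided difference exp[a, b] = (e^a - e^b)/(a - b).

    Stable for any spacing of the nodes; exp[a, a] = e^a.  Evaluated from the
    larger node so the expm1 argument is never positive (no overflow for
    widely separated nodes).
    """
    a, b = np.broadcast_arrays(np.asarray(a, float), np.asarray(b, float))
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    return np.exp(hi) * _phi(lo - hi)


def expdd2(a, b, c):
    """Second divided difference exp[a, b, c].

    Symmetric in its arguments.  Computed from the recursion
    ``(exp[x1, x2] - exp[x2, x3]) / (x1 - x3)`` after sorting the nodes so the
    outer pair is the widest; a confluent Taylor branch handles the case where
    all three nodes (nearly) coincide.
    """
    a, b, c = np.broadcast_arrays(
        np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)
    )
    nodes = np.sort(np.stack([a, b, c], axis=0), axis=0)
    lo, mid, hi = nodes[0], nodes[1], nodes[2]
    spread = hi - lo

    # Generic branch: outer nodes are the extremes, so the denominator is the
    # full spread and the two first differences share the middle node.
    safe_spread = np.where(spread == 0.0, 1.0, spread)
    generic = (expdd1(hi, mid) - expdd1(mid, lo)) / safe_spread

    # Confluent branch: exp[x,x,x] = e^x / 2; second-order Taylor about the
    # mean node keeps the error at O(spread^2).
    m = (lo + mid + hi) / 3.0
    y1, y2, y3 = lo - m, mid - m, hi - m
    e2 = y1 * y2 + y1 * y3 + y2 * y3  # elementary symmetric, sum of nodes is 0
    confluent = np.exp(m) * (0.5 + (-e2) / 24.0)

    return np.where(spread < _CONFLUENT_SPREAD, confluent, generic)
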