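"""Independent textbook Fritsch–Carlson monotone cubic Hermite interpolant.

Serves as the oracle for the canopy module's LAI interpolation; written
directly from the derivative-limiting rules (harmonic-mean interior
slopes, shape-preserving one-sided end slopes) with no reference to the
implementation it checks.
"""

import numpy as np


def _edge_slope(h0, h1, m0, m1):
    d = ((2 * h0 + h1) * m0 - h0 * m1) / (h0 + h1)
    if np.sign(d) != np.sign(m0):
        return 0.0
    if np.sign(m0) != np.sign(m1) and abs(d) > 3 * abs(m0):
        return 3 * m0
    return d


def fritsch_carlson_derivatives(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    h = np.diff(x)
    m = np.diff(y) / h
    n = len(x)
    d = np.zeros(n)
    for k in range(1, n - 1):
        if m[k - 1] * m[k] <= 0:
            d[k] = 0.0
        else:
            w1 = 2 * h[k] + h[k - 1]
            w2 = h[k] + 2 * h[k - 1]
            d[k] = (w1 + w2) / (w1 / m[k - 1] + w2 / m[k])
    d[0] = _edge_slope(h[0], h[1] if n > 2 else h[0], m[0], m[1] if n > 2 else m[0])
    d[-1] = _edge_slope(
        h[-1], h[-2] if n > 2 else h[-1], m[-1], m[-2] if n > 2 else m[-1]
    )
    return d


def pchip_eval(x, y, xq):
    """Evaluate the monotone cubic Hermite interpolant at query points."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xq = np.asarray(xq, float)
    d = fritsch_carlson_derivatives(x, y)
    out = np.empty_like(xq)
    idx = np.clip(np.searchsorted(x, xq, side="right") - 1, 0, len(x) - 2)
    for j, (xi, i) in enumerate(zip(xq, idx)):
        h = x[i + 1] - x[i]
        t = (xi - x[i]) / h
        h00 = (1 + 2 * t) * (1 - t) ** 2
        h10 = t * (1 - t) ** 2
        h01 = t**2 * (3 - 2 * t)
        h11 = t**2 * (t - 1)
        out[j] = (
            h00 * y[i] + h10 * h * d[i] + h01 * y[i + 1] + h11 * h * d[i + 1]
        )
    return out
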