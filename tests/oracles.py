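"""Independent brute-force oracles used by the tests.

Each function re-derives a quantity from its definition with the most
literal code possible, deliberately sharing nothing with the package
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def lpcc_brute_force(a, p, d):
    """Cepstral recursion written as a literal double loop over the formula."""
    c = [0.0] * (d + 1)  # 1-based
    a1 = [0.0] + list(a)  # 1-based LPC coefficients
    for x in range(1, d + 1):
        s = 0.0
        for t in range(1, x):
            if 1 <= x - t <= p:
                s += (t / x) * c[t] * a1[x - t]
        c[x] = s + (a1[x] if x <= p else 0.0)
    return np.array(c[1:])


def pearson_direct(g, h):
    """Correlation evaluated term by term from its definition."""
    n = len(g)
    gbar = sum(g) / n
    hbar = sum(h) / n
    num = sum((g[i] - gbar) * (h[i] - hbar) for i in range(n))
    den = math.sqrt(
        sum((g[i] - gbar) ** 2 for i in range(n))
        * sum((h[i] - hbar) ** 2 for i in range(n))
    )
    return num / den


def lpc_normal_equations(x, p):
    """LPC coefficients by solving the Toeplitz autocorrelation system directly."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = len(x)
    r = np.array([np.dot(x[: n - k], x[k:]) / n for k in range(p + 1)])
    R = np.array([[r[abs(i - j)] for j in range(p)] for i in range(p)])
    return np.linalg.solve(R, r[1: p + 1])


def mask_union_area(segments, disks, ellipses, shape):
    """Pixel count of a union of dilated segments/disks/ellipses.

    Evaluated per pixel from the geometric definitions (distance to a
    segment, disk membership, ellipse membership).
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    covered = np.zeros(shape, dtype=bool)
    for (x0, y0), (x1, y1), radius in segments:
        vx, vy = x1 - x0, y1 - y0
        denom = vx * vx + vy * vy
        if denom == 0:
            t = np.zeros_like(xx, dtype=float)
        else:
            t = np.clip(((xx - x0) * vx + (yy - y0) * vy) / denom, 0, 1)
        d2 = (xx - (x0 + t * vx)) ** 2 + (yy - (y0 + t * vy)) ** 2
        covered |= d2 <= radius**2
    for (cx, cy), radius in disks:
        covered |= (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    for (cx, cy), (rx, ry) in ellipses:
        covered |= ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    return int(covered.sum())
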