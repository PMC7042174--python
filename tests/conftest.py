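"""Shared fixtures and an independent loop-based descriptor oracle.

The oracle deliberately shares no code with the package: reference points,
distances and moments are computed with explicit Python loops and ``math``
only, so agreement with the vectorised implementation is a genuine
cross-check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


def naive_moments(distances):
    n = len(distances)
    m1 = sum(distances) / n
    mu2 = sum((d - m1) ** 2 for d in distances) / n
    mu3 = sum((d - m1) ** 3 for d in distances) / n
    m2 = math.sqrt(mu2)
    m3 = math.copysign(abs(mu3) ** (1.0 / 3.0), mu3) if mu3 != 0 else 0.0
    return [m1, m2, m3]


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def naive_descriptor(coords, charges=None, logp=None, method="usr",
                     charge_scale=25.0, logp_scale=25.0):
    """Loop-based USR / ElectroShape descriptor (independent oracle)."""
    points = []
    for i in range(len(coords)):
        p = list(coords[i])
        if method in ("es4d", "es5d"):
            p.append(charge_scale * charges[i])
        if method == "es5d":
            p.append(logp_scale * logp[i])
        points.append(p)
    n = len(points)
    dim = len(points[0])

    def centroid(pts):
        return [sum(p[k] for p in pts) / len(pts) for k in range(dim)]

    def extreme(ref, want_max):
        best_i, best_d = 0, _dist(points[0], ref)
        for i in range(1, n):
            d = _dist(points[i], ref)
            if (want_max and d > best_d) or (not want_max and d < best_d):
                best_i, best_d = i, d
        return points[best_i]

    if method == "usr":
        ctd = centroid(points)
        cst = extreme(ctd, want_max=False)
        fct = extreme(ctd, want_max=True)
        ftf = extreme(fct, want_max=True)
        refs = [ctd, cst, fct, ftf]
    else:
        c1 = centroid(points)
        c2 = extreme(c1, want_max=True)
        c3 = extreme(c2, want_max=True)
        a = [c2[k] - c1[k] for k in range(dim)]
        b = [c3[k] - c1[k] for k in range(dim)]
        cross = [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
        norm_cross = math.sqrt(sum(c * c for c in cross))
        if norm_cross < 1e-12:
            c4 = list(c1)
            c5 = list(c1)
        else:
            norm_a3 = math.sqrt(sum(a[k] ** 2 for k in range(3)))
            spatial = [c1[k] + norm_a3 / (2 * norm_cross) * cross[k] for k in range(3)]
            qmax = max(p[3] for p in points)
            qmin = min(p[3] for p in points)
            c4 = spatial + [qmax] + list(c1[4:])
            c5 = spatial + [qmin] + list(c1[4:])
        refs = [c1, c2, c3, c4, c5]

    values = []
    for ref in refs:
        values.extend(naive_moments([_dist(p, ref) for p in points]))
    return values


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
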