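"""Independent brute-force oracles used by the test-suite.

These deliberately avoid the library code paths they check: the Delaunay
oracle is an O(n^4) empty-circumcircle scan, the Welch oracle is the
textbook formula, and the log-rank oracle tabulates risk sets explicitly.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def brute_force_delaunay_edges(points: np.ndarray) -> set[tuple[int, int]]:
    """A triangle is Delaunay iff its circumcircle is empty of other
    points; the edge set is the union over all such triangles."""
    n = len(points)
    edges: set[tuple[int, int]] = set()
    for i, j, k in itertools.combinations(range(n), 3):
        ax, ay = points[i]
        bx, by = points[j]
        cx, cy = points[k]
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            continue  # collinear
        ux = (
            (ax**2 + ay**2) * (by - cy)
            + (bx**2 + by**2) * (cy - ay)
            + (cx**2 + cy**2) * (ay - by)
        ) / d
        uy = (
            (ax**2 + ay**2) * (cx - bx)
            + (bx**2 + by**2) * (ax - cx)
            + (cx**2 + cy**2) * (bx - ax)
        ) / d
        r2 = (ax - ux) ** 2 + (ay - uy) ** 2
        empty = True
        for m in range(n):
            if m in (i, j, k):
                continue
            if (points[m, 0] - ux) ** 2 + (points[m, 1] - uy) ** 2 < r2 * (
                1 - 1e-12
            ):
                empty = False
                break
        if empty:
            for a, b in ((i, j), (j, k), (i, k)):
                edges.add((min(a, b), max(a, b)))
    return edges


def welch_by_hand(a, b):
    """Textbook Welch statistic, Welch-Satterthwaite df, two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def logrank_by_hand(time, event, group) -> float:
    """Mantel-Cox chi-square from an explicit risk table: at each distinct
    event time accumulate O - E for group 1 and the hypergeometric
    variance."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    group = np.asarray(group)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
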