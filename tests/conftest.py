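"""Shared fixtures and independent oracles.

The oracle functions here are deliberately naive re-derivations (normal
equations, exhaustive single linkage) kept separate from the library code
paths they validate.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from chromlip import load_study_tables


@pytest.fixture(scope="session")
def fixtures():
    return load_study_tables()


def ols_oracle(x, y):
    """Closed-form OLS + Pearson r via the normal equations (no scipy)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy, syy = (x * x).sum(), (x * y).sum(), (y * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    r = (n * sxy - sx * sy) / math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return slope, intercept, r


def single_linkage_oracle(dist):
    """Exhaustive agglomeration: recompute the min inter-cluster distance each step.

    ``dist`` is a square symmetric array. Returns the sorted-by-step list of
    (frozenset_a, frozenset_b, height).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(dist[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], d))
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges
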