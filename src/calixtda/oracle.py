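"""Exhaustive small-instance persistence oracle.

A deliberately naive reference: build EVERY simplex of the Vietoris-Rips
complex up to dimension 2, order the whole list by (filtration value,
dimension, lexicographic vertex tuple), assemble the full boundary matrix
over Z/2 as dense numpy, and run the textbook left-to-right column
reduction.  No union-find, no clearing, no sparsity tricks — it shares no
code path with :mod:`calixtda.topology` and exists purely to cross-check it
on small inputs (and to be readable).

Intended for clouds of at most a few dozen points; cost grows as O(n^3)
simplices with cubic reduction on top.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

__all__ = ["vr_bars_oracle"]


def vr_bars_oracle(
    dist: np.ndarray, r_max: float | None = None
) -> dict[int, list[tuple[float, float]]]:
    """All H0/H1 bars of the VR complex (dims <= 2) by full dense reduction.

    Returns ``{0: [(birth, death), ...], 1: [...]}`` with ``math.inf`` for
    the essential H0 bar and ``death = r_max`` for H1 cycles still open when
    the filtration is cut (matching the truncation convention of the main
    implementation).  Zero-persistence pairs are dropped.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(dist)

    simplices: list[tuple[float, int, tuple[int, ...]]] = []
    for v in range(n):
        simplices.append((0.0, 0, (v,)))
    for i, j in combinations(range(n), 2):
        f = dist[i, j]
        if r_max is None or f <= r_max:
            simplices.append((float(f), 1, (i, j)))
    for i, j, k in combinations(range(n), 3):
        f = max(dist[i, j], dist[i, k], dist[j, k])
        if r_max is None or f <= r_max:
            simplices.append((float(f), 2, (i, j, k)))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))

    index = {verts: idx for idx, (_, _, verts) in enumerate(simplices)}
    m = len(simplices)
    D = np.zeros((m, m), dtype=np.uint8)
    for col, (_, dim, verts) in enumerate(simplices):
        if dim == 0:
            continue
        for face in combinations(verts, dim):
            D[index[face], col] = 1

    # textbook reduction: reduce each column against earlier same-low columns
    lows: dict[int, int] = {}  # low row -> column index
    for col in range(m):
        while True:
            rows = np.flatnonzero(D[:, col])
            if len(rows) == 0:
                break
            low = int(rows[-1])
            if low not in lows:
                lows[low] = col
                break
            D[:, col] ^= D[:, lows[low]]

    paired_as_death = {col for col in lows.values()}
    paired_birth_to_death = {low: col for low, col in lows.items()}

    bars: dict[int, list[tuple[float, float]]] = {0: [], 1: []}
    for idx, (f, dim, _) in enumerate(simplices):
        if idx in paired_as_death:
            continue  # negative simplex: it kills, it does not create
        if dim == 2:
            continue  # H2 not tracked
        if idx in paired_birth_to_death:
            death = simplices[paired_birth_to_death[idx]][0]
            if death > f:
                bars[dim].append((f, death))
        else:
            if dim == 0:
                bars[dim].append((f, math.inf))
            elif r_max is not None and r_max > f:
                bars[dim].append((f, float(r_max)))
            # with no cut the clique complex on a finite cloud has no
            # essential H1 (every cycle fills once all triangles arrive)
            elif r_max is None:
                bars[dim].append((f, math.inf))
    for dim in bars:
        bars[dim].sort()
    return bars
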