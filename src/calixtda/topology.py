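"""Vietoris-Rips persistence (H0 and H1) of atomic point clouds.

The filtration grows Euclidean balls around every atom; the clique (flag)
complex of the resulting neighbourhood graph is tracked up to dimension 2.
H0 bars record when connected components merge — chemically, when the growing
balls first span a bond or contact — and are computed from the minimum
spanning tree of the distance matrix (single-linkage merge heights).  H1 bars
record independent cycles (atom rings and transient holes) and are computed
by Z/2 boundary-matrix column reduction over the edge/triangle filtration
restricted to edges of length <= r_max.

Each bar carries the element pair of its defining edge (the merge edge for
H0, the cycle-creating birth edge for H1); the imaging stage uses that pair
to modulate the Gaussian spread by electronegativity difference.

Determinism: ties in filtration value are broken by (filtration, dimension,
lexicographic vertex tuple).  Bars still alive at r_max are reported with
death = r_max and flagged truncated; the imaging stage decides their fate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "TopoConfig",
    "PersistenceFeature",
    "PersistenceDiagram",
    "pairwise_distances",
    "h0_persistence",
    "h1_persistence",
    "compute_diagram",
    "write_diagram_csv",
    "read_diagram_csv",
]


@dataclass(frozen=True)
class TopoConfig:
    """Settings for the filtration.

    r_max is twice the persistence-image upper bound by default so features
    dying beyond the plotted window still register before clipping.
    """

    r_max: float = 7.0
    drop_infinite: bool = True
    include_hydrogens: bool = True

    def __post_init__(self) -> None:
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")


@dataclass(frozen=True)
class PersistenceFeature:
    """One bar: homology order, birth/death radii (Å) and its edge's elements."""

    order: int
    birth: float
    death: float  # math.inf for the essential H0 bar
    element_pair: tuple[str, str] | None
    truncated: bool = False

    @property
    def persistence(self) -> float:
        return self.death - self.birth


@dataclass
class PersistenceDiagram:
    structure_id: str
    features: list[PersistenceFeature]
    r_max: float

    def bars(self, order: int) -> list[PersistenceFeature]:
        return [f for f in self.features if f.order == order]


def pairwise_distances(cloud_or_coords) -> np.ndarray:
    """Symmetric Euclidean distance matrix in Å (zero diagonal)."""
    coords = getattr(cloud_or_coords, "coords", cloud_or_coords)
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    if n == 0:
        raise ValueError("need at least one atom")
    if n == 1:
        return np.zeros((1, 1))
    return squareform(pdist(coords))


def _sorted_edges(dist: np.ndarray, r_max: float | None = None) -> list[tuple[float, int, int]]:
    n = len(dist)
    edges = [
        (dist[i, j], i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if r_max is None or dist[i, j] <= r_max
    ]
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    return edges


def h0_persistence(dist: np.ndarray, elements: Sequence[str]) -> list[PersistenceFeature]:
    """H0 bars: N-1 finite bars with deaths at the minimum-spanning-tree edge
    weights plus one essential (infinite) bar per connected input.

    The finite deaths are exactly the single-linkage dendrogram merge
    heights; each bar is tagged with the element pair of its merge edge.
    A Kruskal pass over the (filtration, lexicographic) edge order keeps the
    merge-edge choice deterministic under ties and handles coincident atoms.
    """
    n = len(dist)
    if n != len(elements):
        raise ValueError("element list does not match distance matrix")
    feats: list[PersistenceFeature] = []
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for w, i, j in _sorted_edges(dist):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            feats.append(
                PersistenceFeature(
                    order=0,
                    birth=0.0,
                    death=float(w),
                    element_pair=(elements[i], elements[j]),
                )
            )
            if len(feats) == n - 1:
                break
    feats.append(PersistenceFeature(order=0, birth=0.0, death=math.inf, element_pair=None))
    return feats


def h1_persistence(
    dist: np.ndarray, elements: Sequence[str], r_max: float
) -> list[PersistenceFeature]:
    """H1 bars of the clique complex restricted to edges <= r_max.

    Triangles enter at the length of their longest edge.  Standard column
    reduction over Z/2 pairs each reduced triangle with its youngest cycle-
    creating edge; zero-persistence pairs (a cycle filled the instant it
    appears, e.g. any 3-clique) are dropped.  Cycle-creating edges never
    killed below r_max yield truncated bars with death = r_max.
    """
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    n = len(dist)
    edges = _sorted_edges(dist, r_max)
    edge_index = {(i, j): k for k, (_, i, j) in enumerate(edges)}

    # cycle-creating ("positive") edges: those that do not merge components
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    positive: set[int] = set()
    for k, (_, i, j) in enumerate(edges):
        ri, rj = find(i), find(j)
        if ri == rj:
            positive.add(k)
        else:
            parent[ri] = rj

    # triangles sorted by (filtration, lexicographic vertices)
    adj: list[set[int]] = [set() for _ in range(n)]
    for _, i, j in edges:
        adj[i].add(j)
    triangles: list[tuple[float, int, int, int]] = []
    for _, i, j in edges:
        for k in adj[i] & adj[j]:  # k > j > i by construction
            f = max(dist[i, j], dist[i, k], dist[j, k])
            triangles.append((f, i, j, k))
    triangles.sort(key=lambda t: (t[0], t[1], t[2], t[3]))

    # Z/2 column reduction; triangle boundaries live in edge-index space
    pivot: dict[int, frozenset[int]] = {}
    pairs: list[tuple[int, float]] = []  # (birth edge index, death filtration)
    for f, i, j, k in triangles:
        col = {edge_index[(i, j)], edge_index[(i, k)], edge_index[(j, k)]}
        while col:
            low = max(col)
            if low not in pivot:
                break
            col ^= pivot[low]
        if col:
            low = max(col)
            pivot[low] = frozenset(col)
            pairs.append((low, f))

    feats: list[PersistenceFeature] = []
    killed: set[int] = set()
    for ei, death in pairs:
        killed.add(ei)
        birth, i, j = edges[ei]
        if death > birth:
            feats.append(
                PersistenceFeature(
                    order=1,
                    birth=float(birth),
                    death=float(death),
                    element_pair=(elements[i], elements[j]),
                )
            )
    for ei in sorted(positive - killed):
        birth, i, j = edges[ei]
        if r_max > birth:
            feats.append(
                PersistenceFeature(
                    order=1,
                    birth=float(birth),
                    death=float(r_max),
                    element_pair=(elements[i], elements[j]),
                    truncated=True,
                )
            )
    feats.sort(key=lambda f: (f.birth, f.death))
    return feats


def compute_diagram(cloud, config: TopoConfig = TopoConfig()) -> PersistenceDiagram:
    """Full H0+H1 diagram of a point cloud under the given filtration config."""
    elements = list(cloud.elements)
    coords = np.asarray(cloud.coords, dtype=float)
    if not config.include_hydrogens:
        keep = [k for k, s in enumerate(elements) if s != "H"]
        elements = [elements[k] for k in keep]
        coords = coords[keep]
    if len(elements) == 0:
        return PersistenceDiagram(cloud.id, [], config.r_max)
    dist = pairwise_distances(coords)
    h0 = h0_persistence(dist, elements)
    if config.drop_infinite:
        h0 = [f for f in h0 if math.isfinite(f.death)]
    # keep every finite death inside the filtration window: merges later than
    # r_max are reported at the cut and flagged, like open H1 cycles
    feats = [
        f
        if not math.isfinite(f.death) or f.death <= config.r_max
        else PersistenceFeature(0, f.birth, config.r_max, f.element_pair, truncated=True)
        for f in h0
    ]
    feats += h1_persistence(dist, elements, config.r_max)
    return PersistenceDiagram(cloud.id, feats, config.r_max)


def write_diagram_csv(diagram: PersistenceDiagram, path: str | Path) -> None:
    lines = ["structure_id,order,birth,death,elem_a,elem_b,truncated"]
    for f in diagram.features:
        a, b = f.element_pair if f.element_pair else ("", "")
        death = "inf" if math.isinf(f.death) else f"{f.death:.9g}"
        lines.append(
            f"{diagram.structure_id},{f.order},{f.birth:.9g},{death},{a},{b},{int(f.truncated)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_diagram_csv(path: str | Path) -> PersistenceDiagram:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    feats: list[PersistenceFeature] = []
    sid = ""
    for ln in lines[1:]:
        sid, order, birth, death, a, b, trunc = ln.split(",")
        feats.append(
            PersistenceFeature(
                order=int(order),
                birth=float(birth),
                death=math.inf if death == "inf" else float(death),
                element_pair=(a, b) if a else None,
                truncated=bool(int(trunc)),
            )
        )
    return PersistenceDiagram(sid, feats, r_max=max((f.death for f in feats if math.isfinite(f.death)), default=0.0))
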