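"""Initial curve extraction: thinning and maximal pixel chains.

The binary segmentation is first reduced to its ~1-px centerline by iterative
morphological thinning (scikit-image's ``thin``; ``skeletonize`` and
``medial_axis`` are exposed as alternatives).  The positive pixels of the
thinned mask form the vertices of the 8-neighbor graph; on such skeletons
almost all vertices have degree 2, junctions have degree 3+.

Curves are then extracted as *maximal chains through degree-2 nodes*: seed at
any degree-2 pixel, grow in both directions while the frontier pixel has
degree 2 and an unvisited neighbor, emit the chain, remove its pixels from
the graph (degrees are recomputed on the updated graph), repeat until no
degree-2 pixel remains.  Every emitted chain is an ordered sequence of
8-adjacent pixels, unique up to reversal; chains from one mask are pixel
disjoint.  Isolated pixels and 2-pixel components have no degree-2 seed and
are never extracted.

Seed selection and neighbor tie-breaks use deterministic row-major scan order
(lowest (row, col) first) so results are reproducible; at junctions the first
chain to arrive claims the junction pixel.
"""

from __future__ import annotations

import numpy as np
from skimage.morphology import medial_axis, skeletonize
from skimage.morphology import thin as _sk_thin

Curve = np.ndarray

_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def thin(mask: np.ndarray, method: str = "thin") -> np.ndarray:
    """Reduce a binary mask to a ~1-px centerline.

    ``method`` is one of ``'thin'`` (iterative morphological thinning, the
    default), ``'skeletonize'`` or ``'medial_axis'``.
    """
    mask = np.asarray(mask).astype(bool)
    if method == "thin":
        out = _sk_thin(mask)
    elif method == "skeletonize":
        out = skeletonize(mask)
    elif method == "medial_axis":
        out = medial_axis(mask)
    else:
        raise ValueError(f"unknown thinning method {method!r}")
    return out.astype(np.uint8)


class PixelGraph:
    """8-neighbor graph over the positive pixels of a thinned mask."""

    def __init__(self, adj: dict[tuple[int, int], set[tuple[int, int]]]):
        self.adj = adj

    @property
    def vertices(self) -> list[tuple[int, int]]:
        return sorted(self.adj)

    def degree(self, v: tuple[int, int]) -> int:
        return len(self.adj[v])

    def neighbors(self, v: tuple[int, int]) -> list[tuple[int, int]]:
        return sorted(self.adj[v])

    def remove(self, vs) -> None:
        """Remove vertices and their incident edges; degrees update implicitly."""
        for v in vs:
            for u in self.adj.pop(v, ()):  # noqa: B909 - adj[u] still present
                self.adj[u].discard(v)


def build_graph(thinned: np.ndarray) -> PixelGraph:
    """Build the 8-neighbor graph of the positive pixels."""
    thinned = np.asarray(thinned)
    pix = set(zip(*np.nonzero(thinned)))
    adj: dict[tuple[int, int], set[tuple[int, int]]] = {p: set() for p in pix}
    for r, c in pix:
        for dr, dc in _NEIGH:
            q = (r + dr, c + dc)
            if q in adj:
                adj[(r, c)].add(q)
    return PixelGraph(adj)


def _grow(graph: PixelGraph, chain: list, frontier, visited: set, prepend: bool):
    """Extend the chain from `frontier` while it has degree 2 and a fresh neighbor."""
    while graph.degree(frontier) == 2:
        nxt = [q for q in graph.neighbors(frontier) if q not in visited]
        if not nxt:
            break  # closed loop back into the chain
        q = nxt[0]  # deterministic: lowest (row, col)
        if prepend:
            chain.insert(0, q)
        else:
            chain.append(q)
        visited.add(q)
        frontier = q


def extract_chains(graph: PixelGraph) -> list[Curve]:
    """Extract maximal chains through degree-2 nodes; mutates the graph.

    Each chain is seeded at the smallest remaining degree-2 pixel (with its
    two neighbors), grown in both directions, emitted, and removed from the
    graph before the next seed is chosen.
    """
    curves: list[Curve] = []
    while True:
        seed = None
        for v in graph.vertices:
            if graph.degree(v) == 2:
                seed = v
                break
        if seed is None:
            break
        j, k = graph.neighbors(seed)
        chain = [j, seed, k]
        visited = set(chain)
        _grow(graph, chain, k, visited, prepend=False)
        _grow(graph, chain, j, visited, prepend=True)
        curves.append(np.asarray(chain))
        graph.remove(chain_tuples(chain))
    return curves


def chain_tuples(chain) -> list[tuple[int, int]]:
    return [tuple(p) for p in chain]


def extract_curves(mask: np.ndarray, method: str = "thin") -> list[Curve]:
    """Full initial-curve extraction: thin the mask, then extract chains."""
    t = thin(mask, method=method)
    return extract_chains(build_graph(t))
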