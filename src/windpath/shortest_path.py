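"""Minimum-cost paths on the wind cost graph and the SWPD.

Paths are minimised on accumulated edge *cost*; the shortest wind-field
path distance (SWPD) reported for a pair of cells is the geometric *length*
of that minimum-cost path — two different numbers, both retained in
:class:`PathResult`. Dijkstra's algorithm with a binary heap is used; ties
between equal-cost frontier entries are broken by (cost, row, col) heap
order with neighbours expanded in the fixed N, NE, E, SE, S, SW, W, NW
order, making every path bit-reproducible.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .costgraph import NEIGHBOR_OFFSETS, CostGraph

__all__ = ["PathResult", "dijkstra", "swpd_between", "swpd_matrix", "shortest_path_matrices"]


@dataclass(frozen=True)
class PathResult:
    """A minimum-cost path: its cells, accumulated cost, and SWPD (metres)."""

    cells: tuple[tuple[int, int], ...]
    total_cost: float
    swpd: float


def _check_cell(graph: CostGraph, cell: tuple[int, int], name: str) -> None:
    r, c = cell
    if not (0 <= r < graph.grid.n_rows and 0 <= c < graph.grid.n_cols):
        raise ValueError(
            f"{name} cell {cell} outside {graph.grid.n_rows}x{graph.grid.n_cols} grid"
        )


def dijkstra(graph: CostGraph, source: tuple[int, int]):
    """Single-source minimum accumulated cost over the lattice graph.

    Returns ``(cost_to, predecessor, length_to)``: per-cell arrays of the
    minimum accumulated cost, the flattened index of the previous cell on
    that path (−1 at the source / unreachable cells), and the geometric
    length of the chosen path. Unreachable cells carry +inf.
    """
    _check_cell(graph, source, "source")
    nr, nc = graph.grid.shape
    costs = graph.costs

    cost_to = np.full((nr, nc), np.inf)
    length_to = np.full((nr, nc), np.inf)
    predecessor = np.full((nr, nc), -1, dtype=np.int64)
    done = np.zeros((nr, nc), dtype=bool)

    sr, sc = source
    cost_to[sr, sc] = 0.0
    length_to[sr, sc] = 0.0
    heap: list[tuple[float, int, int]] = [(0.0, sr, sc)]
    lengths = graph.lengths

    while heap:
        d, r, c = heapq.heappop(heap)
        if done[r, c]:
            continue
        done[r, c] = True
        for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < nr and 0 <= c2 < nc) or done[r2, c2]:
                continue
            nd = d + costs[k, r, c]
            if nd < cost_to[r2, c2]:
                cost_to[r2, c2] = nd
                length_to[r2, c2] = length_to[r, c] + lengths[k]
                predecessor[r2, c2] = r * nc + c
                heapq.heappush(heap, (nd, r2, c2))
    return cost_to, predecessor, length_to


def _reconstruct(predecessor: np.ndarray, nc: int, dst: tuple[int, int]):
    cells = [dst]
    r, c = dst
    while predecessor[r, c] >= 0:
        p = int(predecessor[r, c])
        r, c = divmod(p, nc)
        cells.append((r, c))
    cells.reverse()
    return tuple(cells)


def swpd_between(graph: CostGraph, src: tuple[int, int], dst: tuple[int, int]) -> PathResult:
    """Minimum-cost path from src to dst and its SWPD.

    ``src == dst`` yields a zero-cost, zero-length single-cell path.
    """
    _check_cell(graph, src, "source")
    _check_cell(graph, dst, "destination")
    src = (int(src[0]), int(src[1]))
    dst = (int(dst[0]), int(dst[1]))
    if src == dst:
        return PathResult(cells=(src,), total_cost=0.0, swpd=0.0)
    cost_to, predecessor, length_to = dijkstra(graph, src)
    if not np.isfinite(cost_to[dst]):
        raise ValueError(f"destination cell {dst} unreachable from {src}")
    cells = _reconstruct(predecessor, graph.grid.n_cols, dst)
    return PathResult(
        cells=cells,
        total_cost=float(cost_to[dst]),
        swpd=float(length_to[dst]),
    )


def shortest_path_matrices(graph: CostGraph, sources, targets):
    """Per-pair (accumulated cost, SWPD) matrices; one Dijkstra per source."""
    sources = [tuple(map(int, s)) for s in sources]
    targets = [tuple(map(int, t)) for t in targets]
    for s in sources:
        _check_cell(graph, s, "source")
    for t in targets:
        _check_cell(graph, t, "target")
    cost = np.empty((len(sources), len(targets)))
    swpd = np.empty((len(sources), len(targets)))
    for i, s in enumerate(sources):
        cost_to, _, length_to = dijkstra(graph, s)
        for j, t in enumerate(targets):
            if not np.isfinite(cost_to[t]):
                raise ValueError(f"target cell {t} unreachable from {s}")
            cost[i, j] = cost_to[t]
            swpd[i, j] = length_to[t] if s != t else 0.0
    return cost, swpd


def swpd_matrix(graph: CostGraph, sources, targets) -> np.ndarray:
    """SWPD (metres) from each source cell to each target cell.

    Entry (i, j) is the geometric length of the minimum-cost path from
    source i to target j; the matrix need not be symmetric.
    """
    _, swpd = shortest_path_matrices(graph, sources, targets)
    return swpd
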