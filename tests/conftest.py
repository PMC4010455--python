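import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from windpath import (
    ConcentrationObservation,
    CostParams,
    GridSpec,
    WindObservation,
    WindRaster,
    build_cost_graph,
)
from windpath.costgraph import NEIGHBOR_OFFSETS
from windpath.synthetic import make_wind


@pytest.fixture
def small_grid():
    return GridSpec(x_origin=0.0, y_origin=0.0, cell_size=500.0, n_rows=6, n_cols=6)


@pytest.fixture
def calm_graph(small_grid):
    calm = WindRaster(
        grid=small_grid,
        u=np.zeros(small_grid.shape),
        v=np.zeros(small_grid.shape),
    )
    return build_cost_graph(calm, CostParams())


@pytest.fixture
def easterly_graph(small_grid):
    """Uniform flow toward the east (wind from 270°)."""
    wind = make_wind("uniform", small_grid, speed=2.0, direction=270.0)
    return build_cost_graph(wind, CostParams())


@pytest.fixture
def wind_stations():
    return [
        WindObservation("W0", 500.0, 750.0, 2.0, 90.0),
        WindObservation("W1", 2400.0, 500.0, 1.5, 120.0),
        WindObservation("W2", 1200.0, 2600.0, 2.2, 80.0),
        WindObservation("W3", 2700.0, 2300.0, 1.8, 95.0),
    ]


@pytest.fixture
def conc_stations(small_grid):
    cells = [(0, 0), (1, 4), (3, 2), (4, 5), (5, 1)]
    values = [40.0, 55.0, 90.0, 35.0, 60.0]
    return [
        ConcentrationObservation(f"C{i}", *small_grid.cell_center(r, c), val)
        for i, ((r, c), val) in enumerate(zip(cells, values))
    ]


def brute_force_min_cost(graph, source, target):
    """Exhaustive search over all simple paths (pruned DFS); independent of
    the Dijkstra implementation under test."""
    nr, nc = graph.grid.shape
    best = [np.inf]

    def dfs(cell, visited, acc):
        if acc >= best[0]:
            return
        if cell == target:
            best[0] = acc
            return
        r, c = cell
        for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
            nxt = (r + dr, c + dc)
            if 0 <= nxt[0] < nr and 0 <= nxt[1] < nc and nxt not in visited:
                dfs(nxt, visited | {nxt}, acc + graph.costs[k, r, c])

    dfs(source, {source}, 0.0)
    return best[0]


def octile(cell_a, cell_b, cell_size):
    dr = abs(cell_a[0] - cell_b[0])
    dc = abs(cell_a[1] - cell_b[1])
    return cell_size * (max(dr, dc) + (np.sqrt(2) - 1) * min(dr, dc))
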