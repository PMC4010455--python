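"""Movement-cost graph over the 8-neighbour lattice of a gridded wind field.

Pollution moves easily with the flow and with difficulty against or across
it. Following the Gaussian-dispersion picture — concentration decays with
the azimuth between a displacement and the wind axis — each directed edge
between adjacent cells carries a cost

    cost = L · (1 + gamma · (theta_bar / 180)**beta)

where L is the geometric edge length (cell_size or √2·cell_size) and
theta_bar is the mean angular deviation between the edge direction and the
flow direction at the two incident cells. Moving exactly downwind costs the
plain geometric length; moving dead upwind costs L·(1 + gamma). The cost
law is pluggable so alternative penalties can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .grid import GridSpec
from .windfield import WindRaster

__all__ = [
    "CostParams",
    "PlumeParams",
    "CostGraph",
    "NEIGHBOR_OFFSETS",
    "NEIGHBOR_DIRECTIONS",
    "angular_deviation",
    "edge_cost",
    "build_cost_graph",
    "plume_concentration",
]

# lexicographic neighbour order N, NE, E, SE, S, SW, W, NW as (drow, dcol);
# row index grows northward internally
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1),
)
# compass azimuth of each neighbour offset (degrees clockwise from north)
NEIGHBOR_DIRECTIONS: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)


@dataclass(frozen=True)
class CostParams:
    """Tuning parameters of the directional movement penalty.

    gamma : crosswind/upwind penalty weight (>= 0); 0 disables the penalty.
    beta : penalty exponent (> 0) shaping how sharply cost rises with
        angular deviation.
    speed_weighting : when on, costs are additionally scaled by the inverse
        mean wind speed (dispersion dilutes with speed); off by default.
    calm_threshold : m/s below which a cell's wind direction is treated as
        undefined and contributes no penalty.
    """

    gamma: float = 4.0
    beta: float = 2.0
    speed_weighting: bool = False
    calm_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not (self.gamma >= 0 and math.isfinite(self.gamma)):
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.calm_threshold < 0:
            raise ValueError("calm_threshold must be >= 0")


@dataclass(frozen=True)
class PlumeParams:
    """Gaussian plume inputs: emission rate Q (mass/s), source height H (m),
    wind speed u (m/s, > 0), and dispersion sigmas (m, > 0)."""

    Q: float
    H: float
    u: float
    sigma_y: float
    sigma_z: float

    def __post_init__(self) -> None:
        if not self.u > 0:
            raise ValueError(f"wind speed u must be > 0, got {self.u}")
        if not (self.sigma_y > 0 and self.sigma_z > 0):
            raise ValueError("dispersion sigmas must be > 0")
        if self.H < 0:
            raise ValueError("source height must be >= 0")


def plume_concentration(x, y, p: PlumeParams):
    """Ground-level Gaussian plume concentration at downwind x, crosswind y.

    C = Q / (π·u·σy·σz) · exp(−y²/2σy²) · exp(−H²/2σz²); zero upwind (x <= 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = (
        p.Q
        / (math.pi * p.u * p.sigma_y * p.sigma_z)
        * np.exp(-(y**2) / (2 * p.sigma_y**2))
        * math.exp(-(p.H**2) / (2 * p.sigma_z**2))
    )
    c = np.where(x > 0, c, 0.0)
    if c.ndim == 0:
        return float(c)
    return c


def angular_deviation(a, b):
    """Smallest absolute angle in degrees between two directions, in [0, 180]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("angles must be finite")
    d = np.abs(a - b) % 360.0
    d = np.where(d > 180.0, 360.0 - d, d)
    if d.ndim == 0:
        return float(d)
    return d


def _flow_direction(u, v):
    """Compass azimuth of the air motion (toward-direction) for components."""
    return np.degrees(np.arctan2(u, v)) % 360.0


def default_cost_law(length, theta_bar, params: CostParams):
    """The directional penalty law L·(1 + γ·(θ̄/180)^β)."""
    return length * (1.0 + params.gamma * (theta_bar / 180.0) ** params.beta)


def edge_cost(
    wind_a: tuple[float, float],
    wind_b: tuple[float, float],
    edge_vector: tuple[float, float],
    params: CostParams,
    cost_law: Callable = default_cost_law,
) -> float:
    """Cost of moving along one lattice edge given the winds at its endpoints.

    ``wind_a``/``wind_b`` are (u, v) at the tail and head cells; the edge
    vector must be one of the 8 lattice offsets scaled by the cell size.
    A calm endpoint (speed below ``params.calm_threshold``) contributes zero
    angular deviation.
    """
    dx, dy = edge_vector
    length = math.hypot(dx, dy)
    if length <= 0:
        raise ValueError("edge_vector must be nonzero")
    step = min(abs(c) for c in (dx, dy) if c != 0)
    if not all(abs(abs(c) - step) < 1e-9 * step or abs(c) < 1e-9 * step for c in (dx, dy)):
        raise ValueError(f"edge_vector {edge_vector} is not an 8-neighbour lattice offset")

    edge_dir = math.degrees(math.atan2(dx, dy)) % 360.0
    devs = []
    for (u, v) in (wind_a, wind_b):
        if math.hypot(u, v) < params.calm_threshold:
            devs.append(0.0)
        else:
            devs.append(angular_deviation(_flow_direction(u, v), edge_dir))
    theta_bar = 0.5 * (devs[0] + devs[1])

    cost = cost_law(length, theta_bar, params)
    if params.speed_weighting:
        mean_speed = 0.5 * (math.hypot(*wind_a) + math.hypot(*wind_b))
        cost /= max(mean_speed, params.calm_threshold)
    return float(cost)


@dataclass(frozen=True)
class CostGraph:
    """Directed 8-neighbour lattice with per-edge traversal costs.

    ``costs[k]`` holds, for neighbour direction k in the N, NE, E, SE, S,
    SW, W, NW order, the cost of the edge leaving each cell toward that
    neighbour; entries leaving the grid are +inf. ``lengths`` gives the
    geometric edge length per direction.
    """

    grid: GridSpec
    params: CostParams
    costs: np.ndarray  # (8, n_rows, n_cols); inf where no edge
    lengths: np.ndarray  # (8,)

    @property
    def n_edges(self) -> int:
        return int(np.isfinite(self.costs).sum())

    def out_edges(self, row: int, col: int):
        """Yield (neighbour_cell, cost, length) in lexicographic order."""
        self.grid._check_cell(row, col)
        for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
            r2, c2 = row + dr, col + dc
            if 0 <= r2 < self.grid.n_rows and 0 <= c2 < self.grid.n_cols:
                yield (r2, c2), float(self.costs[k, row, col]), float(self.lengths[k])

    def reversed(self) -> "CostGraph":
        """Graph with every edge reversed (for point-to-station distances)."""
        rev = np.full_like(self.costs, np.inf)
        nr, nc = self.grid.shape
        for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
            kk = (k + 4) % 8  # opposite direction
            src = self.costs[k]
            # cost of edge (r,c)->(r+dr,c+dc) becomes out-edge of head cell
            r_lo, r_hi = max(dr, 0), nr + min(dr, 0)
            c_lo, c_hi = max(dc, 0), nc + min(dc, 0)
            rev[kk, r_lo:r_hi, c_lo:c_hi] = src[r_lo - dr:r_hi - dr, c_lo - dc:c_hi - dc]
        return CostGraph(grid=self.grid, params=self.params, costs=rev, lengths=self.lengths)

    def to_edge_dataframe(self) -> pd.DataFrame:
        """Edge list `from_row,from_col,to_row,to_col,length_m,cost` (debug export)."""
        rows = []
        for r in range(self.grid.n_rows):
            for c in range(self.grid.n_cols):
                for (r2, c2), cost, length in self.out_edges(r, c):
                    rows.append((r, c, r2, c2, length, cost))
        return pd.DataFrame(
            rows, columns=["from_row", "from_col", "to_row", "to_col", "length_m", "cost"]
        )


def build_cost_graph(
    field: WindRaster,
    params: CostParams | None = None,
    cost_law: Callable = default_cost_law,
) -> CostGraph:
    """Reform a gridded wind field into the directed movement-cost graph.

    Every interior cell gets 8 outgoing edges (border cells fewer); each
    edge's cost comes from the penalty law applied to the mean angular
    deviation at its two incident cells. Deterministic given field and
    params.
    """
    params = params or CostParams()
    grid = field.grid
    nr, nc = grid.shape

    flow = _flow_direction(field.u, field.v)
    speed = field.speed
    calm = speed < params.calm_threshold

    cell = grid.cell_size
    lengths = np.array(
        [cell * math.hypot(dr, dc) for dr, dc in NEIGHBOR_OFFSETS]
    )

    costs = np.full((8, nr, nc), np.inf)
    for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        edge_dir = NEIGHBOR_DIRECTIONS[k]
        dev = angular_deviation(flow, edge_dir)
        dev = np.where(calm, 0.0, dev)
        # tail slice (cells with a neighbour in direction k) and head slice
        r_lo, r_hi = max(-dr, 0), nr - max(dr, 0)
        c_lo, c_hi = max(-dc, 0), nc - max(dc, 0)
        dev_a = dev[r_lo:r_hi, c_lo:c_hi]
        dev_b = dev[r_lo + dr:r_hi + dr, c_lo + dc:c_hi + dc]
        theta_bar = 0.5 * (dev_a + dev_b)
        ck = cost_law(lengths[k], theta_bar, params)
        if params.speed_weighting:
            sp_a = speed[r_lo:r_hi, c_lo:c_hi]
            sp_b = speed[r_lo + dr:r_hi + dr, c_lo + dc:c_hi + dc]
            ck = ck / np.maximum(0.5 * (sp_a + sp_b), params.calm_threshold)
        costs[k, r_lo:r_hi, c_lo:c_hi] = ck

    return CostGraph(grid=grid, params=params, costs=costs, lengths=lengths)
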