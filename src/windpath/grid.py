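"""Grid geometry shared by every stage of the pipeline.

All coordinates are projected metres. Internally arrays are stored with
row 0 at the *south* edge (y increases with row index); file writers that
need north-up output flip at the boundary. Cell centres sit at
``x_origin + (col + 0.5) * cell_size`` and the analogous expression in y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """A regular square-celled grid.

    Parameters
    ----------
    x_origin, y_origin : float
        Lower-left corner of the lower-left cell, metres.
    cell_size : float
        Cell edge length, metres; must be positive.
    n_rows, n_cols : int
        Grid dimensions; each at least 2.
    """

    x_origin: float
    y_origin: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_origin) and math.isfinite(self.y_origin)):
            raise ValueError("grid origin must be finite")
        if not (self.cell_size > 0 and math.isfinite(self.cell_size)):
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError(
                f"grid must be at least 2x2, got {self.n_rows}x{self.n_cols}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def x_max(self) -> float:
        return self.x_origin + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_origin + self.n_rows * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Centre coordinates of cell ``(row, col)``; row 0 is southernmost."""
        self._check_cell(row, col)
        return (
            self.x_origin + (col + 0.5) * self.cell_size,
            self.y_origin + (row + 0.5) * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(X, Y)`` of all cell-centre coordinates, shape (n_rows, n_cols)."""
        xs = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_origin + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def contains(self, x: float, y: float) -> bool:
        return (
            self.x_origin <= x <= self.x_max and self.y_origin <= y <= self.y_max
        )

    def nearest_cell(self, x: float, y: float) -> tuple[int, int]:
        """Cell whose centre is nearest to ``(x, y)``, clipped to the grid."""
        col = int(np.clip(np.floor((x - self.x_origin) / self.cell_size), 0, self.n_cols - 1))
        row = int(np.clip(np.floor((y - self.y_origin) / self.cell_size), 0, self.n_rows - 1))
        return (row, col)

    def _check_cell(self, row: int, col: int) -> None:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(
                f"cell ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid"
            )
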