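"""Continuous wind fields from scattered station observations.

A wind vector observed as (speed, direction) is decomposed into Cartesian
components u (eastward) and v (northward); each component is interpolated
separately with multiquadric radial basis functions (MQ-RBF), and the
continuous field is recomposed from the two component surfaces. Directions
follow the meteorological convention by default: the angle the wind blows
*from*, measured clockwise from north, so a 180° wind (southerly) moves air
northward, (u, v) = (0, +speed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .grid import GridSpec

__all__ = [
    "WindObservation",
    "WindRaster",
    "MQRBFModel",
    "decompose_wind",
    "recompose_wind",
    "fit_mq_rbf",
    "interpolate_wind_field",
    "default_shape_c",
]

_CONVENTIONS = ("from", "toward")

# condition-number ceiling for the dense MQ system
_COND_LIMIT = 1e12


def _check_convention(convention: str) -> None:
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}, got {convention!r}")


@dataclass(frozen=True)
class WindObservation:
    """One station's wind sample: speed in m/s, direction in degrees [0, 360)."""

    station_id: str
    x: float
    y: float
    speed: float
    direction: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"station {self.station_id}: coordinates must be finite")
        if not math.isfinite(self.speed) or self.speed < 0:
            raise ValueError(
                f"station {self.station_id}: speed must be finite and >= 0, got {self.speed}"
            )
        if not math.isfinite(self.direction):
            raise ValueError(f"station {self.station_id}: direction must be finite")
        object.__setattr__(self, "direction", self.direction % 360.0)

    def components(self, convention: str = "from") -> tuple[float, float]:
        return decompose_wind(self.speed, self.direction, convention)


def decompose_wind(
    speed: float, direction: float, convention: str = "from"
) -> tuple[float, float]:
    """Split (speed, direction) into eastward u and northward v components.

    With ``convention="from"`` (meteorological) the direction is where the
    wind comes from: u = -speed·sin(dir), v = -speed·cos(dir). With
    ``"toward"`` the signs flip and the direction is that of the air motion.
    """
    _check_convention(convention)
    if not np.all(np.isfinite(direction)):
        raise ValueError("direction must be finite")
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0) or not np.all(np.isfinite(speed)):
        raise ValueError("speed must be finite and >= 0")
    rad = np.deg2rad(direction)
    u = -speed * np.sin(rad)
    v = -speed * np.cos(rad)
    if convention == "toward":
        u, v = -u, -v
    if np.ndim(u) == 0:
        return (float(u), float(v))
    return (u, v)


def recompose_wind(u, v, convention: str = "from"):
    """Inverse of :func:`decompose_wind`; calm (u=v=0) maps to (0, 0°)."""
    _check_convention(convention)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("components must be finite")
    speed = np.hypot(u, v)
    uu, vv = (u, v) if convention == "toward" else (-u, -v)
    direction = np.degrees(np.arctan2(uu, vv)) % 360.0
    direction = np.where(speed == 0, 0.0, direction)
    if np.ndim(speed) == 0:
        return (float(speed), float(direction))
    return (speed, direction)


@dataclass(frozen=True)
class MQRBFModel:
    """Fitted multiquadric RBF surface f(p) = Σ λ_k φ(‖p − p_k‖), φ(r) = √(r²+c²).

    No polynomial term is appended; the plain multiquadric system is solved
    directly, so the model interpolates the fitted values exactly.
    """

    centres: np.ndarray  # (n, 2)
    coefficients: np.ndarray  # (n,)
    shape_c: float

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.centres):
            raise ValueError("one coefficient per centre required")

    def __call__(self, points) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        phi = np.sqrt(cdist(points, self.centres, "sqeuclidean") + self.shape_c**2)
        return phi @ self.coefficients


def fit_mq_rbf(points, values, shape_c: float) -> MQRBFModel:
    """Solve the dense MQ interpolation system Φλ = values.

    Φ_ij = √(‖p_i − p_j‖² + c²). Raises on duplicate points and on an
    ill-conditioned system (condition estimate above 1e12).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float)
    if points.shape[0] == 0:
        raise ValueError("at least one point required")
    if points.shape[0] != values.shape[0]:
        raise ValueError("points and values must have the same length")
    if not (shape_c > 0 and math.isfinite(shape_c)):
        raise ValueError(f"shape_c must be positive, got {shape_c}")

    sq = cdist(points, points, "sqeuclidean")
    off_diag = sq[~np.eye(len(points), dtype=bool)]
    if off_diag.size and off_diag.min() == 0.0:
        raise ValueError("duplicate points in RBF fit")

    phi = np.sqrt(sq + shape_c**2)
    cond = np.linalg.cond(phi)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"MQ-RBF system ill-conditioned: condition estimate {cond:.3e}"
        )
    coeff = np.linalg.solve(phi, values)
    return MQRBFModel(centres=points, coefficients=coeff, shape_c=float(shape_c))


def default_shape_c(points, fallback: float) -> float:
    """Mean nearest-neighbour spacing of the stations (scale-aware default)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 2:
        return float(fallback)
    d = cdist(points, points)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


@dataclass(frozen=True)
class WindRaster:
    """Gridded wind field as u/v component arrays of shape (n_rows, n_cols)."""

    grid: GridSpec
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if u.shape != self.grid.shape or v.shape != self.grid.shape:
            raise ValueError(
                f"component arrays must have shape {self.grid.shape}, "
                f"got {u.shape} and {v.shape}"
            )
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise ValueError("wind components must be finite")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    @property
    def direction(self) -> np.ndarray:
        """Meteorological from-direction in degrees, 0 at calm cells."""
        _, d = recompose_wind(self.u, self.v, "from")
        return d


def interpolate_wind_field(
    observations: list[WindObservation],
    grid: GridSpec,
    shape_c: float | None = None,
    convention: str = "from",
) -> WindRaster:
    """Interpolate scattered wind observations onto the grid cell centres.

    Each observation is decomposed into (u, v); one MQ-RBF model is fitted
    per component and evaluated at every cell centre. ``shape_c`` defaults
    to the mean nearest-neighbour station spacing (the grid cell size for a
    single station).
    """
    if not observations:
        raise ValueError("at least one wind observation required")
    _check_convention(convention)
    pts = np.array([(o.x, o.y) for o in observations], dtype=float)
    comps = np.array([o.components(convention) for o in observations], dtype=float)
    if shape_c is None:
        shape_c = default_shape_c(pts, fallback=grid.cell_size)

    model_u = fit_mq_rbf(pts, comps[:, 0], shape_c)
    model_v = fit_mq_rbf(pts, comps[:, 1], shape_c)

    X, Y = grid.cell_centers()
    cells = np.column_stack([X.ravel(), Y.ravel()])
    u = model_u(cells).reshape(grid.shape)
    v = model_v(cells).reshape(grid.shape)
    return WindRaster(grid=grid, u=u, v=v)
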