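"""File plumbing: station CSVs, ESRI ASCII grids, matrices and reports.

All tabular formats are headered UTF-8 CSV with a decimal point. Rasters
use the ESRI ASCII grid dialect with nodata −9999, written north-up
(first data row is the northernmost); internal arrays keep row 0 at the
south edge, so writers and readers flip at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec
from .interpolation import ConcentrationObservation, Surface
from .windfield import WindObservation, WindRaster

__all__ = [
    "read_wind_stations",
    "write_wind_stations",
    "read_concentration_stations",
    "write_concentration_stations",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_wind_raster",
    "read_wind_raster",
    "write_surface",
    "read_surface",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_cv_report",
]

NODATA = -9999.0

_WIND_COLUMNS = ["station_id", "x", "y", "speed", "direction"]
_CONC_COLUMNS = ["station_id", "x", "y", "value"]


def _read_station_csv(path, columns):
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty station file") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; header must be {columns}")
    for i, row in df.iterrows():
        for c in columns[1:]:
            try:
                float(row[c])
            except (TypeError, ValueError):
                # +2: header line plus 1-based numbering
                raise ValueError(
                    f"{path}, line {i + 2}: non-numeric {c!r} value {row[c]!r}"
                ) from None
    return df


def read_wind_stations(path) -> list[WindObservation]:
    """Read `station_id,x,y,speed,direction` CSV into observations."""
    df = _read_station_csv(path, _WIND_COLUMNS)
    return [
        WindObservation(str(r.station_id), float(r.x), float(r.y),
                        float(r.speed), float(r.direction))
        for r in df.itertuples(index=False)
    ]


def write_wind_stations(path, observations: list[WindObservation]) -> None:
    pd.DataFrame(
        [(o.station_id, o.x, o.y, o.speed, o.direction) for o in observations],
        columns=_WIND_COLUMNS,
    ).to_csv(path, index=False, encoding="utf-8")


def read_concentration_stations(path) -> list[ConcentrationObservation]:
    """Read `station_id,x,y,value` CSV into observations."""
    df = _read_station_csv(path, _CONC_COLUMNS)
    return [
        ConcentrationObservation(str(r.station_id), float(r.x), float(r.y), float(r.value))
        for r in df.itertuples(index=False)
    ]


def write_concentration_stations(path, observations: list[ConcentrationObservation]) -> None:
    pd.DataFrame(
        [(o.station_id, o.x, o.y, o.value) for o in observations],
        columns=_CONC_COLUMNS,
    ).to_csv(path, index=False, encoding="utf-8")


def write_ascii_grid(path, grid: GridSpec, values: np.ndarray, nodata: float = NODATA) -> None:
    """Write one band as an ESRI ASCII grid (north-up)."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} != grid shape {grid.shape}")
    out = np.where(np.isfinite(values), values, nodata)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {grid.y_origin!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in out[::-1]:  # internal row 0 is south; files are north-up
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid back into (GridSpec, values) with NaN nodata."""
    with open(path, encoding="utf-8") as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    grid = GridSpec(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        cell_size=header["cellsize"],
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
    )
    data = np.atleast_2d(data)[::-1]  # back to row 0 = south
    data = np.where(data == header["nodata_value"], np.nan, data)
    return grid, data


def write_wind_raster(u_path, v_path, raster: WindRaster) -> None:
    """Write the u and v component bands as two ASCII grids."""
    write_ascii_grid(u_path, raster.grid, raster.u)
    write_ascii_grid(v_path, raster.grid, raster.v)


def read_wind_raster(u_path, v_path) -> WindRaster:
    grid_u, u = read_ascii_grid(u_path)
    grid_v, v = read_ascii_grid(v_path)
    if grid_u != grid_v:
        raise ValueError("u and v rasters have mismatched grids")
    return WindRaster(grid=grid_u, u=u, v=v)


def write_surface(path, surface: Surface) -> None:
    write_ascii_grid(path, surface.grid, surface.values)


def read_surface(path) -> Surface:
    grid, values = read_ascii_grid(path)
    return Surface(grid=grid, values=values)


def write_distance_matrix(path, row_ids, col_ids, matrix) -> None:
    """Station-by-station distance matrix CSV; first row/column are ids."""
    matrix = np.asarray(matrix, dtype=float)
    pd.DataFrame(matrix, index=list(row_ids), columns=list(col_ids)).to_csv(
        path, index_label="station_id", encoding="utf-8"
    )


def read_distance_matrix(path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0, encoding="utf-8")
    return list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float)


def write_cv_report(csv_path, json_path, table: pd.DataFrame, summary: dict) -> None:
    """Write the per-station comparison CSV and the summary-statistics JSON."""
    table.to_csv(csv_path, index=False, float_format="%.2f", encoding="utf-8")
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
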