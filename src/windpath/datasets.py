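"""Packaged worked example: the Beijing May-2013 daily PM2.5 comparison.

The published comparison of SWPD-based and Euclidean IDW over the
13-station urban network of Beijing provides (a) the full per-station
hold-out table for 21 May 2013 and (b) the per-date summary statistics and
improvement ratios for the six experimental dates. Both are reproduced
here as plain data so the evaluation statistics can be re-derived and
checked without any download; the underlying monitoring feeds themselves
were never deposited.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_may21_example", "load_daily_summary"]

# 21 May 2013, 13 urban stations: hold-out estimates of both IDW variants,
# the measured values (µg/m³), and the printed signed relative errors (%).
_MAY21 = [
    # station, est_idws, est_idwe, measured, relerr_idws, relerr_idwe
    ("A", 100.9, 100.2, 129.0, -21.78, -22.33),
    ("B", 116.8, 115.9, 100.0, 16.80, 15.90),
    ("C", 115.7, 121.6, 104.0, 11.25, 16.92),
    ("D", 113.7, 112.6, 95.0, 19.68, 18.53),
    ("E", 100.7, 106.1, 104.0, -3.17, 2.02),
    ("F", 106.2, 107.6, 98.0, 8.37, 9.80),
    ("G", 101.3, 103.2, 179.0, -43.41, -42.35),
    ("H", 123.8, 136.3, 98.0, 26.33, 39.08),
    ("I", 111.2, 117.5, 112.0, -0.71, 4.91),
    ("J", 111.9, 113.6, 118.0, -5.17, -3.73),
    ("K", 111.0, 118.4, 100.0, 11.00, 18.40),
    ("L", 105.6, 112.5, 91.0, 16.04, 23.63),
    ("M", 94.9, 95.6, 113.0, -16.02, -15.40),
]

# Six experimental dates: daily mean PM2.5 (µg/m³), wind speed (m/s),
# wind direction (deg), the published MSE/MAE/MRE of each variant, and the
# published improvement ratios (%).
_DAILY = [
    # date, pm25, speed, direction, mse_idws, mse_idwe, mae_idws, mae_idwe,
    # mre_idws, mre_idwe, improvement_mse, improvement_mae
    ("2013-05-04", 92.2, 2.19, 206.2, 49.33, 62.51, 5.81, 6.24, -0.36, -1.21, 21.07, 7.40),
    ("2013-05-18", 118.8, 1.96, 194.2, 105.86, 129.71, 8.69, 8.91, 0.93, 2.53, 18.39, 2.53),
    ("2013-05-21", 110.8, 1.65, 93.4, 695.81, 781.08, 18.54, 20.99, 1.48, 5.03, 10.92, 13.21),
    ("2013-05-26", 106.9, 1.71, 101.9, 85.78, 90.23, 8.17, 8.09, -0.27, 0.41, 4.93, -0.98),
    ("2013-05-28", 17.7, 1.99, 285.3, 96.71, 113.19, 8.22, 9.09, 0.22, 0.35, 14.56, 10.58),
    ("2013-05-29", 78.8, 1.53, 251.7, 13.83, 18.22, 2.82, 2.99, -1.63, -2.59, 24.11, 6.03),
]


def load_may21_example() -> pd.DataFrame:
    """The 13-station hold-out comparison for 21 May 2013.

    Columns: station_id, estimate_idws, estimate_idwe, measured,
    relerr_idws, relerr_idwe (relative errors in signed percent).
    """
    return pd.DataFrame(
        _MAY21,
        columns=[
            "station_id", "estimate_idws", "estimate_idwe", "measured",
            "relerr_idws", "relerr_idwe",
        ],
    )


def load_daily_summary() -> pd.DataFrame:
    """Per-date accuracy summary for the six experimental dates of May 2013."""
    return pd.DataFrame(
        _DAILY,
        columns=[
            "date", "pm25", "wind_speed", "wind_direction",
            "mse_idws", "mse_idwe", "mae_idws", "mae_idwe",
            "mre_idws", "mre_idwe", "improvement_mse", "improvement_mae",
        ],
    )
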