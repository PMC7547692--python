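"""Climate calibration statistics for the An'sai field-station region.

Monthly precipitation statistics characteristic of the hilly Loess
Plateau around An'sai (semi-arid, monsoonal: the July–September wet
season delivers more than half of the ~560 mm annual total).  The
table drives the stochastic weather generator: per-month wet-day
frequency and a gamma distribution of wet-day amounts, with the gamma
scale derived so the expected monthly total matches ``mean_mm``.

The monthly means sum to 560 mm, the regional mean annual
precipitation.  A companion table provides a monthly potential-
evapotranspiration climatology (mm/day) used by the bucket hydrology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# month -> (expected monthly precip mm, wet-day probability, gamma shape)
_ANSAI_ROWS = [
    (1, 5.0, 0.08, 0.70),
    (2, 8.0, 0.10, 0.70),
    (3, 18.0, 0.14, 0.75),
    (4, 28.0, 0.18, 0.80),
    (5, 45.0, 0.24, 0.85),
    (6, 60.0, 0.28, 0.90),
    (7, 125.0, 0.40, 0.95),
    (8, 120.0, 0.38, 0.95),
    (9, 80.0, 0.32, 0.90),
    (10, 48.0, 0.22, 0.85),
    (11, 16.0, 0.12, 0.75),
    (12, 7.0, 0.08, 0.70),
]

_DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

# Potential ET climatology (mm/day), continental semi-arid annual cycle.
ANSAI_PET_MM_DAY = np.array(
    [0.4, 0.7, 1.5, 2.8, 3.8, 4.6, 4.4, 3.9, 2.7, 1.6, 0.8, 0.4]
)

#: Manning's roughness coefficient per landcover code
#: (0 = natural shrub/grass, 1 = cropland).
MANNING_N = {0: 0.13, 1: 0.09}


def ansai_climate_table() -> pd.DataFrame:
    """Monthly weather-generator calibration table.

    Columns: month, mean_mm (expected monthly total), wet_prob,
    gamma_shape, gamma_scale (mm).  The scale closes the moment
    identity  mean_mm = days * wet_prob * shape * scale.
    """
    df = pd.DataFrame(
        _ANSAI_ROWS, columns=["month", "mean_mm", "wet_prob", "gamma_shape"]
    )
    df["gamma_scale"] = df["mean_mm"] / (
        _DAYS_IN_MONTH * df["wet_prob"] * df["gamma_shape"]
    )
    return df


def ansai_weather_params(seed: int = 0, persistence: float = 0.3):
    """Weather-generator parameters calibrated to the An'sai table."""
    from .synthetic import WeatherParams

    t = ansai_climate_table()
    return WeatherParams(
        wet_prob=t["wet_prob"].to_numpy(),
        gamma_shape=t["gamma_shape"].to_numpy(),
        gamma_scale=t["gamma_scale"].to_numpy(),
        persistence=persistence,
        seed=seed,
    )


ANSAI_MEAN_ANNUAL_MM = float(sum(r[1] for r in _ANSAI_ROWS))
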