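"""Daily bucket hydrology: rainfall partitioning, soil moisture, runoff.

A single-bucket store per cell (depth = active soil column) receives
infiltration, loses evapotranspiration and free drainage above field
capacity, and sheds the non-infiltrated remainder as same-day runoff.
The volumetric moisture state feeds the decomposition moisture factor
f_d(theta), which peaks at field capacity and falls toward both the
dry and saturated ends.  Runoff accumulated down the flow network
supplies the unit discharge that drives stream-power sediment
transport.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MoistureState",
    "partition_rainfall",
    "update_moisture",
    "moisture_factor",
    "unit_discharge",
]


class HydrologyError(ValueError):
    pass


@dataclass
class MoistureState:
    """Per-cell volumetric soil moisture with bucket parameters.

    theta, porosity, field_capacity and wilting_point are volumetric
    fractions; ``depth_m`` is the bucket depth used to convert between
    fraction and mm of stored water.
    """

    theta: np.ndarray
    porosity: float = 0.45
    field_capacity: float = 0.30
    wilting_point: float = 0.08
    depth_m: float = 1.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if not (0 <= self.wilting_point < self.field_capacity < self.porosity <= 1):
            raise HydrologyError(
                "require 0 <= wilting < field capacity < porosity <= 1"
            )
        if np.any(self.theta < -1e-12) or np.any(self.theta > self.porosity + 1e-12):
            raise HydrologyError("theta must lie in [0, porosity]")

    @property
    def storage_mm(self) -> np.ndarray:
        return self.theta * self.depth_m * 1000.0


def partition_rainfall(precip_mm, state: MoistureState, infiltration_capacity_mm=20.0):
    """Split daily rainfall into (infiltration, runoff), both mm/day.

    Infiltration is limited by the infiltration capacity
    (infiltration excess) and by the remaining pore space
    (saturation excess); the identity infiltration + runoff = precip
    holds exactly.
    """
    p = np.asarray(precip_mm, dtype=float)
    if np.any(p < 0):
        raise HydrologyError("precipitation must be non-negative")
    pore_space_mm = (state.porosity - state.theta) * state.depth_m * 1000.0
    infil = np.minimum(p, np.minimum(infiltration_capacity_mm, pore_space_mm))
    infil = np.maximum(infil, 0.0)
    runoff = p - infil
    return infil, runoff


def update_moisture(
    state: MoistureState,
    infiltration_mm,
    et_demand_mm,
    drainage_coefficient: float = 0.05,
):
    """Advance the bucket one day; returns (new state, actual ET mm, drainage mm).

    Actual ET is the demand scaled linearly below field capacity and
    floored so theta never drops under the wilting point; drainage
    removes a fixed fraction per day of storage above field capacity.
    The water balance Delta(storage) = infiltration - ET - drainage
    closes to machine precision.
    """
    inf = np.asarray(infiltration_mm, dtype=float)
    etd = np.asarray(et_demand_mm, dtype=float)
    if np.any(inf < 0) or np.any(etd < 0) or drainage_coefficient < 0:
        raise HydrologyError("inputs must be non-negative")
    mm = state.depth_m * 1000.0
    theta = state.theta + inf / mm

    avail = np.maximum((theta - state.wilting_point) * mm, 0.0)
    stress = np.clip(
        (theta - state.wilting_point) / (state.field_capacity - state.wilting_point),
        0.0, 1.0,
    )
    et = np.minimum(etd * stress, avail)
    theta = theta - et / mm

    excess = np.maximum((theta - state.field_capacity) * mm, 0.0)
    drain = drainage_coefficient * excess
    # saturation overflow leaves as drainage the same day
    over = np.maximum((theta - drain / mm - state.porosity) * mm, 0.0)
    drain = drain + over
    theta = theta - drain / mm

    new = replace(state, theta=np.clip(theta, 0.0, state.porosity))
    return new, et, drain


def moisture_factor(theta, field_capacity: float, porosity: float,
                    wet_floor: float = 0.25):
    """Decomposition moisture factor f_d(theta) in [0, 1].

    Piecewise linear: rises from 0 at oven-dry to 1 at field capacity
    (the optimum), then falls toward ``wet_floor`` at saturation where
    anoxia suppresses but does not stop decomposition.
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < -1e-12) or np.any(th > porosity + 1e-12):
        raise HydrologyError("theta outside [0, porosity]")
    dry = np.clip(th / field_capacity, 0.0, 1.0)
    wet = wet_floor + (1.0 - wet_floor) * (porosity - th) / (porosity - field_capacity)
    out = np.where(th <= field_capacity, dry, wet)
    return out if out.ndim else float(out)


def unit_discharge(runoff_mm, network, cell_size: float) -> np.ndarray:
    """Per-cell unit discharge q (m^2/day) accumulated down the network.

    Each cell contributes its local runoff volume (runoff depth x cell
    area) plus everything received from upstream; division by the cell
    width converts the volumetric discharge to discharge per unit
    width, the quantity entering the stream-power law.
    """
    r = np.asarray(runoff_mm, dtype=float)
    if r.shape != network.shape:
        raise HydrologyError("runoff grid does not match the flow network")
    local = (r / 1000.0) * cell_size**2  # m^3/day
    q = network.accumulate(local)
    return q / cell_size
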