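"""Daily coupled stepping of hydrology, landscape evolution and SOC.

The engine advances, in order: bucket hydrology -> sediment transport
and elevation change -> lateral SOC transport -> vertical
transformation -> bioturbation (tillage on cropland every April 1).
It keeps two per-cell ledgers — cumulative lateral (transport) and
vertical (transformation) SOC flux — whose sum equals the total
stock change per cell to machine precision, because each ledger
records the stock difference actually produced by its operators.
Monthly ledger increments are retained for intra-annual climatology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import soc_transport as st
from . import terrain
from .ansai import ANSAI_PET_MM_DAY, MANNING_N, ansai_weather_params
from .biogeochem import (
    ReferenceState,
    TransformParams,
    bioturbation_step_arrays,
    calibrate_residence_time,
    depth_attenuation,
    transform_step,
)
from .grid import ElevationGrid, GridDomain
from .hydrology import MoistureState, moisture_factor, partition_rainfall, \
    unit_discharge, update_moisture
from .profiles import ColumnStack, SurfaceSOCMap, build_initial_columns, \
    CROPS_PARAMS, TREES_SHRUBS_PARAMS
from .synthetic import CORNFIELD_LITTER_CURVE, NATURAL_LITTER_CURVE, \
    generate_dem, generate_landcover, generate_ndvi, generate_weather, \
    ndvi_to_litter

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "RunConfig",
    "SimulationInputs",
    "SimulationState",
    "RunResult",
    "build_synthetic_simulation",
    "step_day",
    "run",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One management scenario: litter multiplier x target surface MRT."""

    litter_multiplier: float = 1.0
    target_mrt_years: float = 12.9

    def __post_init__(self) -> None:
        if self.litter_multiplier <= 0 or self.target_mrt_years <= 0:
            raise ValueError("scenario multiplier and MRT must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Engine configuration (durations in calendar years)."""

    duration_years: int = 50
    start_year: int = 2021
    reporting_interval_days: int = 30
    tillage_month: int = 4
    tillage_depth: float = 0.20
    transport_enabled: bool = True
    scenario: ScenarioSpec | None = None
    seed: int = 0
    diffusivity: float = 0.002 / 365.0   # hillslope D_x = D_y, m^2/day
    transport: terrain.TransportParams = field(default_factory=terrain.TransportParams)
    transform: TransformParams = field(default_factory=TransformParams)
    k_soc: float = 1.0
    infiltration_capacity_mm: float = 20.0
    drainage_coefficient: float = 0.05
    routing_interval_days: int = 30
    depth_atten_scale: float = 0.15

    def __post_init__(self) -> None:
        if self.duration_years < 1:
            raise ValueError("duration must be at least 1 year")
        if self.k_soc <= 0:
            raise ValueError("enrichment ratio k_soc must be positive")


@dataclass
class SimulationInputs:
    """Everything a run consumes."""

    dem: ElevationGrid
    landcover: np.ndarray              # 0 natural, 1 cropland
    forcing: pd.DataFrame              # date, precip_mm
    stack: ColumnStack
    litter_by_class: dict[int, np.ndarray]  # per-class kg C/m^2/day by day-of-year
    moisture: MoistureState | None = None
    pet_mm_day: np.ndarray = field(default_factory=lambda: ANSAI_PET_MM_DAY.copy())
    manning_by_class: dict[int, float] = field(default_factory=lambda: dict(MANNING_N))


@dataclass
class SimulationState:
    """Mutable per-day model state with the two flux ledgers."""

    dem: ElevationGrid
    stack: ColumnStack
    moisture: MoistureState
    lateral_ledger: np.ndarray
    vertical_ledger: np.ndarray
    date: pd.Timestamp
    network: terrain.FlowNetwork | None = None
    days_since_routing: int = 0
    totals: dict = field(default_factory=lambda: {
        "litter_kg": 0.0, "efflux_kg": 0.0, "export_kg": 0.0, "clipped_kg": 0.0,
    })


@dataclass
class RunResult:
    """Run outputs: monthly ledger increments plus final state."""

    config: RunConfig
    months: pd.PeriodIndex
    monthly_lateral: np.ndarray        # (n_months, nr, nc) kg C/m^2
    monthly_vertical: np.ndarray
    monthly_precip_mm: np.ndarray      # (n_months,)
    initial_stock: np.ndarray
    final_state: SimulationState
    initial_elevation: np.ndarray

    @property
    def final_stock(self) -> np.ndarray:
        return self.final_state.stack.stock()

    @property
    def stock_change(self) -> np.ndarray:
        return self.final_stock - self.initial_stock

    def to_dataset(self):
        """Gridded monthly output as an xarray Dataset."""
        import xarray as xr

        nr, nc = self.initial_stock.shape
        coords = {"month": self.months.to_timestamp(), "row": np.arange(nr),
                  "col": np.arange(nc)}
        return xr.Dataset(
            {
                "lateral_flux": (("month", "row", "col"), self.monthly_lateral),
                "vertical_flux": (("month", "row", "col"), self.monthly_vertical),
                "precip_mm": (("month",), self.monthly_precip_mm),
                "stock_change": (("row", "col"), self.stock_change),
                "elevation_change": (
                    ("row", "col"),
                    self.final_state.dem.elevation - self.initial_elevation,
                ),
            },
            coords=coords,
        )


# ---------------------------------------------------------------------------
# Synthetic-simulation assembly
# ---------------------------------------------------------------------------

def _synthetic_surface_map(domain: GridDomain, landcover: np.ndarray,
                           seed: int) -> SurfaceSOCMap:
    """Survey-like surface SOC (g C/kg): class means with mild seeded
    spatial variation, interpolated from a coarse synthetic sampling grid."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed + 7)
    noise = gaussian_filter(rng.standard_normal(domain.shape), sigma=4.0,
                            mode="nearest")
    base = np.where(landcover == 1, 3.08, 3.60)  # cornfield ~4.0 kg C/m^3
    vals = base * (1.0 + 0.08 * noise)
    return SurfaceSOCMap(domain, np.maximum(vals, 2.80))


def build_synthetic_simulation(
    kind: str,
    n_rows: int = 32,
    n_cols: int = 32,
    seed: int = 0,
    relief: float = 15.0,
    config: RunConfig | None = None,
    cell_size: float = 2.0,
) -> SimulationInputs:
    """Assemble a full synthetic run (terrain, forcing, NDVI, columns)."""
    config = config or RunConfig()
    domain = GridDomain(n_rows, n_cols, cell_size)
    dem = generate_dem(domain, kind, relief=relief, seed=seed)
    landcover = generate_landcover(domain, kind)

    forcing = generate_weather(
        ansai_weather_params(seed=seed + 1),
        n_years=config.duration_years,
        start_year=config.start_year,
    )

    doy_dates = pd.date_range("2000-01-01", "2000-12-31", freq="D")  # leap: 366
    litter_by_class = {}
    for code, nk, curve in ((0, "natural", NATURAL_LITTER_CURVE),
                            (1, "cornfield", CORNFIELD_LITTER_CURVE)):
        ndvi = generate_ndvi(nk, doy_dates)
        litter_by_class[code] = np.asarray(ndvi_to_litter(ndvi.to_numpy(), curve))

    surface = _synthetic_surface_map(dem.domain, landcover, seed)
    # per-class depth-profile shape (b, c fixed per landcover)
    stack_nat = build_initial_columns(surface, TREES_SHRUBS_PARAMS.b,
                                      TREES_SHRUBS_PARAMS.c)
    stack = stack_nat
    if np.any(landcover == 1):
        stack_crop = build_initial_columns(surface, CROPS_PARAMS.b, CROPS_PARAMS.c)
        mask = landcover == 1
        stack.pools[:, :, mask] = stack_crop.pools[:, :, mask]

    return SimulationInputs(dem=dem, landcover=landcover, forcing=forcing,
                            stack=stack, litter_by_class=litter_by_class)


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------

def _layer_geometry(stack: ColumnStack):
    z_bot = np.cumsum(stack.thickness, axis=0)
    z_mid = z_bot - stack.thickness / 2.0
    return z_bot, z_mid


def _root_weights(stack: ColumnStack, params: TransformParams) -> np.ndarray:
    """Per-layer litter-partition weights (sum 1 over layers).

    Above-ground share to the surface layer; root share distributed
    proportional to an exponential root profile truncated at
    ``root_depth``.
    """
    z_bot, _ = _layer_geometry(stack)
    z_top = z_bot - stack.thickness
    ef = params.root_efold
    lo = np.minimum(z_top, params.root_depth)
    hi = np.minimum(z_bot, params.root_depth)
    seg = np.exp(-lo / ef) - np.exp(-hi / ef)   # ∝ root mass per layer
    total = seg.sum(axis=0)
    seg = np.where(total > 0, seg / np.maximum(total, 1e-30), 0.0)
    w = (1.0 - params.litter_surface_fraction) * seg
    w[0] += params.litter_surface_fraction
    return w


def _k_h_multiplier_field(stack: ColumnStack, landcover: np.ndarray,
                          scenario: ScenarioSpec | None,
                          params: TransformParams) -> np.ndarray:
    """(L, nr, nc) humus-rate multiplier: scenario applies to the top
    5 cm of managed (cropland) cells."""
    L = stack.n_layers
    mult = np.ones((L,) + landcover.shape)
    if scenario is None:
        return mult
    m = calibrate_residence_time(scenario.target_mrt_years,
                                 ReferenceState(params))
    _, z_mid = _layer_geometry(stack)
    in_top = z_mid <= 0.05 + 1e-9
    mult[in_top & (landcover == 1)[None, ...].repeat(L, axis=0)] = m
    return mult


def _tillage(stack: ColumnStack, landcover: np.ndarray, depth: float) -> None:
    """Mix cropland columns down to the layer interface nearest
    ``depth`` (exactly mass-conserving), in place."""
    cells = np.argwhere(landcover == 1)
    for r, c in cells:
        z_bot = np.cumsum(stack.thickness[:, r, c])
        k = int(np.argmin(np.abs(z_bot - depth)))
        zmix = z_bot[k]
        th = stack.thickness[: k + 1, r, c]
        mass = (stack.pools[: k + 1, :, r, c] * th[:, None]).sum(axis=0)
        stack.pools[: k + 1, :, r, c] = mass / zmix


def step_day(state: SimulationState, precip_mm: float, inputs: SimulationInputs,
             config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """Advance one day in place; returns (lateral, vertical) per-cell
    stock increments (kg C/m^2) for aggregation."""
    stack = state.stack
    dt = 1.0
    doy = min(state.date.dayofyear, 366) - 1
    month = state.date.month - 1

    # --- hydrology -------------------------------------------------------
    infil, runoff = partition_rainfall(
        np.full(state.dem.domain.shape, float(precip_mm)),
        state.moisture, config.infiltration_capacity_mm)
    state.moisture, _, _ = update_moisture(
        state.moisture, infil, float(inputs.pet_mm_day[month]),
        config.drainage_coefficient)
    fd = np.asarray(moisture_factor(state.moisture.theta,
                                    state.moisture.field_capacity,
                                    state.moisture.porosity))

    # --- sediment transport and lateral SOC ------------------------------
    stock0 = stack.stock()
    if config.transport_enabled:
        if state.network is None or state.days_since_routing >= config.routing_interval_days:
            state.network = terrain.route_flow(state.dem)
            state.days_since_routing = 0
        state.days_since_routing += 1
        net = state.network

        div_d = terrain.diffusion_divergence(state.dem, config.diffusivity,
                                             config.diffusivity)
        c1 = stack.pools[0]  # (3, nr, nc)
        soc_div = st.soc_diffusive_flux(c1, state.dem, config.diffusivity,
                                        config.diffusivity, config.k_soc)
        div_s = np.zeros_like(div_d)
        if np.any(runoff > 0):
            manning = np.vectorize(inputs.manning_by_class.get)(inputs.landcover)
            q = unit_discharge(runoff, net, state.dem.domain.cell_size)
            sed = terrain.overland_divergence(state.dem, net, q,
                                              config.transport, manning)
            div_s = sed.divergence
            adv, export_rate = st.soc_advective_flux(c1, net, sed, config.k_soc)
            soc_div = soc_div + adv
            state.totals["export_kg"] += export_rate * dt
        state.dem, _ = terrain.step_elevation(state.dem, div_d, div_s, dt)
        clipped = st.apply_transport_to_stack(stack, div_d + div_s, soc_div, dt)
        st.remesh_surface_layer(stack)
        state.totals["clipped_kg"] += clipped * state.dem.domain.cell_area
    lateral = stack.stock() - stock0
    state.lateral_ledger += lateral

    # --- vertical transformation ----------------------------------------
    stock1 = stack.stock()
    litter_cell = np.empty(state.dem.domain.shape)
    for code, series in inputs.litter_by_class.items():
        litter_cell[inputs.landcover == code] = series[min(doy, len(series) - 1)]
    if config.scenario is not None:
        litter_cell = np.where(inputs.landcover == 1,
                               litter_cell * config.scenario.litter_multiplier,
                               litter_cell)

    w = _root_weights(stack, config.transform)
    litter_conc = litter_cell[None, ...] * w / stack.thickness
    _, z_mid = _layer_geometry(stack)
    atten = depth_attenuation(z_mid, float(z_mid[0].mean()),
                              config.depth_atten_scale)
    fd_layers = np.clip(fd[None, ...] * atten, 0.0, 1.0)
    mult = _k_h_multiplier_field(stack, inputs.landcover, config.scenario,
                                 config.transform)

    new_pools, co2 = transform_step(stack.pools, litter_conc, fd_layers,
                                    config.transform, dt, mult)
    stack.pools = new_pools
    area = state.dem.domain.cell_area
    state.totals["litter_kg"] += float(litter_cell.sum()) * dt * area
    state.totals["efflux_kg"] += float((co2 * stack.thickness).sum()) * area

    stack.pools = bioturbation_step_arrays(
        stack.thickness, stack.pools, config.transform.d0_bioturb,
        config.transform.z_bioturb, dt)

    if (state.date.month == config.tillage_month and state.date.day == 1
            and np.any(inputs.landcover == 1)):
        _tillage(stack, inputs.landcover, config.tillage_depth)

    vertical = stack.stock() - stock1
    state.vertical_ledger += vertical

    state.date = state.date + pd.Timedelta(days=1)
    return lateral, vertical


def run(config: RunConfig, inputs: SimulationInputs,
        n_days: int | None = None) -> RunResult:
    """Run the coupled model over the forcing period.

    ``n_days`` limits the run (defaults to the full forcing length);
    deterministic given the config and inputs.
    """
    dx = inputs.dem.domain.cell_size
    if config.diffusivity * 1.0 / dx**2 > 0.25:
        raise terrain.StabilityError("hillslope diffusivity violates the CFL limit")

    forcing = inputs.forcing
    if n_days is None:
        n_days = len(forcing)
    n_days = min(n_days, len(forcing))

    shape = inputs.dem.domain.shape
    state = SimulationState(
        dem=inputs.dem.copy(),
        stack=inputs.stack.copy(),
        moisture=inputs.moisture or MoistureState(np.full(shape, 0.20)),
        lateral_ledger=np.zeros(shape),
        vertical_ledger=np.zeros(shape),
        date=pd.Timestamp(forcing["date"].iloc[0]) if n_days else
        pd.Timestamp(f"{config.start_year}-01-01"),
    )
    initial_stock = state.stack.stock()
    initial_elev = state.dem.elevation.copy()

    months: list[pd.Period] = []
    m_lat: list[np.ndarray] = []
    m_ver: list[np.ndarray] = []
    m_pr: list[float] = []
    precip = forcing["precip_mm"].to_numpy()
    dates = pd.DatetimeIndex(forcing["date"])

    cur = None
    for i in range(n_days):
        per = dates[i].to_period("M")
        if per != cur:
            months.append(per)
            m_lat.append(np.zeros(shape))
            m_ver.append(np.zeros(shape))
            m_pr.append(0.0)
            cur = per
        lat, ver = step_day(state, float(precip[i]), inputs, config)
        m_lat[-1] += lat
        m_ver[-1] += ver
        m_pr[-1] += float(precip[i])
        if dates[i].month == 12 and dates[i].day == 31:
            logger.info("completed year %s", dates[i].year)

    return RunResult(
        config=config,
        months=pd.PeriodIndex(months, freq="M") if months else
        pd.PeriodIndex([], freq="M"),
        monthly_lateral=np.array(m_lat) if m_lat else np.zeros((0,) + shape),
        monthly_vertical=np.array(m_ver) if m_ver else np.zeros((0,) + shape),
        monthly_precip_mm=np.array(m_pr),
        initial_stock=initial_stock,
        final_state=state,
        initial_elevation=initial_elev,
    )
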