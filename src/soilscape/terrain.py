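"""Landscape evolution: D8 flow routing, hillslope diffusion and
detachment-limited overland-flow sediment transport.

Elevation obeys the Exner mass balance

    d(eta)/dt = U - div(q_d) - div(q_s),     U = 0 here,

with q_d a linear (slope-proportional) hillslope-diffusion flux and
div(q_s) the overland-flow term, computed per cell as the smaller of
the detachment capacity D_c and the transport-capacity deficit
(q_out - sum q_in)/d_s; a negative deficit means net deposition.
Flow directions come from steepest-descent D8 on a priority-flood
filled surface (epsilon-incremented so flats drain), tie-broken by
lowest linear index, so routing is deterministic.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np

from .grid import ElevationGrid

logger = logging.getLogger(__name__)

__all__ = [
    "FlowNetwork",
    "TransportParams",
    "SedimentFluxField",
    "route_flow",
    "diffusion_divergence",
    "overland_divergence",
    "step_elevation",
    "StabilityError",
]


class RoutingError(RuntimeError):
    pass


class StabilityError(RuntimeError):
    """Explicit diffusion step would violate the CFL limit."""


_D8_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class FlowNetwork:
    """D8 receiver graph on a filled DEM.

    ``receiver``: flat index of the downstream cell, -1 for exit cells
    (boundary cells with no lower neighbour; water and sediment leave
    the domain there).  ``order`` lists flat indices from upstream to
    downstream, so a single pass accumulates any quantity.
    """

    shape: tuple[int, int]
    cell_size: float
    receiver: np.ndarray
    distance: np.ndarray
    slope: np.ndarray
    filled: np.ndarray
    order: np.ndarray
    drainage_area: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def exits(self) -> np.ndarray:
        return np.flatnonzero(self.receiver < 0)

    def accumulate(self, local: np.ndarray) -> np.ndarray:
        """Downstream-accumulated totals of a per-cell local input."""
        acc = np.asarray(local, dtype=float).ravel().copy()
        rcv = self.receiver
        for i in self.order:
            r = rcv[i]
            if r >= 0:
                acc[r] += acc[i]
        return acc.reshape(self.shape)


def _priority_flood_fill(elev: np.ndarray, eps: float) -> np.ndarray:
    """Barnes priority-flood depression filling with an epsilon gradient."""
    nr, nc = elev.shape
    filled = elev.copy()
    closed = np.zeros(elev.shape, dtype=bool)
    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    for r in range(nr):
        for c in range(nc):
            if r in (0, nr - 1) or c in (0, nc - 1):
                heapq.heappush(heap, (filled[r, c], counter, r, c))
                counter += 1
                closed[r, c] = True
    while heap:
        z, _, r, c = heapq.heappop(heap)
        for dr, dc in _D8_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not closed[rr, cc]:
                closed[rr, cc] = True
                filled[rr, cc] = max(filled[rr, cc], z + eps)
                heapq.heappush(heap, (filled[rr, cc], counter, rr, cc))
                counter += 1
    return filled


def route_flow(dem: ElevationGrid, eps: float = 1e-8) -> FlowNetwork:
    """Build the D8 flow network for a DEM.

    Pits are resolved by priority-flood filling; flow directions are
    steepest descent on the filled surface (ties broken by lowest
    linear index).  Every non-exit cell ends with a receiver, drainage
    areas are >= the cell's own area everywhere, and the receiver
    graph is acyclic by construction (receivers are strictly lower on
    the epsilon-filled surface).
    """
    elev = dem.elevation
    if np.ptp(elev) == 0:
        logger.warning("all-equal DEM: flow routed by deterministic tie-break")
    nr, nc = elev.shape
    filled = _priority_flood_fill(elev, eps)

    zf = filled.ravel()
    receiver = np.full(nr * nc, -1, dtype=np.int64)
    distance = np.full(nr * nc, dem.domain.cell_size)
    slope = np.zeros(nr * nc)
    cs = dem.domain.cell_size
    for r in range(nr):
        for c in range(nc):
            i = r * nc + c
            best_s, best_j, best_d = 0.0, -1, cs
            for dr, dc in _D8_OFFSETS:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nr and 0 <= cc < nc):
                    continue
                j = rr * nc + cc
                d = cs * (np.sqrt(2.0) if dr and dc else 1.0)
                s = (zf[i] - zf[j]) / d
                if s > best_s or (s == best_s and s > 0 and j < best_j):
                    best_s, best_j, best_d = s, j, d
            receiver[i] = best_j
            distance[i] = best_d
            slope[i] = max(best_s, 0.0)

    order = np.argsort(-zf, kind="stable")
    area = np.full(nr * nc, cs * cs)
    for i in order:
        r = receiver[i]
        if r >= 0:
            area[r] += area[i]
    return FlowNetwork(
        shape=(nr, nc), cell_size=cs, receiver=receiver, distance=distance,
        slope=slope, filled=filled, order=order,
        drainage_area=area.reshape(nr, nc),
    )


# ---------------------------------------------------------------------------
# Hillslope diffusion
# ---------------------------------------------------------------------------

def diffusion_divergence(dem: ElevationGrid, D_x: float, D_y: float) -> np.ndarray:
    """Divergence of the linear hillslope-diffusion flux (m/day).

    Face-centred flux form with zero-flux domain boundaries, so the
    area-weighted sum of the divergence is exactly zero (sediment is
    only rearranged; export happens through the overland term).
    Positive divergence lowers the surface.
    """
    if D_x < 0 or D_y < 0:
        raise ValueError("diffusivities must be non-negative")
    eta = dem.elevation
    dx = dem.domain.cell_size
    div = np.zeros_like(eta)
    # x faces (between columns): flux F = -D_x * d(eta)/dx
    fx = -D_x * np.diff(eta, axis=1) / dx
    div[:, :-1] += fx / dx  # right-face contribution to div
    div[:, 1:] -= fx / dx   # same face is the left face of the next cell
    fy = -D_y * np.diff(eta, axis=0) / dx
    div[:-1, :] += fy / dx
    div[1:, :] -= fy / dx
    return div  # positive where flux diverges (crests erode)


# ---------------------------------------------------------------------------
# Overland-flow transport
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransportParams:
    """Stream-power transport-capacity and detachment-capacity law.

    capacity  q_out = (k_t / n_manning) * q^m_exp * S^n_exp   [m^2/day]
    detachment D_c  = (k_d / n_manning) * q^dc_exp * S        [m/day]
    """

    k_t: float = 4.0e-4
    m_exp: float = 1.5
    n_exp: float = 1.1
    k_d: float = 4.0e-4
    dc_exp: float = 0.5

    def __post_init__(self) -> None:
        if self.k_t < 0 or self.k_d < 0:
            raise ValueError("transport coefficients must be non-negative")


@dataclass
class SedimentFluxField:
    """Overland sediment-transport solution on the flow network.

    ``divergence`` (m/day): positive = erosion, negative = deposition;
    ``detachment_limited``: True where D_c capped the erosion rate;
    ``q_out``/``q_in`` (m^2/day): actual sediment fluxes leaving /
    entering each cell; ``export_volume`` (m^3/day): total sediment
    leaving through exit cells.
    """

    divergence: np.ndarray
    detachment_limited: np.ndarray
    capacity: np.ndarray
    detachment: np.ndarray
    q_out: np.ndarray
    q_in: np.ndarray
    export_volume: float


def overland_divergence(
    dem: ElevationGrid,
    network: FlowNetwork,
    discharge: np.ndarray,
    params: TransportParams = TransportParams(),
    manning_n: np.ndarray | float = 0.1,
) -> SedimentFluxField:
    """Detachment-limited overland sediment divergence (m/day).

    Cells are processed from upstream to downstream.  Each cell's
    erosion rate is min(D_c, (capacity - inflow)/d_s); when the
    incoming flux exceeds the local capacity the rate is negative and
    the cell deposits.  The actual outgoing flux (inflow + erosion *
    d_s) feeds the downstream cell, which makes the scheme exactly
    mass-conservative: the area-weighted divergence sums to the outlet
    export.
    """
    if discharge is None:
        raise ValueError("discharge field is required")
    q = np.asarray(discharge, dtype=float).ravel()
    if q.size != network.n_cells:
        raise ValueError("discharge does not match the network")
    n_man = np.broadcast_to(np.asarray(manning_n, dtype=float), network.shape).ravel()
    S = network.slope
    d_s = network.cell_size

    cap = (params.k_t / n_man) * np.power(q, params.m_exp) * np.power(S, params.n_exp)
    d_c = (params.k_d / n_man) * np.power(q, params.dc_exp) * S

    rcv = network.receiver
    q_in = np.zeros(network.n_cells)
    q_out = np.zeros(network.n_cells)
    div = np.zeros(network.n_cells)
    limited = np.zeros(network.n_cells, dtype=bool)
    export = 0.0
    for i in network.order:
        r = rcv[i]
        if r < 0:
            # exit cell: open boundary, flux passes through unchanged
            q_out[i] = q_in[i]
            export += q_in[i] * d_s
            continue
        deficit = (cap[i] - q_in[i]) / d_s
        if d_c[i] < deficit:
            ero = d_c[i]
            limited[i] = True
        else:
            ero = deficit
        div[i] = ero
        out = q_in[i] + ero * d_s
        q_out[i] = out
        q_in[r] += out
    sh = network.shape
    return SedimentFluxField(
        divergence=div.reshape(sh),
        detachment_limited=limited.reshape(sh),
        capacity=cap.reshape(sh),
        detachment=d_c.reshape(sh),
        q_out=q_out.reshape(sh),
        q_in=q_in.reshape(sh),
        export_volume=export,
    )


def step_elevation(
    dem: ElevationGrid,
    div_diffusive: np.ndarray,
    div_overland: np.ndarray,
    dt: float,
    diffusivity: float | None = None,
) -> tuple[ElevationGrid, np.ndarray]:
    """Explicit Euler elevation update  eta -= dt * (div_d + div_s).

    Soil thickness changes identically and is floored at zero; the
    floored deficit (m of over-erosion) is returned so callers can log
    and account for it.  If ``diffusivity`` is given, the diffusion
    CFL number D*dt/dx^2 is checked against 0.25 before stepping.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dx = dem.domain.cell_size
    if diffusivity is not None and diffusivity * dt / dx**2 > 0.25:
        raise StabilityError(
            f"diffusion CFL {diffusivity * dt / dx**2:.3g} exceeds 0.25"
        )
    dz = -dt * (np.asarray(div_diffusive) + np.asarray(div_overland))
    new_elev = dem.elevation + dz
    thickness = dem.soil_thickness + dz
    deficit = np.maximum(-thickness, 0.0)
    if np.any(deficit > 0):
        logger.warning("soil thickness exhausted at %d cells", int((deficit > 0).sum()))
        new_elev = new_elev + deficit
        thickness = thickness + deficit
    out = dem.copy()
    out.elevation = new_elev
    out.soil_thickness = thickness
    return out, deficit
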