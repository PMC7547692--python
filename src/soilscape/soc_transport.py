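"""Lateral SOC transport with the sediment fluxes (enrichment ratio).

Surface-layer SOC moves with the soil: the SOC flux is k_soc * C1 * q
for both the diffusive and the overland sediment flux, where C1 is
the surface-layer concentration of each pool and k_soc an enrichment
ratio expressing preferential mobilisation of carbon relative to bulk
soil (default 1: no enrichment).  Eroded mass carries the donor
cell's concentration and pool proportions; deposition adds the
incoming (upstream) carbon to the receiving surface layer.  On the
detachment-limited branch the SOC divergence is k_soc * C1 * D_c;
otherwise it is the net of donor-concentration fluxes,
(k_soc C1_out q_out - sum k_soc C1_in q_in) / d_s.
"""

from __future__ import annotations

import logging

import numpy as np

from .grid import ElevationGrid
from .profiles import ColumnStack, SOCColumn
from .terrain import FlowNetwork, SedimentFluxField

logger = logging.getLogger(__name__)

__all__ = [
    "soc_diffusive_flux",
    "soc_advective_flux",
    "update_surface_layer",
    "apply_transport_to_stack",
    "remesh_surface_layer",
]


class TransportError(ValueError):
    pass


def _pool_axis(c1: np.ndarray, dem_shape) -> np.ndarray:
    c1 = np.asarray(c1, dtype=float)
    if c1.shape == dem_shape:
        return c1[None, ...]
    if c1.ndim == 3 and c1.shape[1:] == dem_shape:
        return c1
    raise TransportError(f"surface-concentration shape {c1.shape} does not match grid")


def soc_diffusive_flux(c1, dem: ElevationGrid, D_x: float, D_y: float,
                       k_soc: float = 1.0) -> np.ndarray:
    """Divergence of the diffusive SOC flux (kg C m^-2 day^-1 per pool).

    Face fluxes are the sediment diffusion fluxes times k_soc and the
    donor (upslope) cell's surface concentration, so moving soil
    carries its own carbon; zero-flux domain boundaries make the
    operator globally conservative.  With uniform C1 and k_soc = 1
    this reduces exactly to C1 times the sediment diffusive
    divergence.
    """
    C = _pool_axis(c1, dem.domain.shape)
    eta = dem.elevation
    dx = dem.domain.cell_size
    div = np.zeros_like(C)

    fx = -D_x * np.diff(eta, axis=1) / dx  # >0: flux from col j to j+1
    donor_x = np.where(fx[None, ...] > 0, C[:, :, :-1], C[:, :, 1:])
    fcx = k_soc * donor_x * fx[None, ...]
    div[:, :, :-1] += fcx / dx
    div[:, :, 1:] -= fcx / dx

    fy = -D_y * np.diff(eta, axis=0) / dx
    donor_y = np.where(fy[None, ...] > 0, C[:, :-1, :], C[:, 1:, :])
    fcy = k_soc * donor_y * fy[None, ...]
    div[:, :-1, :] += fcy / dx
    div[:, 1:, :] -= fcy / dx

    return div if np.asarray(c1).ndim == 3 else div[0]


def soc_advective_flux(
    c1,
    network: FlowNetwork,
    sediment: SedimentFluxField,
    k_soc: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Divergence of the overland SOC flux and the outlet SOC export.

    Walks the flow network from upstream to downstream carrying the
    actual SOC flux per pool.  Detachment-limited cells contribute
    k_soc * C1 * D_c; capacity-branch cells send k_soc * C1 * q_out
    downstream, so the net divergence is the donor-weighted flux
    difference and the whole field telescopes to the export at exit
    cells (kg C/day).  Returns (divergence in kg C m^-2 day^-1,
    export in kg C/day).
    """
    if sediment.detachment_limited is None:
        raise TransportError("sediment flux field lacks branch flags")
    C = _pool_axis(c1, network.shape)
    npool = C.shape[0]
    Cf = C.reshape(npool, -1)
    d_s = network.cell_size
    rcv = network.receiver
    limited = sediment.detachment_limited.ravel()
    d_c = sediment.detachment.ravel()
    q_out = sediment.q_out.ravel()

    soc_in = np.zeros((npool, network.n_cells))
    div = np.zeros((npool, network.n_cells))
    export = 0.0
    for i in network.order:
        r = rcv[i]
        if r < 0:
            # exit cell: carbon leaves with the through-flowing sediment
            export += float(soc_in[:, i].sum()) * d_s
            continue
        if limited[i]:
            d = k_soc * Cf[:, i] * d_c[i]
            out = soc_in[:, i] + d * d_s
        else:
            out = k_soc * Cf[:, i] * q_out[i]
            d = (out - soc_in[:, i]) / d_s
        div[:, i] = d
        soc_in[:, r] += out
    div = div.reshape(C.shape)
    return (div if np.asarray(c1).ndim == 3 else div[0]), export


def update_surface_layer(
    column: SOCColumn,
    soc_divergence: np.ndarray,
    sediment_divergence: float,
    g1: np.ndarray | None = None,
    dt: float = 1.0,
) -> SOCColumn:
    """Advance one column's surface layer under transport (and g1).

    Discretizes  d(C1 z1)/dt = g1 z1 - div(q_C): the surface-layer
    carbon mass changes by (g1 z1 - div q_C) dt while the thickness
    changes by the sediment divergence.  Erosion exceeding the surface
    layer consumes sub-layers top-down; pools are floored at zero with
    the deficit logged.
    """
    if dt <= 0:
        raise TransportError("dt must be positive")
    col = column.copy()
    dz = -float(sediment_divergence) * dt  # >0: deposition
    dmass = -np.asarray(soc_divergence, dtype=float) * dt
    if g1 is not None:
        dmass = dmass + np.asarray(g1, dtype=float) * col.thickness[0] * dt

    # consume sub-layers if erosion removes more than the surface layer
    while dz < 0 and col.thickness[0] + dz < 1e-12 and col.n_layers > 1:
        logger.warning("surface layer exhausted; consuming the layer below")
        dz += col.thickness[0]
        dmass = dmass + col.pools[0] * col.thickness[0]  # its mass is gone too
        col = SOCColumn(col.thickness[1:], col.pools[1:], col.bulk_density)
    z_new = max(col.thickness[0] + dz, 1e-6)
    mass = col.pools[0] * col.thickness[0] + dmass
    deficit = np.minimum(mass, 0.0)
    if np.any(deficit < -1e-15):
        logger.warning("surface pools floored; deficit %s kg C/m^2", -deficit)
    mass = np.maximum(mass, 0.0)
    col.thickness[0] = z_new
    col.pools[0] = mass / z_new
    return col


def apply_transport_to_stack(
    stack: ColumnStack,
    sediment_divergence: np.ndarray,
    soc_divergence: np.ndarray,
    dt: float,
) -> float:
    """Vectorized surface-layer transport update for every cell, in place.

    ``soc_divergence``: (3, nr, nc) per-pool rates.  Returns the total
    carbon clipped by the non-negativity floor (kg C per unit area
    summed over cells), which callers fold into their mass ledgers.
    """
    dz = -np.asarray(sediment_divergence) * dt
    dmass = -np.asarray(soc_divergence) * dt
    z0 = stack.thickness[0]
    z_new = z0 + dz

    # rare: erosion exceeding the surface layer -> consume layers below
    bad = z_new < 1e-9
    if np.any(bad):
        logger.warning("surface layer exhausted at %d cells", int(bad.sum()))
        for r, c in zip(*np.nonzero(bad)):
            need = -(z_new[r, c]) + 0.05
            for k in range(1, stack.n_layers):
                take = min(need, stack.thickness[k, r, c] - 0.01)
                if take <= 0:
                    continue
                stack.thickness[k, r, c] -= take
                dmass[:, r, c] += stack.pools[k, :, r, c] * take
                z_new[r, c] += take
                need -= take
                if need <= 0:
                    break
        z_new = np.maximum(z_new, 1e-9)

    mass = stack.pools[0] * z0[None] + dmass
    clipped = float(np.minimum(mass, 0.0).sum())
    mass = np.maximum(mass, 0.0)
    stack.thickness[0] = z_new
    stack.pools[0] = mass / z_new[None]
    return -clipped


def remesh_surface_layer(stack: ColumnStack, lo: float = 0.05, hi: float = 0.60,
                         pull_to: float = 0.10, push_to: float = 0.50) -> None:
    """Keep the surface-layer thickness inside [lo, hi], in place.

    A too-thin surface layer pulls material (with its concentration)
    up from the layer below; a too-thick one pushes its excess down.
    Both exchanges conserve mass exactly.
    """
    z0 = stack.thickness[0]
    thin = z0 < lo
    for r, c in zip(*np.nonzero(thin)):
        need = pull_to - z0[r, c]
        mass = stack.pools[0, :, r, c] * z0[r, c]
        gained = 0.0
        for k in range(1, stack.n_layers):
            take = min(need, stack.thickness[k, r, c] - 0.01)
            if take <= 0:
                continue
            mass = mass + stack.pools[k, :, r, c] * take
            stack.thickness[k, r, c] -= take
            gained += take
            need -= take
            if need <= 0:
                break
        if gained > 0:
            stack.thickness[0, r, c] = z0[r, c] + gained
            stack.pools[0, :, r, c] = mass / stack.thickness[0, r, c]
    z0 = stack.thickness[0]
    thick = z0 > hi
    for r, c in zip(*np.nonzero(thick)):
        push = z0[r, c] - push_to
        z1 = stack.thickness[1, r, c]
        m1 = stack.pools[1, :, r, c] * z1 + stack.pools[0, :, r, c] * push
        stack.thickness[1, r, c] = z1 + push
        stack.pools[1, :, r, c] = m1 / (z1 + push)
        stack.thickness[0, r, c] = push_to
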