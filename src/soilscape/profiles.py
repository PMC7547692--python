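"""Initial SOC depth profiles, surface interpolation and column stocks.

SOC content in undisturbed loess decreases exponentially with depth,

    SOC(Z) = a * exp(-b * Z) + c        [g C / kg soil]

with Z positive downward from the surface, ``a + c`` the surface
content, ``b`` the decay rate (1/m) and ``c`` the stable (immobile)
content at depth.  ``b`` and ``c`` are taken spatially uniform per
landcover class (fitted once from deep cores); ``a`` varies in space
and is back-calculated from shallow survey samples.  Surface samples
are interpolated over the grid (ordinary kriging with an exponential
variogram, or deterministic inverse-distance weighting) and combined
with the profile shape to build layered three-pool soil columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .grid import GridDomain

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileParams",
    "SOCColumn",
    "SurfaceSOCMap",
    "ColumnStack",
    "profile_value",
    "fit_profile",
    "back_calculate_a",
    "interpolate_surface",
    "build_initial_columns",
    "integrate_stock",
    "DEFAULT_LAYERING",
    "TREES_SHRUBS_PARAMS",
    "CROPS_PARAMS",
]

#: Default vertical layering (m): thicknesses in the allowed 0.05-0.60 m
#: band, summing to the 1-m active soil column, with interfaces at
#: 0.05, 0.10, 0.20 m so a 20-cm tillage plane aligns with a layer edge.
DEFAULT_LAYERING = (0.05, 0.05, 0.10, 0.10, 0.20, 0.20, 0.30)


class ProfileError(ValueError):
    """Invalid profile parameters or data."""


class UnderDeterminedError(ProfileError):
    """Too few distinct depths to constrain the profile fit."""


class FitFailure(RuntimeError):
    """Nonlinear profile fit failed to converge."""


@dataclass(frozen=True)
class ProfileParams:
    """Exponential-with-depth SOC profile parameters (g C/kg, 1/m)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ProfileError(
                f"profile parameters must be positive: a={self.a}, b={self.b}, c={self.c}"
            )


# Fitted deep-core relationships for the two landcover classes
# (surface = a + c; decay b in 1/m; immobile c at depth).
TREES_SHRUBS_PARAMS = ProfileParams(a=8.04, b=9.63, c=2.55)
CROPS_PARAMS = ProfileParams(a=3.71, b=7.06, c=2.27)


def profile_value(params: ProfileParams, depth) -> float | np.ndarray:
    """Evaluate SOC(Z) = a e^{-bZ} + c at depth Z >= 0 (m)."""
    z = np.asarray(depth, dtype=float)
    if np.any(z < 0):
        raise ProfileError("depth must be non-negative")
    out = params.a * np.exp(-params.b * z) + params.c
    return out if out.ndim else float(out)


def fit_profile(samples: pd.DataFrame | np.ndarray) -> ProfileParams:
    """Nonlinear least-squares fit of (depth, concentration) samples.

    ``samples``: two columns, depth (m) and SOC (g C/kg).  Requires at
    least 4 samples at >= 3 distinct depths (3 free parameters).
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ProfileError("samples must be a (n, 2) table of depth, concentration")
    z, y = arr[:, 0], arr[:, 1]
    if len(z) < 4 or len(np.unique(z)) < 3:
        raise UnderDeterminedError(
            "need >= 4 samples at >= 3 distinct depths to fit a, b, c"
        )

    c0 = max(float(y.min()) * 0.9, 1e-6)
    a0 = max(float(y.max()) - c0, 1e-6)
    b0 = 5.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda zz, a, b, c: a * np.exp(-b * zz) + c,
                z, y, p0=(a0, b0, c0),
                bounds=([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
    except RuntimeError as exc:
        resid = float(np.sum((y - (a0 * np.exp(-b0 * z) + c0)) ** 2))
        raise FitFailure(f"profile fit did not converge (residual {resid:.3g})") from exc
    return ProfileParams(*[float(p) for p in popt])


def back_calculate_a(soc_5cm: float, soc_15cm: float, b: float, c: float) -> float:
    """Spatially varying amplitude ``a`` from two shallow-layer values.

    Survey samples give SOC at the midpoints of the 0-10 and 10-20 cm
    layers (Z = 0.05 and 0.15 m).  With b, c fixed per landcover, the
    least-squares solution over the two depths is linear in ``a``:

        a = sum_i e_i (o_i - c) / sum_i e_i^2,   e_i = exp(-b Z_i).
    """
    if soc_5cm <= 0 or soc_15cm <= 0 or b < 0 or c <= 0:
        raise ProfileError("inputs must be positive (b non-negative)")
    obs = np.array([soc_5cm, soc_15cm])
    if np.all(obs <= c):
        raise ProfileError(
            "both observations at or below the immobile content c: no signal for a"
        )
    e = np.exp(-b * np.array([0.05, 0.15]))
    a = float(e @ (obs - c) / (e @ e))
    if a <= 0:
        raise ProfileError(f"back-calculated a is non-positive ({a:.3g})")
    return a


# ---------------------------------------------------------------------------
# Surface interpolation
# ---------------------------------------------------------------------------

@dataclass
class SurfaceSOCMap:
    """Per-cell surface SOC concentration (g C/kg) on a grid domain."""

    domain: GridDomain
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.domain.shape:
            raise ProfileError("surface map shape mismatch")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ProfileError("surface SOC must be finite and positive")


def _cell_centers(domain: GridDomain) -> tuple[np.ndarray, np.ndarray]:
    """x (east) and y (north) coordinates of cell centers; origin at the
    lower-left corner of the grid."""
    cs = domain.cell_size
    x = (np.arange(domain.n_cols) + 0.5) * cs
    y = ((domain.n_rows - 1 - np.arange(domain.n_rows)) + 0.5) * cs
    return np.meshgrid(x, y)


def _idw(px, py, pv, gx, gy, power: float = 2.0) -> np.ndarray:
    d2 = (gx[..., None] - px) ** 2 + (gy[..., None] - py) ** 2
    out = np.empty(gx.shape)
    exact = d2.min(axis=-1) < 1e-20
    w = 1.0 / np.maximum(d2, 1e-20) ** (power / 2.0)
    out = (w * pv).sum(axis=-1) / w.sum(axis=-1)
    if np.any(exact):
        nearest = d2.argmin(axis=-1)
        out[exact] = pv[nearest[exact]]
    return out


def _fit_exponential_variogram(px, py, pv):
    """Weighted-least-squares exponential variogram from empirical bins."""
    n = len(pv)
    dx = px[:, None] - px[None, :]
    dy = py[:, None] - py[None, :]
    h = np.sqrt(dx**2 + dy**2)[np.triu_indices(n, 1)]
    g = 0.5 * (pv[:, None] - pv[None, :])[np.triu_indices(n, 1)] ** 2
    if h.max() <= 0:
        raise ProfileError("all sample points coincide")
    bins = np.linspace(0, h.max() * 0.7, 11)
    hb, gb, wb = [], [], []
    for lo, hi in zip(bins[:-1], bins[1:]):
        m = (h > lo) & (h <= hi)
        if m.sum() >= 2:
            hb.append(h[m].mean())
            gb.append(g[m].mean())
            wb.append(m.sum())
    hb, gb, wb = map(np.asarray, (hb, gb, wb))
    if len(hb) < 3 or gb.max() <= 0:
        # flat or data-poor structure: small nugget-free default
        return 1e-10, max(float(np.var(pv)), 1e-10), h.max() / 3.0

    def model(hh, nugget, sill, rng_):
        return nugget + sill * (1.0 - np.exp(-hh / rng_))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, hb, gb, p0=(0.0, float(gb.max()), float(hb.max() / 3)),
                sigma=1.0 / np.sqrt(wb), bounds=(0, np.inf), maxfev=10000,
            )
        nugget, sill, rng_ = map(float, popt)
        if sill <= 0 or rng_ <= 0:
            raise RuntimeError
        return nugget, sill, rng_
    except RuntimeError:
        return 1e-10, max(float(np.var(pv)), 1e-10), float(h.max() / 3)


def interpolate_surface(
    points: pd.DataFrame | np.ndarray,
    domain: GridDomain,
    method: str = "ordinary_kriging",
) -> SurfaceSOCMap:
    """Interpolate survey points (x, y, concentration) onto the grid.

    Ordinary kriging with an exponential variogram fitted by weighted
    least squares; falls back to inverse-distance weighting (power 2)
    on a singular kriging system, with a logged warning.  Exact at the
    sample locations.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 3 or len(arr) == 0:
        raise ProfileError("need a non-empty (n, 3) table of x, y, concentration")
    px, py, pv = arr[:, 0], arr[:, 1], arr[:, 2]
    gx, gy = _cell_centers(domain)

    if len(arr) == 1:
        return SurfaceSOCMap(domain, np.full(domain.shape, float(pv[0])))
    if method == "idw":
        return SurfaceSOCMap(domain, _idw(px, py, pv, gx, gy))
    if method != "ordinary_kriging":
        raise ProfileError(f"unknown interpolation method {method!r}")

    nugget, sill, vrange = _fit_exponential_variogram(px, py, pv)

    def gamma(h):
        return nugget + sill * (1.0 - np.exp(-h / vrange))

    n = len(pv)
    hpp = np.sqrt((px[:, None] - px[None, :]) ** 2 + (py[:, None] - py[None, :]) ** 2)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma(hpp)
    np.fill_diagonal(A[:n, :n], 0.0)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        logger.warning("singular kriging system; falling back to IDW")
        return SurfaceSOCMap(domain, _idw(px, py, pv, gx, gy))

    hg = np.sqrt((gx[..., None] - px) ** 2 + (gy[..., None] - py) ** 2)
    B = np.concatenate([gamma(hg), np.ones(gx.shape + (1,))], axis=-1)
    weights = B @ Ainv.T
    vals = weights[..., :n] @ pv
    # exact at sample locations
    exact = hg.min(axis=-1) < 1e-20
    if np.any(exact):
        vals[exact] = pv[hg.argmin(axis=-1)[exact]]
    if np.any(~np.isfinite(vals)):
        logger.warning("non-finite kriging output; falling back to IDW")
        return SurfaceSOCMap(domain, _idw(px, py, pv, gx, gy))
    vals = np.maximum(vals, 1e-9)
    return SurfaceSOCMap(domain, vals)


# ---------------------------------------------------------------------------
# Columns
# ---------------------------------------------------------------------------

POOL_NAMES = ("litter", "humus", "biomass")


@dataclass
class SOCColumn:
    """Layered vertical soil column with three carbon pools.

    ``thickness``: per-layer thickness (m), each within [0.05, 0.60];
    ``pools``: (n_layers, 3) concentrations (kg C/m^3) ordered as
    (litter/fast, humus/slow, microbial biomass).
    """

    thickness: np.ndarray
    pools: np.ndarray
    bulk_density: float = 1300.0

    def __post_init__(self) -> None:
        self.thickness = np.atleast_1d(np.asarray(self.thickness, dtype=float))
        self.pools = np.asarray(self.pools, dtype=float)
        if self.pools.shape != (len(self.thickness), 3):
            raise ProfileError("pools must have shape (n_layers, 3)")
        if np.any(self.thickness <= 0):
            raise ProfileError("layer thicknesses must be positive")
        if np.any(self.pools < -1e-12):
            raise ProfileError("pool concentrations must be non-negative")

    @property
    def n_layers(self) -> int:
        return len(self.thickness)

    @property
    def total_thickness(self) -> float:
        return float(self.thickness.sum())

    @property
    def layer_bottoms(self) -> np.ndarray:
        return np.cumsum(self.thickness)

    @property
    def layer_midpoints(self) -> np.ndarray:
        b = self.layer_bottoms
        return b - self.thickness / 2.0

    def copy(self) -> "SOCColumn":
        return SOCColumn(self.thickness.copy(), self.pools.copy(), self.bulk_density)


@dataclass
class ColumnStack:
    """Vectorized per-cell columns on a grid.

    ``thickness``: (n_layers, n_rows, n_cols) m;
    ``pools``: (n_layers, 3, n_rows, n_cols) kg C/m^3.
    """

    thickness: np.ndarray
    pools: np.ndarray
    bulk_density: float = 1300.0

    @property
    def n_layers(self) -> int:
        return self.thickness.shape[0]

    def column(self, r: int, c: int) -> SOCColumn:
        return SOCColumn(self.thickness[:, r, c].copy(),
                         self.pools[:, :, r, c].copy(), self.bulk_density)

    def total_concentration(self) -> np.ndarray:
        """(n_layers, n_rows, n_cols) total SOC concentration."""
        return self.pools.sum(axis=1)

    def stock(self) -> np.ndarray:
        """Per-cell areal SOC stock (kg C/m^2)."""
        return (self.thickness * self.pools.sum(axis=1)).sum(axis=0)

    def copy(self) -> "ColumnStack":
        return ColumnStack(self.thickness.copy(), self.pools.copy(), self.bulk_density)


def build_initial_columns(
    surface: SurfaceSOCMap,
    b: float,
    c: float,
    layering=DEFAULT_LAYERING,
    bulk_density: float = 1300.0,
    pool_fractions=(0.10, 0.85, 0.05),
) -> ColumnStack:
    """Build per-cell initial columns from the surface SOC map.

    Per-layer total concentration is the exponential profile evaluated
    at the layer midpoint, converted from g C/kg to kg C/m^3 with the
    bulk density; pools are a fixed partition of the total (default
    humus-dominated, typical of cultivated loess).
    """
    fr = np.asarray(pool_fractions, dtype=float)
    if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ProfileError("pool fractions must be non-negative and sum to 1")
    th = np.asarray(layering, dtype=float)
    if np.any(th < 0.05 - 1e-12) or np.any(th > 0.60 + 1e-12):
        raise ProfileError("layer thicknesses must lie within [0.05, 0.60] m")
    mids = np.cumsum(th) - th / 2.0
    # a varies per cell: a = surface - c
    a = surface.values - c
    if np.any(a <= 0):
        raise ProfileError("surface SOC must exceed the immobile content c")
    conc_gkg = a[None, :, :] * np.exp(-b * mids)[:, None, None] + c
    conc = conc_gkg * bulk_density / 1000.0  # g/kg -> kg C/m^3
    nl = len(th)
    nr, nc = surface.domain.shape
    thickness = np.broadcast_to(th[:, None, None], (nl, nr, nc)).copy()
    pools = conc[:, None, :, :] * fr[None, :, None, None]
    return ColumnStack(thickness, pools.copy(), bulk_density)


def integrate_stock(column: SOCColumn) -> float:
    """Areal SOC stock (kg C/m^2): sum of thickness x total concentration."""
    return float((column.thickness * column.pools.sum(axis=1)).sum())
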