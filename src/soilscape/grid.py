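"""Gridded spatial domain shared by every model component.

The model operates on a uniform rectangular grid of square cells
(default 2 m, matching the resolution of drone-LiDAR terrain surveys
on the Loess Plateau).  Arrays are stored row-major with row 0 at the
northern edge, the same orientation as an ESRI ASCII grid file; the
single watershed outlet sits on the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DomainError(ValueError):
    """Invalid grid-domain geometry."""


@dataclass(frozen=True)
class GridDomain:
    """Uniform 2-D grid geometry.

    Parameters
    ----------
    n_rows, n_cols:
        Grid dimensions; at least 4 each.
    cell_size:
        Cell edge length in metres (default 2 m).  Also used as the
        flow-path length across a cell in flux-divergence terms.
    outlet:
        (row, col) of the watershed outlet; must lie on the boundary.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 2.0
    outlet: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 4 or self.n_cols < 4:
            raise DomainError(
                f"grid must be at least 4x4, got {self.n_rows}x{self.n_cols}"
            )
        if not self.cell_size > 0:
            raise DomainError(f"cell_size must be positive, got {self.cell_size}")
        if self.outlet is not None:
            r, c = self.outlet
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise DomainError(f"outlet {self.outlet} outside the grid")
            if not (r in (0, self.n_rows - 1) or c in (0, self.n_cols - 1)):
                raise DomainError(f"outlet {self.outlet} must lie on the boundary")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area(self) -> float:
        return self.cell_size**2


@dataclass
class ElevationGrid:
    """Surface elevation and mobile-soil thickness on a :class:`GridDomain`.

    ``soil_thickness`` starts uniform (1 m by default: the biologically
    active depth of loess profiles) and changes only through surface
    erosion and deposition — bedrock weathering is neglected.
    """

    domain: GridDomain
    elevation: np.ndarray
    soil_thickness: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.shape != self.domain.shape:
            raise DomainError(
                f"elevation shape {self.elevation.shape} != domain {self.domain.shape}"
            )
        if not np.all(np.isfinite(self.elevation)):
            raise DomainError("elevation contains non-finite values")
        if self.soil_thickness is None:
            self.soil_thickness = np.full(self.domain.shape, 1.0)
        else:
            self.soil_thickness = np.asarray(self.soil_thickness, dtype=float)
            if self.soil_thickness.shape != self.domain.shape:
                raise DomainError("soil_thickness shape mismatch")
            if np.any(self.soil_thickness < 0):
                raise DomainError("soil_thickness must be non-negative")

    def copy(self) -> "ElevationGrid":
        return ElevationGrid(
            self.domain, self.elevation.copy(), self.soil_thickness.copy()
        )
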