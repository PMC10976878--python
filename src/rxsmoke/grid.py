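"""Model domain grid.

A regular grid of square cells on a projected plane, indexed (row, col).
Coordinates are in km; the default 12 km cell size matches a typical
regional air-quality modelling resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class DomainGrid:
    """Regular square-cell model domain.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions (>= 1 each).
    cell_size : float
        Cell edge length in km (> 0). Default 12 km.
    origin : tuple of float
        Projected (x, y) of the lower-left corner of cell (0, 0), in km.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 12.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate arrays, each (n_rows, n_cols), km.

        Row index increases with y; column index increases with x.
        """
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(xs, ys)
        return xx, yy

    def contains(self, x: float, y: float) -> bool:
        x0, y0 = self.origin
        return (
            x0 <= x <= x0 + self.n_cols * self.cell_size
            and y0 <= y <= y0 + self.n_rows * self.cell_size
        )
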