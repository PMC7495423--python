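"""Metric site grid shared by all pipeline stages.

Cells live on a regular ``n_y x n_x`` lattice with square cells of
``cell_size`` km.  Cell ids are 0-based and row-major with the origin at
the *south-west* corner: ``cell_id = iy * n_x + ix`` where ``iy`` counts
rows northward and ``ix`` columns eastward.  Centroid coordinates are in
km, so cell (0, 0) sits at ``(cell_size/2, cell_size/2)``.

Every raster exchanged between modules is a ``(n_y, n_x)`` array whose
row 0 is the southernmost row; off-mask cells are NaN (floats) or False
(booleans).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SiteGrid"]


@dataclass(frozen=True)
class SiteGrid:
    """A rectangular metric lattice of analysis cells.

    Parameters
    ----------
    n_x, n_y
        Number of columns (west-east) and rows (south-north).
    cell_size
        Edge length of a cell in km.
    mask
        Boolean ``(n_y, n_x)`` array; True marks land / analyzed cells.
    """

    n_x: int
    n_y: int
    cell_size: float
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid must have at least one cell per axis")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != (self.n_y, self.n_x):
            raise ValueError(
                f"mask shape {mask.shape} != (n_y, n_x)=({self.n_y}, {self.n_x})"
            )
        object.__setattr__(self, "mask", mask)

    # ------------------------------------------------------------------
    # indexing helpers
    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def cell_id(self, ix: int, iy: int) -> int:
        return iy * self.n_x + ix

    def cell_xy(self, cell_id: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        """(ix, iy) column/row indices for flat cell ids."""
        cell_id = np.asarray(cell_id)
        return cell_id % self.n_x, cell_id // self.n_x

    @property
    def coords(self) -> np.ndarray:
        """``(n_cells, 2)`` centroid (x, y) in km, row-major from the SW corner."""
        ix, iy = np.meshgrid(np.arange(self.n_x), np.arange(self.n_y))
        x = (ix.ravel() + 0.5) * self.cell_size
        y = (iy.ravel() + 0.5) * self.cell_size
        return np.column_stack([x, y])

    @property
    def masked_ids(self) -> np.ndarray:
        """Flat ids of masked (land) cells, ascending."""
        return np.flatnonzero(self.mask.ravel())

    # ------------------------------------------------------------------
    # raster <-> flat conversions
    # ------------------------------------------------------------------
    def to_raster(self, flat: np.ndarray) -> np.ndarray:
        """Reshape a length ``n_cells`` vector to ``(n_y, n_x)``."""
        flat = np.asarray(flat)
        return flat.reshape(self.n_y, self.n_x)

    def raster_from_masked(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter per-masked-cell values into a full raster (off-mask = fill)."""
        out = np.full(self.n_cells, fill, dtype=float)
        out[self.masked_ids] = values
        return out.reshape(self.n_y, self.n_x)

    def with_mask(self, mask: np.ndarray) -> "SiteGrid":
        return SiteGrid(self.n_x, self.n_y, self.cell_size, np.asarray(mask, bool))

    def __eq__(self, other: object) -> bool:  # dataclass eq chokes on arrays
        if not isinstance(other, SiteGrid):
            return NotImplemented
        return (
            self.n_x == other.n_x
            and self.n_y == other.n_y
            and self.cell_size == other.cell_size
            and bool(np.array_equal(self.mask, other.mask))
        )
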