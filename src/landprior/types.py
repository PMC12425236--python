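"""Shared domain types: the grid lattice and the layers that live on it.

All layers in a run share one :class:`Grid` — a 2-D row-major lattice with a
boolean validity mask (``True`` = analysable cell) and a per-cell area in km².
Grid indexing is 0-based, origin top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional

import numpy as np

__all__ = [
    "Grid",
    "LandClass",
    "LandCoverGrid",
    "SpeciesLayer",
    "CostLayer",
    "PAMask",
    "OccurrenceSet",
    "VirtualSpeciesSpec",
    "EvalResult",
    "IUCN_WEIGHTS",
]

#: IUCN Red List category → prioritization weight.
IUCN_WEIGHTS: Mapping[str, int] = {"LC": 1, "NT": 2, "VU": 3, "EN": 4, "CR": 5}


@dataclass(frozen=True)
class Grid:
    """The shared 2-D lattice on which every layer lives.

    Parameters
    ----------
    n_rows, n_cols:
        Lattice dimensions; both must be positive.
    cell_area:
        Area of a single cell in km² (default 1.0, the 1-by-1-km convention).
    valid_mask:
        Boolean lattice, ``True`` where a cell is analysable. ``None`` means
        all cells are valid.
    """

    n_rows: int
    n_cols: int
    cell_area: float = 1.0
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        mask = self.valid_mask
        if mask is None:
            mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (self.n_rows, self.n_cols):
                raise ValueError(
                    f"valid_mask shape {mask.shape} does not match grid "
                    f"({self.n_rows}, {self.n_cols})"
                )
        if not mask.any():
            raise ValueError("valid_mask must contain at least one valid cell")
        mask.setflags(write=False)
        object.__setattr__(self, "valid_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def check_same(self, other: "Grid") -> None:
        """Raise if *other* is not aligned with this grid."""
        if (
            self.shape != other.shape
            or self.cell_area != other.cell_area
            or not np.array_equal(self.valid_mask, other.valid_mask)
        ):
            raise ValueError("grids are not aligned")

    def contains_cells(self, cells: np.ndarray) -> bool:
        cells = np.asarray(cells)
        if cells.size == 0:
            return True
        return bool(
            (cells[:, 0] >= 0).all()
            and (cells[:, 0] < self.n_rows).all()
            and (cells[:, 1] >= 0).all()
            and (cells[:, 1] < self.n_cols).all()
        )


class LandClass(NamedTuple):
    label: str
    is_natural: bool


@dataclass(frozen=True)
class LandCoverGrid:
    """Categorical land cover: integer codes plus a code → class table."""

    grid: Grid
    codes: np.ndarray
    class_map: Mapping[int, LandClass]

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.shape != self.grid.shape:
            raise ValueError("codes shape does not match grid")
        present = np.unique(codes[self.grid.valid_mask])
        missing = [int(c) for c in present if int(c) not in self.class_map]
        if missing:
            raise ValueError(f"codes {missing} missing from class_map")
        object.__setattr__(self, "codes", codes)

    def natural_mask(self) -> np.ndarray:
        """Boolean lattice, True where the land-cover class is natural."""
        out = np.zeros(self.grid.shape, dtype=bool)
        for code, cls in self.class_map.items():
            if cls.is_natural:
                out |= self.codes == code
        return out & self.grid.valid_mask


@dataclass
class SpeciesLayer:
    """One species on the grid: continuous suitability in [0,1] or a binary range.

    ``values`` with a boolean dtype is binary mode; anything else is
    continuous and must lie within [0, 1] on valid cells.
    """

    species_id: str
    grid: Grid
    values: np.ndarray
    iucn_category: Optional[str] = None
    weight: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if values.dtype != bool:
            vals = values[self.grid.valid_mask]
            if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
                raise ValueError("continuous suitability must lie in [0, 1]")
        self.values = values
        if self.iucn_category is not None:
            if self.iucn_category not in IUCN_WEIGHTS:
                raise ValueError(f"unknown IUCN category {self.iucn_category!r}")
            expected = IUCN_WEIGHTS[self.iucn_category]
            if self.weight is None:
                self.weight = expected
            elif self.weight != expected:
                raise ValueError(
                    f"weight {self.weight} inconsistent with category "
                    f"{self.iucn_category} (expected {expected})"
                )

    @property
    def is_binary(self) -> bool:
        return self.values.dtype == bool

    @property
    def range_size_km2(self) -> float:
        if not self.is_binary:
            raise ValueError("range size is defined for binary layers only")
        return float(
            np.count_nonzero(self.values & self.grid.valid_mask) * self.grid.cell_area
        )


@dataclass(frozen=True)
class CostLayer:
    """Per-cell acquisition cost; strictly positive on valid cells."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError("cost shape does not match grid")
        if (values[self.grid.valid_mask] <= 0).any():
            raise ValueError("cost must be positive on valid cells")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class PAMask:
    """Boolean mask of cells forced into the top of the priority ranking."""

    grid: Grid
    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if (mask & ~self.grid.valid_mask).any():
            raise ValueError("PA mask extends outside the valid grid")
        object.__setattr__(self, "mask", mask)

    @property
    def land_fraction(self) -> float:
        return float(self.mask.sum()) / self.grid.n_valid


@dataclass
class OccurrenceSet:
    """Presence records as (row, col) cell coordinates, optionally folded."""

    species_id: str
    cells: np.ndarray
    folds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        cells = np.atleast_2d(np.asarray(self.cells, dtype=int))
        if cells.size and cells.shape[1] != 2:
            raise ValueError("cells must be an (n, 2) array of row, col")
        self.cells = cells
        if self.folds is not None:
            folds = np.asarray(self.folds, dtype=int)
            if folds.shape[0] != cells.shape[0]:
                raise ValueError("folds length does not match cells")
            self.folds = folds

    def __len__(self) -> int:
        return self.cells.shape[0]


@dataclass(frozen=True)
class VirtualSpeciesSpec:
    """Recipe for one simulated species."""

    species_id: str
    center: tuple[int, int]
    spread: float
    max_suitability: float = 1.0
    iucn_category: str = "LC"
    n_presences: int = 30

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if not 0 < self.max_suitability <= 1:
            raise ValueError("max_suitability must be in (0, 1]")
        if self.iucn_category not in IUCN_WEIGHTS:
            raise ValueError(f"unknown IUCN category {self.iucn_category!r}")
        if self.n_presences < 1:
            raise ValueError("n_presences must be at least 1")


@dataclass(frozen=True)
class EvalResult:
    """Discrimination metrics for one species' suitability surface."""

    auc: float
    tss: float
    threshold: float

    def __post_init__(self) -> None:
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must be in [0, 1]")
        if not -1 <= self.tss <= 1:
            raise ValueError("TSS must be in [-1, 1]")
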