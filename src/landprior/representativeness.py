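"""Range coverage by a protection mask and the well-represented criterion.

A species counts as well-represented when the percentage of its binary range
inside the mask reaches a range-size-dependent requirement: 100% for ranges
under 1,000 km², 10% for ranges over 25,000 km², linearly interpolated in
between (in raw km² by default; log-area available for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .range_mapping import RESTRICTED_MAX_KM2, WIDE_MIN_KM2, breadth_class
from .types import SpeciesLayer

__all__ = [
    "GapReport",
    "coverage_pct",
    "required_pct",
    "gap_report",
    "gap_report_from_rows",
]


@dataclass(frozen=True)
class GapReport:
    """Per-species coverage table plus summary statistics.

    ``rows`` columns: species_id, range_km2, breadth, coverage_pct,
    required_pct, well_represented.
    """

    rows: pd.DataFrame
    mean_coverage_pct: float
    n_well: int
    n_poor: int
    n_species: int

    def __post_init__(self) -> None:
        if self.n_well + self.n_poor != self.n_species:
            raise ValueError("n_well + n_poor must equal n_species")

    @property
    def summary(self) -> dict:
        return {
            "mean_coverage_pct": self.mean_coverage_pct,
            "n_well": self.n_well,
            "n_poor": self.n_poor,
            "n_species": self.n_species,
        }


def coverage_pct(range_layer: SpeciesLayer, mask: np.ndarray) -> float:
    """Percentage of the binary range inside *mask*: 100·|range ∩ mask|/|range|."""
    if not range_layer.is_binary:
        raise ValueError("coverage requires a binary range layer")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != range_layer.grid.shape:
        raise ValueError("mask shape does not match grid")
    rng = range_layer.values & range_layer.grid.valid_mask
    n_range = int(rng.sum())
    if n_range == 0:
        raise ValueError(
            f"species {range_layer.species_id!r} has an empty range; "
            "coverage is undefined"
        )
    return 100.0 * int((rng & mask).sum()) / n_range


def required_pct(area_km2: float, mode: str = "area") -> float:
    """Coverage requirement (%) as a function of range size.

    <1,000 km² → 100; >25,000 km² → 10; linear interpolation between,
    continuous at both breakpoints. ``mode="log-area"`` interpolates in
    log(km²) instead (sensitivity switch).
    """
    if area_km2 < 0:
        raise ValueError("area must be non-negative")
    if mode not in ("area", "log-area"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    if area_km2 < RESTRICTED_MAX_KM2:
        return 100.0
    if area_km2 > WIDE_MIN_KM2:
        return 10.0
    if mode == "area":
        frac = (area_km2 - RESTRICTED_MAX_KM2) / (WIDE_MIN_KM2 - RESTRICTED_MAX_KM2)
    else:
        frac = (np.log(area_km2) - np.log(RESTRICTED_MAX_KM2)) / (
            np.log(WIDE_MIN_KM2) - np.log(RESTRICTED_MAX_KM2)
        )
    return float(100.0 - 90.0 * frac)


def gap_report(
    ranges: Sequence[SpeciesLayer], mask: np.ndarray, mode: str = "area"
) -> GapReport:
    """Coverage, requirement and well-represented flag for every species."""
    if not ranges:
        raise ValueError("at least one species is required")
    records = []
    for layer in ranges:
        area = layer.range_size_km2
        cov = coverage_pct(layer, mask)
        req = required_pct(area, mode=mode)
        records.append(
            {
                "species_id": layer.species_id,
                "range_km2": area,
                "breadth": breadth_class(area),
                "coverage_pct": cov,
                "required_pct": req,
                "well_represented": cov >= req,
            }
        )
    return gap_report_from_rows(pd.DataFrame.from_records(records))


def gap_report_from_rows(rows: pd.DataFrame) -> GapReport:
    """Assemble a :class:`GapReport` (summary recomputed) from a row table."""
    required = {
        "species_id",
        "range_km2",
        "breadth",
        "coverage_pct",
        "required_pct",
        "well_represented",
    }
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"gap-report rows missing columns {sorted(missing)}")
    n_well = int(rows["well_represented"].sum())
    return GapReport(
        rows=rows.reset_index(drop=True),
        mean_coverage_pct=float(rows["coverage_pct"].mean()),
        n_well=n_well,
        n_poor=len(rows) - n_well,
        n_species=len(rows),
    )
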