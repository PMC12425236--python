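"""Protection scenarios cut from a rank map, and expansion summaries.

The top fraction f of the rank map defines the f-coverage scenario; because
protected cells always carry the highest ranks, every scenario nests the
current protected-area network, and scenarios for growing targets nest each
other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prioritizer import RankMap
from .representativeness import GapReport
from .types import PAMask

__all__ = ["Scenario", "select_top_fraction", "expansion_summary"]


@dataclass(frozen=True)
class Scenario:
    name: str
    mask: np.ndarray
    land_fraction: float
    added_fraction: float


def select_top_fraction(rank: RankMap, fraction: float, pa: PAMask) -> Scenario:
    """Select the ``round(fraction · N)`` highest-ranked cells.

    Rounds half away from zero. The protected mask is contained by
    construction (protected cells hold the top ranks); a target below the
    current protected fraction is an error.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rank.grid.check_same(pa.grid)
    n_valid = rank.grid.n_valid
    n_pa = int(pa.mask.sum())
    n_sel = int(math.floor(fraction * n_valid + 0.5))
    if n_sel < n_pa:
        raise ValueError(
            f"target fraction {fraction} selects {n_sel} cells but the current "
            f"protected network already holds {n_pa}"
        )
    ranks = np.where(np.isnan(rank.rank), -np.inf, rank.rank)
    mask = np.zeros(rank.grid.shape, dtype=bool)
    if n_sel > 0:
        flat = np.argsort(ranks, axis=None, kind="stable")[::-1][:n_sel]
        mask.ravel()[flat] = True
    if (pa.mask & ~mask).any():
        raise RuntimeError("rank map does not place protected cells on top")
    return Scenario(
        name=f"top_{fraction:g}",
        mask=mask,
        land_fraction=n_sel / n_valid,
        added_fraction=(n_sel - n_pa) / n_valid,
    )


def _row(metric: str, a: float, b: float) -> dict:
    rel = 100.0 * (b - a) / a if a != 0 else float("nan")
    fold = b / a if a != 0 else float("nan")
    return {
        "metric": metric,
        "baseline": a,
        "target": b,
        "relative_increase_pct": rel,
        "fold": fold,
    }


def expansion_summary(
    report_a: GapReport,
    report_b: GapReport,
    frac_a: float,
    frac_b: float,
) -> pd.DataFrame:
    """Change table between a baseline and a target protection level.

    One row per metric (land_fraction, mean_coverage_pct, n_well) with the
    percent relative increase 100·(b−a)/a and the fold ratio b/a. A zero
    baseline yields NaN markers rather than an exception.
    """
    if report_a.n_species != report_b.n_species or not report_a.rows[
        "species_id"
    ].equals(report_b.rows["species_id"]):
        raise ValueError("expansion summary requires the same species set")
    rows = [
        _row("land_fraction", frac_a, frac_b),
        _row("mean_coverage_pct", report_a.mean_coverage_pct, report_b.mean_coverage_pct),
        _row("n_well", report_a.n_well, report_b.n_well),
    ]
    return pd.DataFrame(rows)
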