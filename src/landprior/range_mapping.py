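"""Binary range maps and model-quality metrics from continuous suitability.

Implements the percentile-of-training-presences binarization rule, greedy
collinearity pruning, spatial block cross-validation fold assignment, and the
presence/background discrimination metrics (rank AUC, TSS).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import EvalResult, Grid, OccurrenceSet, SpeciesLayer

__all__ = [
    "collinearity_filter",
    "threshold_10pct",
    "range_size",
    "breadth_class",
    "block_folds",
    "auc_presence_background",
    "tss",
    "evaluate_layer",
]

#: Range-size breakpoints (km²) separating restricted / intermediate / wide.
RESTRICTED_MAX_KM2 = 1_000.0
WIDE_MIN_KM2 = 25_000.0

#: Percentile convention used throughout (recorded in run manifests).
PERCENTILE_METHOD = "linear"


def collinearity_filter(
    correlations: np.ndarray,
    names: Sequence[str],
    priority: Sequence[str],
    threshold: float = 0.7,
) -> list[str]:
    """Greedy collinearity pruning on a Spearman correlation matrix.

    Variables are visited in ``priority`` order; one is retained iff its
    absolute correlation with every already-retained variable is strictly
    below ``threshold``. Returns retained names in priority order.
    """
    corr = np.asarray(correlations, dtype=float)
    names = list(names)
    if corr.shape != (len(names), len(names)):
        raise ValueError("correlation matrix shape does not match names")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-9):
        raise ValueError("correlation matrix must have unit diagonal")
    if sorted(priority) != sorted(names):
        raise ValueError("priority must be a permutation of names")

    index = {n: i for i, n in enumerate(names)}
    kept: list[str] = []
    for name in priority:
        i = index[name]
        if all(abs(corr[i, index[k]]) < threshold for k in kept):
            kept.append(name)
    return kept


def threshold_10pct(
    layer: SpeciesLayer, training: OccurrenceSet, percentile: float = 10.0
) -> tuple[float, SpeciesLayer]:
    """Binarize suitability at the given percentile of training presences.

    The threshold is the linear-interpolation percentile of the suitability
    values at the training cells, capped at the order statistic that keeps the
    number of strictly-omitted presences within ``percentile``% (the
    interpolated value can otherwise overshoot for some sample sizes). The
    binary range keeps cells with suitability ≥ threshold.
    """
    if layer.is_binary:
        raise ValueError("layer is already binary")
    if len(training) == 0:
        raise ValueError("training set is empty")
    cells = training.cells
    if not layer.grid.contains_cells(cells):
        raise ValueError("training cells fall outside the grid")
    train_vals = layer.values[cells[:, 0], cells[:, 1]]
    thr = float(np.percentile(train_vals, percentile, method=PERCENTILE_METHOD))
    max_below = percentile / 100.0 * len(train_vals)
    if (train_vals < thr).sum() > max_below:
        thr = float(np.sort(train_vals)[int(np.floor(max_below))])
    binary = (layer.values >= thr) & layer.grid.valid_mask
    out = SpeciesLayer(
        species_id=layer.species_id,
        grid=layer.grid,
        values=binary,
        iucn_category=layer.iucn_category,
        weight=layer.weight,
        meta={
            **layer.meta,
            "threshold": thr,
            "percentile": percentile,
            "percentile_method": PERCENTILE_METHOD,
        },
    )
    return thr, out


def range_size(binary: SpeciesLayer, grid: Optional[Grid] = None) -> float:
    """Range size in km²: count of true valid cells × cell area."""
    if not binary.is_binary:
        raise ValueError("range_size requires a binary layer")
    if grid is not None:
        binary.grid.check_same(grid)
    return binary.range_size_km2


def breadth_class(area_km2: float) -> str:
    """Classify a range size as restricted (<1,000 km²), wide (>25,000 km²),
    or intermediate (boundaries inclusive to intermediate)."""
    if area_km2 < 0:
        raise ValueError("area must be non-negative")
    if area_km2 < RESTRICTED_MAX_KM2:
        return "restricted"
    if area_km2 > WIDE_MIN_KM2:
        return "wide"
    return "intermediate"


def block_folds(
    occ: OccurrenceSet,
    grid: Grid,
    block_size: int,
    k: int = 5,
    seed: int = 0,
) -> OccurrenceSet:
    """Assign spatial-block cross-validation folds to occurrence records.

    The grid is tiled into ``block_size``-cell square blocks; blocks are dealt
    to the ``k`` folds round-robin after a seeded shuffle (balanced by block
    count), and every record inherits its block's fold.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if block_size < 1:
        raise ValueError("block_size must be at least 1")
    if not grid.contains_cells(occ.cells):
        raise ValueError("occurrence cells fall outside the grid")

    n_brow = -(-grid.n_rows // block_size)
    n_bcol = -(-grid.n_cols // block_size)
    block_of = (occ.cells[:, 0] // block_size) * n_bcol + occ.cells[:, 1] // block_size
    if len(np.unique(block_of)) < k:
        raise ValueError(
            f"only {len(np.unique(block_of))} non-empty blocks for k={k} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_brow * n_bcol)
    fold_of_block = np.empty(n_brow * n_bcol, dtype=int)
    fold_of_block[order] = np.arange(n_brow * n_bcol) % k + 1
    return OccurrenceSet(
        species_id=occ.species_id, cells=occ.cells, folds=fold_of_block[block_of]
    )


def auc_presence_background(
    scores_presence: Sequence[float], scores_background: Sequence[float]
) -> float:
    """Rank-based AUC: P(presence score > background score) + ½·P(tie)."""
    pres = np.asarray(scores_presence, dtype=float)
    back = np.asarray(scores_background, dtype=float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("presence and background score lists must be non-empty")
    ranks = stats.rankdata(np.concatenate([pres, back]))
    r_pres = ranks[: pres.size].sum()
    return float((r_pres - pres.size * (pres.size + 1) / 2) / (pres.size * back.size))


def tss(
    binary_pred_at_presences: Sequence[bool],
    binary_pred_at_background: Sequence[bool],
) -> float:
    """True Skill Statistic: sensitivity + specificity − 1."""
    pres = np.asarray(binary_pred_at_presences, dtype=bool)
    back = np.asarray(binary_pred_at_background, dtype=bool)
    if pres.size == 0 or back.size == 0:
        raise ValueError("prediction lists must be non-empty")
    sensitivity = pres.mean()
    specificity = (~back).mean()
    return float(sensitivity + specificity - 1.0)


def evaluate_layer(
    layer: SpeciesLayer,
    presences: OccurrenceSet,
    background: Optional[np.ndarray] = None,
    percentile: float = 10.0,
) -> EvalResult:
    """AUC and TSS of a continuous layer against presences and a background.

    ``background`` is an (n, 2) array of background cells; by default all
    valid cells are used. TSS uses the same percentile-of-presences threshold
    as binarization.
    """
    if background is None:
        background = np.argwhere(layer.grid.valid_mask)
    scores_p = layer.values[presences.cells[:, 0], presences.cells[:, 1]]
    scores_b = layer.values[background[:, 0], background[:, 1]]
    auc = auc_presence_background(scores_p, scores_b)
    thr = float(np.percentile(scores_p, percentile, method=PERCENTILE_METHOD))
    t = tss(scores_p >= thr, scores_b >= thr)
    return EvalResult(auc=auc, tss=t, threshold=thr)
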