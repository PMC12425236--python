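"""Greedy additive-benefit cell-removal ranking.

Every cell in the landscape is ranked by iteratively removing the cells whose
loss costs the least summed, weighted benefit across species, divided by the
cell's cost and adjusted by a boundary-length penalty:

    δi = (1/ci) · Σj wj·[V(qj) − V(qj without i)] + β · Δ(BL/A)

where qj is the fraction of species j's total occurrence still remaining and
V(q) = q**z. Higher δi means the cell is more valuable to keep. Removal
proceeds in batches of ``warp`` lowest-δ cells, restricted (by default) to the
edges of the remaining patches; protected cells are never candidates and end
up with the highest ranks. The normalized removal order is the rank map: the
top fraction f of ranks is the f-coverage scenario.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import CostLayer, Grid, PAMask, SpeciesLayer

__all__ = [
    "PrioritizerConfig",
    "RepresentationState",
    "RankMap",
    "PerformanceCurves",
    "PrioritizationResult",
    "DegenerateStateError",
    "benefit",
    "marginal_value",
    "edge_candidates",
    "boundary_delta",
    "boundary_length",
    "run_prioritization",
    "greedy_oracle",
]


class DegenerateStateError(RuntimeError):
    """Raised when an operation would empty or has emptied the landscape."""


@dataclass(frozen=True)
class PrioritizerConfig:
    """Knobs of the removal loop.

    beta: strength of the boundary-length penalty (0 disables it).
    warp: cells removed per iteration.
    z: exponent of the benefit function V(q) = q**z.
    edge_only: restrict candidates to patch edges.
    neighborhood: 4- or 8-connectivity for edge detection (boundary length is
        always counted over cell sides, i.e. 4-connectivity).
    seed: seeds the random tie-break permutation.
    """

    beta: float = 0.1
    warp: int = 50
    z: float = 0.25
    edge_only: bool = True
    neighborhood: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.warp < 1:
            raise ValueError("warp must be at least 1")
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")


def benefit(q: float, z: float) -> float:
    """Benefit V(q) = q**z; V(0)=0, V(1)=1, concave for z<1."""
    if z <= 0:
        raise ValueError("z must be positive")
    q_arr = np.asarray(q, dtype=float)
    if (q_arr < 0).any() or (q_arr > 1).any():
        raise ValueError("q must lie in [0, 1]")
    out = q_arr**z
    return float(out) if np.isscalar(q) or q_arr.ndim == 0 else out


def boundary_length(remaining: np.ndarray) -> float:
    """Total exposed cell sides of the remaining patches.

    A side is exposed if it faces a non-remaining cell, NoData, or the
    lattice border; NoData cells contribute no sides of their own.
    """
    padded = np.pad(np.asarray(remaining, dtype=bool), 1, constant_values=False)
    horiz = padded[:, 1:] != padded[:, :-1]
    vert = padded[1:, :] != padded[:-1, :]
    return float(horiz.sum() + vert.sum())


@dataclass
class RepresentationState:
    """Mutable state of the removal loop.

    ``q`` is derived: per-species remaining occurrence over total occurrence.
    """

    grid: Grid
    remaining: np.ndarray  # bool lattice; NoData cells are always False
    occupancy: np.ndarray  # (n_species, n_cells) uint8, flattened row-major
    totals: np.ndarray  # (n_species,) occurrence over the full landscape
    remaining_counts: np.ndarray  # (n_species,) occurrence over `remaining`
    species_ids: list[str]
    boundary_length: float
    area: float

    @classmethod
    def from_layers(
        cls, layers: Sequence[SpeciesLayer], grid: Grid
    ) -> "RepresentationState":
        for layer in layers:
            grid.check_same(layer.grid)
            if not layer.is_binary:
                raise ValueError(f"layer {layer.species_id!r} is not binary")
        occ = np.stack(
            [(l.values & grid.valid_mask).ravel() for l in layers]
        ).astype(np.uint8)
        totals = occ.sum(axis=1).astype(float)
        zero = [layers[j].species_id for j in np.flatnonzero(totals == 0)]
        if zero:
            raise ValueError(f"species with zero occurrence: {zero}")
        remaining = grid.valid_mask.copy()
        return cls(
            grid=grid,
            remaining=remaining,
            occupancy=occ,
            totals=totals,
            remaining_counts=totals.copy(),
            species_ids=[l.species_id for l in layers],
            boundary_length=boundary_length(remaining),
            area=float(remaining.sum()),
        )

    @property
    def q(self) -> np.ndarray:
        return self.remaining_counts / self.totals

    def remove(self, flat_cells: np.ndarray) -> None:
        """Remove a batch of flat cell indices and update all running totals."""
        flat_cells = np.atleast_1d(flat_cells)
        rem_flat = self.remaining.ravel()
        if not rem_flat[flat_cells].all():
            raise ValueError("attempt to remove a cell that is not remaining")
        rem_flat[flat_cells] = False
        self.remaining_counts = self.remaining_counts - self.occupancy[
            :, flat_cells
        ].sum(axis=1)
        self.area -= len(flat_cells)
        self.boundary_length = boundary_length(self.remaining)


def _neighbor_shifts(neighborhood: int) -> list[tuple[int, int]]:
    shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if neighborhood == 8:
        shifts += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    return shifts


def _count_remaining_neighbors(
    remaining: np.ndarray, shifts: list[tuple[int, int]]
) -> np.ndarray:
    """Per-cell count of remaining neighbors (off-grid counts as absent)."""
    padded = np.pad(remaining, 1, constant_values=False)
    count = np.zeros(remaining.shape, dtype=np.int8)
    for dr, dc in shifts:
        count += padded[
            1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc
        ]
    return count


def edge_candidates(
    state: RepresentationState, pa: PAMask, config: PrioritizerConfig
) -> np.ndarray:
    """Boolean lattice of removal candidates.

    Candidates are remaining, unprotected cells that either lie on the
    lattice border or touch a non-remaining cell under the configured
    neighborhood. If ``edge_only`` is set but no edge candidate exists while
    unprotected cells remain, all remaining unprotected cells are returned.
    """
    free = state.remaining & ~pa.mask
    if not config.edge_only:
        return free
    shifts = _neighbor_shifts(config.neighborhood)
    n_nb = _count_remaining_neighbors(state.remaining, shifts)
    on_border = np.zeros(state.remaining.shape, dtype=bool)
    on_border[0, :] = on_border[-1, :] = True
    on_border[:, 0] = on_border[:, -1] = True
    edge = free & (on_border | (n_nb < len(shifts)))
    if not edge.any() and free.any():
        return free
    return edge


def boundary_delta(
    state: RepresentationState, cell: tuple[int, int], config: PrioritizerConfig
) -> float:
    """Change of the boundary-length-to-area ratio if *cell* were removed.

    Returns BL'/A' − BL/A (post minus pre). Sides are always counted under
    4-connectivity regardless of the configured neighborhood.
    """
    r, c = cell
    if not state.remaining[r, c]:
        raise ValueError(f"cell {cell} is not remaining")
    if state.area < 2:
        raise DegenerateStateError("removal would empty the landscape")
    n_rem = 0
    for dr, dc in _neighbor_shifts(4):
        rr, cc = r + dr, c + dc
        if 0 <= rr < state.grid.n_rows and 0 <= cc < state.grid.n_cols:
            n_rem += int(state.remaining[rr, cc])
    bl_after = state.boundary_length + 2 * n_rem - 4
    return bl_after / (state.area - 1) - state.boundary_length / state.area


def marginal_value(
    state: RepresentationState,
    cell: tuple[int, int],
    layers: Sequence[SpeciesLayer],
    weights: Sequence[float],
    cost: CostLayer,
    config: PrioritizerConfig,
) -> float:
    """δi of one remaining cell: the value of keeping it.

    (1/ci) · Σj wj·[V(qj) − V(qj with cell i removed)] + β·Δ(BL/A).
    """
    r, c = cell
    if not state.remaining[r, c]:
        raise ValueError(f"cell {cell} is not remaining")
    if state.area < 2:
        raise DegenerateStateError("removing the cell would empty the landscape")
    flat = r * state.grid.n_cols + c
    delta = 0.0
    for j, layer in enumerate(layers):
        if state.occupancy[j, flat]:
            qj = state.remaining_counts[j] / state.totals[j]
            qji = (state.remaining_counts[j] - 1) / state.totals[j]
            delta += weights[j] * (benefit(qj, config.z) - benefit(qji, config.z))
    delta /= cost.values[r, c]
    if config.beta > 0:
        delta += config.beta * boundary_delta(state, cell, config)
    return float(delta)


@dataclass(frozen=True)
class RankMap:
    """Per-cell priority in (0, 1]: normalized removal order, higher = removed
    later = more important. NaN outside the valid mask."""

    grid: Grid
    rank: np.ndarray

    def top_fraction_count(self, fraction: float) -> int:
        """Number of cells in the top *fraction*, rounding half away from zero."""
        import math

        return int(math.floor(fraction * self.grid.n_valid + 0.5))


@dataclass(frozen=True)
class PerformanceCurves:
    """Per-species representation q as a function of landscape retained."""

    retained_fractions: np.ndarray  # decreasing, starts at 1.0
    representation: np.ndarray  # (n_steps, n_species)
    species_ids: list[str]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.representation,
            columns=self.species_ids,
            index=pd.Index(self.retained_fractions, name="retained_fraction"),
        )


@dataclass(frozen=True)
class PrioritizationResult:
    rank_map: RankMap
    curves: PerformanceCurves
    removal_order: np.ndarray  # (n_valid, 2) cells, first removed first
    log: list[dict] = field(default_factory=list)


def _tie_break_perm(n_cells: int, seed: int) -> np.ndarray:
    """Seeded random permutation used to break δ ties deterministically."""
    return np.random.default_rng(seed).permutation(n_cells).astype(float)


def _batch_deltas(
    state: RepresentationState,
    cand_flat: np.ndarray,
    weights: np.ndarray,
    cost_flat: np.ndarray,
    config: PrioritizerConfig,
) -> np.ndarray:
    """Vectorized δi over a set of candidate flat indices."""
    q = state.q
    q_minus = np.maximum(state.remaining_counts - 1, 0.0) / state.totals
    per_species = weights * (q**config.z - q_minus**config.z)
    species_term = per_species @ state.occupancy[:, cand_flat]
    delta = species_term / cost_flat[cand_flat]
    if config.beta > 0 and state.area >= 2:
        n_nb = _count_remaining_neighbors(
            state.remaining, _neighbor_shifts(4)
        ).ravel()[cand_flat]
        bl_after = state.boundary_length + 2 * n_nb - 4
        dbla = bl_after / (state.area - 1) - state.boundary_length / state.area
        delta = delta + config.beta * dbla
    return delta


def run_prioritization(
    layers: Sequence[SpeciesLayer],
    weights: Sequence[float],
    cost: CostLayer,
    pa: PAMask,
    config: PrioritizerConfig = PrioritizerConfig(),
) -> PrioritizationResult:
    """Rank every valid cell by iterative lowest-δ removal.

    Unprotected cells are removed in ``warp``-sized batches (δ computed once
    per iteration, ties broken by a seeded permutation then row-major index)
    until only protected cells remain; protected cells are then ranked by a
    warp=1 pass over the protected-only landscape, so they always receive the
    highest ranks. Removal position k of N yields rank k/N.
    """
    if not layers:
        raise ValueError("at least one species layer is required")
    grid = layers[0].grid
    grid.check_same(cost.grid)
    grid.check_same(pa.grid)
    state = RepresentationState.from_layers(layers, grid)
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(layers),):
        raise ValueError("weights length does not match layers")
    cost_flat = cost.values.ravel()
    n_cells = grid.n_rows * grid.n_cols
    n_valid = grid.n_valid
    perm = _tie_break_perm(n_cells, config.seed)
    if pa.mask.all() or not (grid.valid_mask & ~pa.mask).any():
        warnings.warn("PA mask covers the whole landscape; ranks follow PA ordering")

    removal: list[int] = []
    fractions: list[float] = [1.0]
    reps: list[np.ndarray] = [state.q.copy()]
    log: list[dict] = []

    def _remove_batch(cand_mask: np.ndarray, warp: int) -> None:
        cand_flat = np.flatnonzero(cand_mask.ravel())
        delta = _batch_deltas(state, cand_flat, w, cost_flat, config)
        order = np.lexsort((cand_flat, perm[cand_flat], delta))
        batch = cand_flat[order[: min(warp, len(cand_flat))]]
        state.remove(batch)
        removal.extend(int(b) for b in batch)
        fractions.append(state.area / n_valid)
        reps.append(state.q.copy())
        log.append(
            {"candidates": int(len(cand_flat)), "removed": int(len(batch))}
        )

    # Phase 1: strip unprotected cells.
    while True:
        cand = edge_candidates(state, pa, config)
        if not cand.any():
            break
        _remove_batch(cand, config.warp)

    # Phase 2: rank protected cells on the PA-only landscape, one at a time.
    no_pa = PAMask(grid=grid, mask=np.zeros(grid.shape, dtype=bool))
    pa_config = PrioritizerConfig(
        beta=config.beta,
        warp=1,
        z=config.z,
        edge_only=False,
        neighborhood=config.neighborhood,
        seed=config.seed,
    )
    while state.remaining.any():
        cand = edge_candidates(state, no_pa, pa_config)
        _remove_batch(cand, 1)

    rank = np.full(grid.shape, np.nan)
    flat_order = np.asarray(removal)
    rank.ravel()[flat_order] = np.arange(1, n_valid + 1) / n_valid
    removal_cells = np.column_stack(np.unravel_index(flat_order, grid.shape))
    return PrioritizationResult(
        rank_map=RankMap(grid=grid, rank=rank),
        curves=PerformanceCurves(
            retained_fractions=np.asarray(fractions),
            representation=np.vstack(reps),
            species_ids=state.species_ids,
        ),
        removal_order=removal_cells,
        log=log,
    )


def greedy_oracle(
    layers: Sequence[SpeciesLayer],
    weights: Sequence[float],
    cost: CostLayer,
    pa: PAMask,
    config: PrioritizerConfig,
) -> list[tuple[int, int]]:
    """From-scratch single-cell greedy removal for validating the fast path.

    At every step δi is recomputed for every remaining unprotected cell using
    fresh recounts of each species' remaining occurrence (no incremental
    state), and the single minimum is removed; ties are broken by the same
    seeded permutation as :func:`run_prioritization`. Returns the removal
    order of unprotected cells. Intended for small grids (≲ 12×12).
    """
    if config.warp != 1:
        raise ValueError("greedy_oracle requires warp=1")
    grid = layers[0].grid
    for layer in layers:
        if not layer.is_binary:
            raise ValueError("oracle requires binary layers")
    occ = [(l.values & grid.valid_mask) for l in layers]
    totals = [float(o.sum()) for o in occ]
    if any(t == 0 for t in totals):
        raise ValueError("species with zero occurrence")
    remaining = grid.valid_mask.copy()
    perm = _tie_break_perm(grid.n_rows * grid.n_cols, config.seed)
    order: list[tuple[int, int]] = []

    def _bl(mask: np.ndarray) -> float:
        return boundary_length(mask)

    while True:
        free = [
            (r, c)
            for r, c in np.argwhere(remaining & ~pa.mask)
        ]
        if not free:
            break
        best_key, best_cell = None, None
        area = float(remaining.sum())
        bl_now = _bl(remaining)
        for r, c in free:
            delta = 0.0
            for j, o in enumerate(occ):
                if o[r, c]:
                    rem_j = float((o & remaining).sum())
                    qj = rem_j / totals[j]
                    qji = (rem_j - 1) / totals[j]
                    delta += weights[j] * (qj ** config.z - qji ** config.z)
            delta /= float(cost.values[r, c])
            if config.beta > 0 and area >= 2:
                trial = remaining.copy()
                trial[r, c] = False
                delta += config.beta * (_bl(trial) / (area - 1) - bl_now / area)
            key = (delta, perm[r * grid.n_cols + c], r * grid.n_cols + c)
            if best_key is None or key < best_key:
                best_key, best_cell = key, (int(r), int(c))
        remaining[best_cell] = False
        order.append(best_cell)
    return order
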