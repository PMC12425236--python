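"""Virtual landscapes: land cover, suitability surfaces, presences, costs, PAs.

Every generator takes an explicit integer seed and is bit-reproducible; there
is no global random state. The generators emulate the statistical structure
the downstream analysis assumes — species pools with range sizes spanning two
orders of magnitude, a natural/human land-cover dichotomy driving a two-valued
cost layer, and compact protected-area patches.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage

from .types import (
    IUCN_WEIGHTS,
    CostLayer,
    Grid,
    LandClass,
    LandCoverGrid,
    OccurrenceSet,
    PAMask,
    SpeciesLayer,
    VirtualSpeciesSpec,
)

__all__ = [
    "gen_landcover",
    "gen_suitability",
    "sample_presences",
    "gen_cost",
    "gen_pa_mask",
    "weight_from_iucn",
    "gen_species_pool",
]


def weight_from_iucn(category: str) -> int:
    """Map an IUCN Red List category to an integer conservation weight.

    LC→1, NT→2, VU→3, EN→4, CR→5. Unknown categories raise — there is no
    silent default.
    """
    try:
        return IUCN_WEIGHTS[category]
    except KeyError:
        raise ValueError(
            f"unknown IUCN category {category!r}; expected one of "
            f"{sorted(IUCN_WEIGHTS)}"
        ) from None


def gen_landcover(
    grid: Grid,
    n_types: int,
    natural_fraction: float,
    patchiness: float = 3.0,
    seed: int = 0,
) -> LandCoverGrid:
    """Generate a categorical land-cover grid with a target natural fraction.

    A Gaussian-smoothed noise field is thresholded at its empirical
    ``1 - natural_fraction`` quantile to split the landscape into natural and
    human super-regions (so the realized fraction is exact up to one cell);
    a second smoothed field subdivides each super-region into classes.
    ``patchiness`` is the smoothing sigma in cells — larger means coarser
    patches.
    """
    if n_types < 2:
        raise ValueError("n_types must be at least 2")
    if not 0 <= natural_fraction <= 1:
        raise ValueError("natural_fraction must be in [0, 1]")
    if patchiness <= 0:
        raise ValueError("patchiness must be positive")

    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.normal(size=grid.shape), patchiness)
    sub = ndimage.gaussian_filter(rng.normal(size=grid.shape), patchiness)

    valid = grid.valid_mask
    if natural_fraction >= 1.0:
        natural = valid.copy()
    elif natural_fraction <= 0.0:
        natural = np.zeros(grid.shape, dtype=bool)
    else:
        cut = np.quantile(field[valid], 1.0 - natural_fraction)
        natural = (field > cut) & valid

    # Split the class budget between the two super-regions, keeping at least
    # one class on each side whenever both sides exist.
    if natural_fraction >= 1.0:
        n_nat, n_hum = n_types, 0
    elif natural_fraction <= 0.0:
        n_nat, n_hum = 0, n_types
    else:
        n_nat = int(np.clip(round(n_types * natural_fraction), 1, n_types - 1))
        n_hum = n_types - n_nat

    codes = np.zeros(grid.shape, dtype=np.int32)
    class_map: dict[int, LandClass] = {}

    def _assign(mask: np.ndarray, n_classes: int, offset: int, is_nat: bool) -> None:
        for k in range(n_classes):
            kind = "natural" if is_nat else "human"
            class_map[offset + k] = LandClass(f"{kind}_{k}", is_nat)
        if not mask.any():
            return
        vals = sub[mask]
        edges = np.quantile(vals, np.linspace(0, 1, n_classes + 1)[1:-1])
        codes[mask] = offset + np.searchsorted(edges, vals, side="right")

    _assign(natural, n_nat, 0, True) if n_nat else None
    _assign(valid & ~natural, n_hum, n_nat, False) if n_hum else None
    return LandCoverGrid(grid=grid, codes=codes, class_map=class_map)


def gen_suitability(
    grid: Grid,
    spec: VirtualSpeciesSpec,
    landcover: LandCoverGrid,
    affinity: Mapping[int, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SpeciesLayer:
    """Continuous habitat suitability for one virtual species.

    Isotropic Gaussian kernel in cell distance from ``spec.center``, scaled to
    ``spec.max_suitability``, multiplied by the per-class land-cover affinity,
    plus truncated Gaussian noise; the result is clipped to [0, 1].
    """
    grid.check_same(landcover.grid)
    present = set(int(c) for c in np.unique(landcover.codes[grid.valid_mask]))
    missing = present - set(int(k) for k in affinity)
    if missing:
        raise ValueError(f"affinity undefined for land-cover codes {sorted(missing)}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rows, cols = np.indices(grid.shape)
    d2 = (rows - spec.center[0]) ** 2.0 + (cols - spec.center[1]) ** 2.0
    kernel = spec.max_suitability * np.exp(-d2 / (2.0 * spec.spread**2))

    aff = np.zeros(grid.shape)
    for code, a in affinity.items():
        aff[landcover.codes == code] = a
    values = kernel * aff
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(scale=noise_sd, size=grid.shape)
    values = np.clip(values, 0.0, 1.0)
    values[~grid.valid_mask] = 0.0
    return SpeciesLayer(
        species_id=spec.species_id,
        grid=grid,
        values=values,
        iucn_category=spec.iucn_category,
    )


def sample_presences(layer: SpeciesLayer, n: int, seed: int = 0) -> OccurrenceSet:
    """Draw ``n`` presence cells with replacement, probability ∝ suitability."""
    if layer.is_binary:
        raise ValueError("presence sampling requires a continuous layer")
    if n < 1:
        raise ValueError("n must be at least 1")
    weights = np.where(layer.grid.valid_mask, layer.values, 0.0).ravel()
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            f"species {layer.species_id!r} has all-zero suitability; "
            "cannot sample presences"
        )
    rng = np.random.default_rng(seed)
    flat = rng.choice(weights.size, size=n, replace=True, p=weights / total)
    cells = np.column_stack(np.unravel_index(flat, layer.grid.shape))
    return OccurrenceSet(species_id=layer.species_id, cells=cells)


def gen_cost(
    landcover: LandCoverGrid, natural_cost: float = 10.0, human_cost: float = 1.0
) -> CostLayer:
    """Two-valued cost layer: ``natural_cost`` on natural classes, else ``human_cost``."""
    if natural_cost <= 0 or human_cost <= 0:
        raise ValueError("costs must be positive")
    natural = landcover.natural_mask()
    values = np.where(natural, natural_cost, human_cost)
    return CostLayer(grid=landcover.grid, values=values)


def gen_pa_mask(
    grid: Grid, fraction: float, n_patches: int = 1, seed: int = 0
) -> PAMask:
    """Protected-area mask covering ``round(fraction * n_valid)`` cells.

    Patches are grown by seeded region-growing (random frontier expansion,
    4-connected), producing compact reserves. If the cell budget cannot
    support ``n_patches`` non-empty patches the patch count is reduced with a
    warning.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if n_patches < 1:
        raise ValueError("n_patches must be at least 1")
    n_target = int(round(fraction * grid.n_valid))
    mask = np.zeros(grid.shape, dtype=bool)
    if n_target == 0:
        return PAMask(grid=grid, mask=mask)
    if n_target < n_patches:
        warnings.warn(
            f"PA budget of {n_target} cells cannot fill {n_patches} patches; "
            f"reducing to {n_target}",
            stacklevel=2,
        )
        n_patches = n_target

    rng = np.random.default_rng(seed)
    valid_cells = np.argwhere(grid.valid_mask)
    seeds = valid_cells[rng.choice(len(valid_cells), size=n_patches, replace=False)]
    # Near-equal per-patch budgets.
    sizes = np.full(n_patches, n_target // n_patches)
    sizes[: n_target % n_patches] += 1

    for patch_seed, size in zip(seeds, sizes):
        frontier = [tuple(patch_seed)]
        grown = 0
        while frontier and grown < size:
            idx = rng.integers(len(frontier))
            r, c = frontier.pop(idx)
            if mask[r, c]:
                continue
            mask[r, c] = True
            grown += 1
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if (
                    0 <= rr < grid.n_rows
                    and 0 <= cc < grid.n_cols
                    and grid.valid_mask[rr, cc]
                    and not mask[rr, cc]
                ):
                    frontier.append((rr, cc))
    # Top up from remaining valid cells if region-growing hit dead ends.
    deficit = n_target - int(mask.sum())
    if deficit > 0:
        free = np.argwhere(grid.valid_mask & ~mask)
        extra = free[rng.choice(len(free), size=deficit, replace=False)]
        mask[extra[:, 0], extra[:, 1]] = True
    return PAMask(grid=grid, mask=mask)


def gen_species_pool(
    grid: Grid,
    landcover: LandCoverGrid,
    n_species: int,
    spread_range: tuple[float, float] = (1.0, 100.0),
    categories: Optional[Sequence[str]] = None,
    noise_sd: float = 0.02,
    n_presences: int = 30,
    seed: int = 0,
) -> tuple[list[SpeciesLayer], list[OccurrenceSet]]:
    """Convenience pool generator: ``n_species`` virtual species whose kernel
    spreads are log-spaced across ``spread_range`` (two orders of magnitude by
    default), with random centers and IUCN categories.

    Natural land-cover classes get affinity 1.0, human classes 0.2, so ranges
    track the natural super-region as the analysis assumes.
    """
    if n_species < 1:
        raise ValueError("n_species must be at least 1")
    rng = np.random.default_rng(seed)
    spreads = np.geomspace(spread_range[0], spread_range[1], n_species)
    cats = list(categories) if categories else list(IUCN_WEIGHTS)
    affinity = {
        code: (1.0 if cls.is_natural else 0.2)
        for code, cls in landcover.class_map.items()
    }
    valid_cells = np.argwhere(grid.valid_mask)
    layers: list[SpeciesLayer] = []
    occs: list[OccurrenceSet] = []
    for i in range(n_species):
        center = tuple(valid_cells[rng.integers(len(valid_cells))])
        spec = VirtualSpeciesSpec(
            species_id=f"sp{i:03d}",
            center=(int(center[0]), int(center[1])),
            spread=float(spreads[i]),
            max_suitability=float(rng.uniform(0.6, 1.0)),
            iucn_category=cats[int(rng.integers(len(cats)))],
            n_presences=n_presences,
        )
        sub_seed = int(rng.integers(2**31))
        layer = gen_suitability(grid, spec, landcover, affinity, noise_sd, sub_seed)
        if layer.values[grid.valid_mask].max() <= 0:  # pragma: no cover
            continue
        layers.append(layer)
        occs.append(sample_presences(layer, spec.n_presences, seed=sub_seed + 1))
    return layers, occs
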