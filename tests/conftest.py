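import numpy as np
import pytest

from landprior import Grid, synthetic_landscape as synth
from landprior.range_mapping import threshold_10pct
from landprior.types import CostLayer, PAMask, SpeciesLayer


@pytest.fixture
def grid20():
    return Grid(20, 20)


@pytest.fixture
def landcover20(grid20):
    return synth.gen_landcover(grid20, 5, 0.6, patchiness=2.0, seed=1)


@pytest.fixture
def landscape20(grid20, landcover20):
    """A complete small landscape: cost, PAs, binary ranges with weights."""
    cost = synth.gen_cost(landcover20)
    pa = synth.gen_pa_mask(grid20, 0.05, n_patches=2, seed=2)
    layers, occs = synth.gen_species_pool(
        grid20, landcover20, 5, spread_range=(1.0, 8.0), noise_sd=0.0, seed=3
    )
    binaries = [threshold_10pct(l, o)[1] for l, o in zip(layers, occs)]
    return {"grid": grid20, "cost": cost, "pa": pa, "binaries": binaries, "occs": occs}


def random_binary_layers(grid, n_species, seed, density=0.3):
    """Random non-empty binary layers for oracle-style tests."""
    rng = np.random.default_rng(seed)
    layers = []
    for i in range(n_species):
        while True:
            values = rng.random(grid.shape) < density
            values &= grid.valid_mask
            if values.any():
                break
        layers.append(SpeciesLayer(species_id=f"sp{i}", grid=grid, values=values))
    return layers


def random_cost(grid, seed):
    rng = np.random.default_rng(seed)
    return CostLayer(grid=grid, values=rng.choice([1.0, 10.0], size=grid.shape))


def empty_pa(grid):
    return PAMask(grid=grid, mask=np.zeros(grid.shape, dtype=bool))
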