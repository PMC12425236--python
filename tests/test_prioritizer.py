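import numpy as np
import pytest

from conftest import empty_pa, random_binary_layers, random_cost
from landprior import Grid, prioritizer as pz
from landprior.types import CostLayer, PAMask, SpeciesLayer


def uniform_cost(grid, value=1.0):
    return CostLayer(grid=grid, values=np.full(grid.shape, value))


def single_species_state(grid, occupied_cells):
    values = np.zeros(grid.shape, dtype=bool)
    for r, c in occupied_cells:
        values[r, c] = True
    layer = SpeciesLayer(species_id="sp", grid=grid, values=values)
    return [layer], pz.RepresentationState.from_layers([layer], grid)


class TestBenefit:
    def test_normalization(self):
        for z in (0.25, 1.0, 2.0):
            assert pz.benefit(1.0, z) == 1.0
            assert pz.benefit(0.0, z) == 0.0

    def test_linear_at_z_one(self):
        assert pz.benefit(0.25, 1.0) == pytest.approx(0.25)

    def test_strictly_increasing_and_concave(self):
        qs = np.linspace(0, 1, 50)
        vals = pz.benefit(qs, 0.25)
        assert (np.diff(vals) > 0).all()
        assert (np.diff(np.diff(vals)) < 1e-12).all()  # concave for z<1

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            pz.benefit(1.5, 0.25)
        with pytest.raises(ValueError):
            pz.benefit(0.5, 0.0)


class TestMarginalValue:
    def test_hand_example_quarter(self):
        # One species on 4 cells, w=1, c=1, beta=0, z=1: removing an occupied
        # cell loses 1/4 of representation -> delta = 1 - 3/4 = 0.25.
        grid = Grid(3, 3)
        layers, state = single_species_state(grid, [(0, 0), (0, 1), (1, 0), (1, 1)])
        config = pz.PrioritizerConfig(beta=0.0, z=1.0, warp=1)
        delta = pz.marginal_value(state, (0, 0), layers, [1.0], uniform_cost(grid), config)
        assert delta == pytest.approx(0.25, abs=1e-12)

    def test_unoccupied_cell_zero(self):
        grid = Grid(3, 3)
        layers, state = single_species_state(grid, [(0, 0)])
        config = pz.PrioritizerConfig(beta=0.0, z=1.0, warp=1)
        delta = pz.marginal_value(state, (2, 2), layers, [1.0], uniform_cost(grid), config)
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_cost_divides(self):
        grid = Grid(3, 3)
        layers, state = single_species_state(grid, [(0, 0), (0, 1), (1, 0), (1, 1)])
        config = pz.PrioritizerConfig(beta=0.0, z=1.0, warp=1)
        delta = pz.marginal_value(
            state, (0, 0), layers, [1.0], uniform_cost(grid, 10.0), config
        )
        assert delta == pytest.approx(0.025, abs=1e-12)

    def test_removed_cell_raises(self):
        grid = Grid(2, 2)
        layers, state = single_species_state(grid, [(0, 0)])
        state.remove(np.array([3]))  # cell (1, 1)
        config = pz.PrioritizerConfig(beta=0.0, z=1.0, warp=1)
        with pytest.raises(ValueError, match="not remaining"):
            pz.marginal_value(state, (1, 1), layers, [1.0], uniform_cost(grid), config)


class TestBoundaryDelta:
    def test_corner_of_full_block(self):
        grid = Grid(3, 3)
        _, state = single_species_state(grid, [(1, 1)])
        assert state.boundary_length == 12 and state.area == 9
        config = pz.PrioritizerConfig()
        delta = pz.boundary_delta(state, (0, 0), config)
        assert delta == pytest.approx(12 / 8 - 12 / 9, abs=1e-12)  # = 1/6

    def test_domino(self):
        grid = Grid(1, 2)
        _, state = single_species_state(grid, [(0, 0), (0, 1)])
        assert state.boundary_length == 6 and state.area == 2
        delta = pz.boundary_delta(state, (0, 0), pz.PrioritizerConfig())
        assert delta == pytest.approx(4 / 1 - 6 / 2, abs=1e-12)  # = 1.0

    def test_isolated_single_cell_patch(self):
        # Isolate (0, 0) by removing its neighbors; removing it then drops BL
        # by 4 and A by 1. Cross-checked against an independent recount.
        grid = Grid(5, 5)
        _, state = single_species_state(grid, [(4, 4)])
        state.remove(np.array([1, 5]))  # cells (0, 1) and (1, 0)
        bl, area = state.boundary_length, state.area
        trial = state.remaining.copy()
        trial[0, 0] = False
        assert pz.boundary_length(trial) == bl - 4
        expected = pz.boundary_length(trial) / (area - 1) - bl / area
        delta = pz.boundary_delta(state, (0, 0), pz.PrioritizerConfig())
        assert delta == pytest.approx(expected, abs=1e-12)

    def test_degenerate_landscape_raises(self):
        grid = Grid(1, 1)
        _, state = single_species_state(grid, [(0, 0)])
        with pytest.raises(pz.DegenerateStateError):
            pz.boundary_delta(state, (0, 0), pz.PrioritizerConfig())


class TestEdgeCandidates:
    def test_full_rectangle_perimeter(self):
        grid = Grid(4, 6)
        _, state = single_species_state(grid, [(0, 0)])
        cand = pz.edge_candidates(state, empty_pa(grid), pz.PrioritizerConfig())
        expected = np.zeros(grid.shape, dtype=bool)
        expected[0, :] = expected[-1, :] = expected[:, 0] = expected[:, -1] = True
        assert np.array_equal(cand, expected)

    def test_inner_block_border(self):
        grid = Grid(5, 5)
        _, state = single_species_state(grid, [(2, 2)])
        keep = np.zeros(grid.shape, dtype=bool)
        keep[1:4, 1:4] = True
        state.remove(np.flatnonzero(~keep.ravel()))
        cand = pz.edge_candidates(state, empty_pa(grid), pz.PrioritizerConfig())
        assert cand.sum() == 8
        assert not cand[2, 2]

    def test_all_pa_gives_empty_set(self):
        grid = Grid(3, 3)
        _, state = single_species_state(grid, [(0, 0)])
        pa = PAMask(grid=grid, mask=np.ones(grid.shape, dtype=bool))
        cand = pz.edge_candidates(state, pa, pz.PrioritizerConfig())
        assert not cand.any()


def recount_q(layers, remaining):
    """Independent from-scratch recount of per-species representation."""
    return np.array(
        [
            (l.values & remaining).sum() / l.values.sum()
            for l in layers
        ]
    )


class TestRunPrioritization:
    def test_two_by_two_single_occupied_cell(self):
        grid = Grid(2, 2)
        values = np.zeros(grid.shape, dtype=bool)
        values[0, 1] = True
        layer = SpeciesLayer("sp", grid, values)
        config = pz.PrioritizerConfig(beta=0.0, warp=1, z=1.0, edge_only=False, seed=1)
        res = pz.run_prioritization(
            [layer], [1.0], uniform_cost(grid), empty_pa(grid), config
        )
        assert res.rank_map.rank[0, 1] == 1.0
        assert tuple(res.removal_order[-1]) == (0, 1)

    def test_rank_multiset(self, landscape20):
        res = pz.run_prioritization(
            landscape20["binaries"],
            [b.weight for b in landscape20["binaries"]],
            landscape20["cost"],
            landscape20["pa"],
            pz.PrioritizerConfig(warp=7, seed=2),
        )
        n = landscape20["grid"].n_valid
        ranks = np.sort(res.rank_map.rank[landscape20["grid"].valid_mask])
        assert np.allclose(ranks, np.arange(1, n + 1) / n)

    def test_pa_cells_outrank_everything(self, landscape20):
        res = pz.run_prioritization(
            landscape20["binaries"],
            [b.weight for b in landscape20["binaries"]],
            landscape20["cost"],
            landscape20["pa"],
            pz.PrioritizerConfig(warp=5, seed=3),
        )
        pa = landscape20["pa"].mask
        valid = landscape20["grid"].valid_mask
        assert res.rank_map.rank[pa].min() > res.rank_map.rank[valid & ~pa].max()

    def test_determinism(self, landscape20):
        args = (
            landscape20["binaries"],
            [b.weight for b in landscape20["binaries"]],
            landscape20["cost"],
            landscape20["pa"],
            pz.PrioritizerConfig(warp=5, seed=4),
        )
        a = pz.run_prioritization(*args)
        b = pz.run_prioritization(*args)
        assert np.array_equal(a.rank_map.rank, b.rank_map.rank, equal_nan=True)
        assert np.array_equal(a.removal_order, b.removal_order)

    def test_zero_occurrence_species_named(self):
        grid = Grid(3, 3)
        good = SpeciesLayer("good", grid, np.ones(grid.shape, dtype=bool))
        bad = SpeciesLayer("ghost", grid, np.zeros(grid.shape, dtype=bool))
        with pytest.raises(ValueError, match="ghost"):
            pz.run_prioritization(
                [good, bad], [1, 1], uniform_cost(grid), empty_pa(grid),
                pz.PrioritizerConfig(),
            )

    def test_all_pa_warns_and_ranks(self):
        grid = Grid(3, 3)
        layer = SpeciesLayer("sp", grid, np.ones(grid.shape, dtype=bool))
        pa = PAMask(grid=grid, mask=np.ones(grid.shape, dtype=bool))
        with pytest.warns(UserWarning, match="whole landscape"):
            res = pz.run_prioritization(
                [layer], [1.0], uniform_cost(grid), pa, pz.PrioritizerConfig(seed=5)
            )
        ranks = np.sort(res.rank_map.rank.ravel())
        assert np.allclose(ranks, np.arange(1, 10) / 9)

    def test_q_conservation_along_trajectory(self, landscape20):
        binaries = landscape20["binaries"]
        res = pz.run_prioritization(
            binaries,
            [b.weight for b in binaries],
            landscape20["cost"],
            landscape20["pa"],
            pz.PrioritizerConfig(warp=9, seed=6),
        )
        grid = landscape20["grid"]
        remaining = grid.valid_mask.copy()
        removed_so_far = 0
        for step, log_entry in enumerate(res.log, start=1):
            batch = res.removal_order[removed_so_far : removed_so_far + log_entry["removed"]]
            remaining[batch[:, 0], batch[:, 1]] = False
            removed_so_far += log_entry["removed"]
            np.testing.assert_allclose(
                res.curves.representation[step],
                recount_q(binaries, remaining),
                atol=1e-12,
            )
        # Curves are non-increasing for every species.
        assert (np.diff(res.curves.representation, axis=0) <= 1e-12).all()
        assert (res.curves.representation[0] == 1.0).all()


class TestGreedyOracle:
    def test_matches_fast_path_on_random_instances(self):
        for seed in range(1, 6):
            grid = Grid(4 + seed % 3, 4 + seed % 2)
            layers = random_binary_layers(grid, 3, seed=seed)
            cost = random_cost(grid, seed=seed + 100)
            pa = empty_pa(grid)
            config = pz.PrioritizerConfig(
                beta=0.0, warp=1, z=0.25, edge_only=False, seed=seed
            )
            oracle = pz.greedy_oracle(layers, [1, 2, 3], cost, pa, config)
            fast = pz.run_prioritization(layers, [1, 2, 3], cost, pa, config)
            assert [tuple(c) for c in fast.removal_order[: len(oracle)]] == oracle

    def test_unoccupied_removed_before_occupied(self):
        grid = Grid(5, 5)
        values = np.zeros(grid.shape, dtype=bool)
        values[2, 1:4] = True
        layer = SpeciesLayer("sp", grid, values)
        config = pz.PrioritizerConfig(beta=0.0, warp=1, z=1.0, edge_only=False, seed=7)
        order = pz.greedy_oracle([layer], [1.0], uniform_cost(grid), empty_pa(grid), config)
        occupied_positions = [i for i, cell in enumerate(order) if values[cell]]
        assert min(occupied_positions) >= 25 - 3

    def test_weightier_species_ranked_higher(self):
        # Disjoint equal-size ranges with weights 5 vs 1: the heavy species'
        # cells are removed later on average.
        grid = Grid(6, 6)
        a = np.zeros(grid.shape, dtype=bool)
        b = np.zeros(grid.shape, dtype=bool)
        a[1:3, 1:3] = True
        b[3:5, 3:5] = True
        layers = [SpeciesLayer("heavy", grid, a), SpeciesLayer("light", grid, b)]
        config = pz.PrioritizerConfig(beta=0.0, warp=1, z=0.25, edge_only=False, seed=8)
        order = pz.greedy_oracle(layers, [5, 1], uniform_cost(grid), empty_pa(grid), config)
        pos = {tuple(c): i for i, c in enumerate(order)}
        mean_heavy = np.mean([pos[tuple(c)] for c in np.argwhere(a)])
        mean_light = np.mean([pos[tuple(c)] for c in np.argwhere(b)])
        assert mean_heavy > mean_light

    def test_requires_warp_one(self):
        grid = Grid(3, 3)
        layer = SpeciesLayer("sp", grid, np.ones(grid.shape, dtype=bool))
        with pytest.raises(ValueError, match="warp"):
            pz.greedy_oracle(
                [layer], [1.0], uniform_cost(grid), empty_pa(grid),
                pz.PrioritizerConfig(warp=2),
            )


def test_cost_sensitivity_rank_non_increasing_in_own_cost():
    # warp=1, single species: raising one occupied cell's cost cannot raise
    # its rank.
    grid = Grid(6, 6)
    rng = np.random.default_rng(9)
    values = rng.random(grid.shape) < 0.4
    values[2, 2] = True
    layer = SpeciesLayer("sp", grid, values)
    config = pz.PrioritizerConfig(beta=0.0, warp=1, z=1.0, edge_only=False, seed=10)
    base_cost = np.ones(grid.shape)
    ranks = []
    for cost_at_cell in (1.0, 5.0, 50.0):
        cost_vals = base_cost.copy()
        cost_vals[2, 2] = cost_at_cell
        res = pz.run_prioritization(
            [layer], [1.0], CostLayer(grid=grid, values=cost_vals),
            empty_pa(grid), config,
        )
        ranks.append(res.rank_map.rank[2, 2])
    assert ranks[0] >= ranks[1] >= ranks[2]


def test_beta_increases_compactness_quick():
    # Smaller companion of the acceptance compactness property: 3 seeds.
    from landprior import synthetic_landscape as synth
    from landprior.range_mapping import threshold_10pct

    ratios = {0.0: [], 1.0: []}
    for seed in range(3):
        grid = Grid(25, 25)
        lc = synth.gen_landcover(grid, 4, 0.6, seed=seed)
        cost = synth.gen_cost(lc)
        layers, occs = synth.gen_species_pool(
            grid, lc, 4, spread_range=(2.0, 8.0), noise_sd=0.0, seed=seed + 50
        )
        binaries = [threshold_10pct(l, o)[1] for l, o in zip(layers, occs)]
        for beta in (0.0, 1.0):
            res = pz.run_prioritization(
                binaries, [b.weight for b in binaries], cost, empty_pa(grid),
                pz.PrioritizerConfig(beta=beta, warp=10, seed=seed),
            )
            top = res.rank_map.rank >= np.nanquantile(res.rank_map.rank, 0.7)
            ratios[beta].append(pz.boundary_length(top) / top.sum())
    assert np.mean(ratios[1.0]) <= np.mean(ratios[0.0])
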