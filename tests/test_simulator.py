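"""Unit and property tests for the lattice simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import termitory as tm
from termitory.model import ACTIVE, EMPTY, INACTIVE, _census
from conftest import build_grid


# ---------------------------------------------------------------- landscape

class TestLandscape:
    @pytest.mark.parametrize("L", [1, 5, 200])
    def test_shape_and_range(self, L, rng):
        land = tm.generate_landscape(L, rng)
        assert land.values.shape == (L, L)
        assert land.values.min() >= 0.0 and land.values.max() <= 1.0

    def test_deterministic_from_seed(self):
        a = tm.generate_landscape(50, np.random.default_rng(7)).values
        b = tm.generate_landscape(50, np.random.default_rng(7)).values
        np.testing.assert_array_equal(a, b)

    def test_immutable(self, rng):
        land = tm.generate_landscape(5, rng)
        with pytest.raises(ValueError):
            land.values[0, 0] = 0.5

    @pytest.mark.parametrize("L", [0, -3])
    def test_invalid_size(self, L, rng):
        with pytest.raises(ValueError):
            tm.generate_landscape(L, rng)

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            tm.Landscape(np.full((3, 3), 1.5))


# ------------------------------------------------------------------ seeding

class TestPlaceSeeds:
    @pytest.mark.parametrize("L,N", [(200, 30), (5, 1), (3, 9)])
    def test_seed_count_and_labels(self, L, N, rng):
        grid = tm.place_seeds(tm.empty_grid(L), N, rng)
        assert np.count_nonzero(grid.state == ACTIVE) == N
        labels = grid.label[grid.state == ACTIVE]
        assert sorted(labels) == list(range(1, N + 1))
        assert len(np.unique(grid.seed_pos, axis=0)) == N
        grid.validate()

    @pytest.mark.parametrize("N", [0, 26])
    def test_invalid_N(self, N, rng):
        with pytest.raises(ValueError):
            tm.place_seeds(tm.empty_grid(5), N, rng)

    def test_requires_empty_grid(self, rng):
        grid = tm.place_seeds(tm.empty_grid(5), 2, rng)
        with pytest.raises(ValueError):
            tm.place_seeds(grid, 2, rng)


# ----------------------------------------------------------- growth attempt

class TestProposeGrowth:
    def test_forced_single_neighbor(self, rng):
        # Lone empty neighbor with P_trans = 1: certain success there.
        grid = build_grid(
            3,
            territories={1: [(r, c) for r in range(3) for c in range(3)
                             if (r, c) not in {(0, 0)}]},
            seeds={1: (1, 1)},
            active={(1, 1)},
        )
        land = tm.Landscape(np.ones((3, 3)))
        prop = tm.propose_growth((1, 1), grid, land, rng)
        assert prop.outcome == "SUCCESS_PENDING"
        assert prop.target == (0, 0)

    def test_target_sampled_proportional_to_ptrans(self):
        # Two empty neighbors with P_trans 0.9 / 0.1: the easy site is
        # chosen with frequency 0.9/(0.9+0.1) over many attempts.
        grid = build_grid(
            3,
            territories={1: [(r, c) for r in range(3) for c in range(3)
                             if (r, c) not in {(0, 1), (2, 1)}]},
            seeds={1: (1, 1)},
            active={(1, 1)},
        )
        vals = np.ones((3, 3))
        vals[0, 1] = 0.9
        vals[2, 1] = 0.1
        land = tm.Landscape(vals)
        rng = np.random.default_rng(42)
        n = 10_000
        hits = sum(
            tm.propose_growth((1, 1), grid, land, rng).target == (0, 1)
            for _ in range(n)
        )
        assert abs(hits / n - 0.9) < 0.02

    def test_no_empty_neighbor_stops(self, rng, uniform_landscape):
        grid = build_grid(
            3,
            territories={1: [(r, c) for r in range(3) for c in range(3)]},
            seeds={1: (1, 1)},
            active={(1, 1)},
        )
        prop = tm.propose_growth((1, 1), grid, land=uniform_landscape(3), rng=rng)
        assert prop.outcome == "STOPPED" and prop.target is None

    def test_requires_active_source(self, rng, uniform_landscape):
        grid = tm.empty_grid(3)
        with pytest.raises(ValueError):
            tm.propose_growth((1, 1), grid, uniform_landscape(3), rng)


# ------------------------------------------------------- conflict resolution

class TestResolveConflicts:
    @pytest.mark.parametrize("k", [2, 3])
    def test_uniform_winner_frequency(self, k):
        rng = np.random.default_rng(11)
        n = 10_000
        wins = np.zeros(k)
        for _ in range(n):
            props = [
                tm.GrowthProposal(source=(i, 0), target=(5, 5),
                                  outcome="SUCCESS_PENDING")
                for i in range(k)
            ]
            assignment = tm.resolve_conflicts(props, rng)
            wins[assignment[(5, 5)][0]] += 1
        assert np.all(np.abs(wins / n - 1 / k) < 0.02)

    def test_single_proposal_always_wins(self, rng):
        p = tm.GrowthProposal(source=(0, 0), target=(1, 1),
                              outcome="SUCCESS_PENDING")
        assert tm.resolve_conflicts([p], rng) == {(1, 1): (0, 0)}
        assert p.outcome == "SUCCESS_PENDING"

    def test_empty_input(self, rng):
        assert tm.resolve_conflicts([], rng) == {}

    def test_losers_marked_stopped(self, rng):
        props = [
            tm.GrowthProposal(source=(i, 0), target=(1, 1),
                              outcome="SUCCESS_PENDING")
            for i in range(2)
        ]
        tm.resolve_conflicts(props, rng)
        outcomes = sorted(p.outcome for p in props)
        assert outcomes == ["STOPPED", "SUCCESS_PENDING"]

    def test_rejects_stopped_input(self, rng):
        p = tm.GrowthProposal(source=(0, 0), target=None, outcome="STOPPED")
        with pytest.raises(ValueError):
            tm.resolve_conflicts([p], rng)


# ------------------------------------------------------------- state changes

class TestApplyStateChanges:
    def test_seven_inactive_neighbors_inactivates(self):
        # Center active, 7 of 8 Moore neighbors inactive -> walled in.
        cells = [(r, c) for r in range(3) for c in range(3)]
        grid = build_grid(3, territories={1: cells}, seeds={1: (1, 1)},
                          active={(1, 1), (0, 0)})
        out = tm.apply_state_changes(grid, [])
        assert out.state[1, 1] == INACTIVE
        np.testing.assert_array_equal(out.label, grid.label)

    def test_six_inactive_neighbors_keeps_active(self):
        cells = [(r, c) for r in range(3) for c in range(3)]
        grid = build_grid(3, territories={1: cells}, seeds={1: (1, 1)},
                          active={(1, 1), (0, 0), (0, 1)})
        out = tm.apply_state_changes(grid, [])
        assert out.state[1, 1] == ACTIVE

    def test_stopped_cells_inactivate(self):
        grid = build_grid(5, territories={1: [(2, 2)]}, seeds={1: (2, 2)},
                          active={(2, 2)})
        out = tm.apply_state_changes(grid, [(2, 2)])
        assert out.state[2, 2] == INACTIVE

    def test_open_active_cell_unchanged(self):
        grid = build_grid(5, territories={1: [(2, 2)]}, seeds={1: (2, 2)},
                          active={(2, 2)})
        out = tm.apply_state_changes(grid, [])
        assert out.state[2, 2] == ACTIVE

    def test_corner_cell_off_lattice_not_counted(self):
        # Corner active cell has only 3 on-lattice neighbors; even all
        # inactive they cannot reach the 7-neighbor threshold.
        grid = build_grid(3, territories={1: [(0, 0), (0, 1), (1, 0), (1, 1)]},
                          seeds={1: (0, 0)}, active={(0, 0)})
        out = tm.apply_state_changes(grid, [])
        assert out.state[0, 0] == ACTIVE

    def test_rejects_non_active_stopped(self):
        grid = tm.empty_grid(3)
        with pytest.raises(ValueError):
            tm.apply_state_changes(grid, [(0, 0)])


# -------------------------------------------------------------- summer step

class TestSummerStep:
    def test_no_active_cells_fixed_point(self, rng, uniform_landscape):
        grid = build_grid(4, territories={1: [(1, 1)]}, seeds={1: (1, 1)})
        out = tm.summer_step(grid, uniform_landscape(4), rng)
        np.testing.assert_array_equal(out.state, grid.state)
        np.testing.assert_array_equal(out.label, grid.label)

    def test_single_seed_certain_soil_adds_one(self, rng, uniform_landscape):
        grid = build_grid(5, territories={1: [(2, 2)]}, seeds={1: (2, 2)},
                          active={(2, 2)})
        out = tm.summer_step(grid, uniform_landscape(5, 1.0), rng)
        assert out.total_termite_cells() == 2

    def test_count_monotone_non_decreasing(self, rng):
        land = tm.generate_landscape(20, rng)
        grid = tm.place_seeds(tm.empty_grid(20), 5, rng)
        for _ in range(15):
            before = grid.total_termite_cells()
            grid = tm.summer_step(grid, land, rng)
            assert grid.total_termite_cells() >= before
            grid.validate()

    def test_landscape_untouched(self, rng):
        land = tm.generate_landscape(10, rng)
        ref = land.values.copy()
        grid = tm.place_seeds(tm.empty_grid(10), 3, rng)
        for _ in range(5):
            grid = tm.summer_step(grid, land, rng)
        np.testing.assert_array_equal(land.values, ref)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 8))
    def test_territories_stay_disjoint(self, seed, n):
        """Exclusivity: every occupied cell has exactly one label."""
        rng = np.random.default_rng(seed)
        land = tm.generate_landscape(12, rng)
        grid = tm.place_seeds(tm.empty_grid(12), n, rng)
        for _ in range(6):
            grid = tm.summer_step(grid, land, rng)
        grid.validate()
        # Labels only ever propagate from a single source territory.
        assert set(np.unique(grid.label)) <= set(range(n + 1))


class TestRunSummer:
    def test_zero_steps_identity(self, rng, uniform_landscape):
        grid = build_grid(4, territories={1: [(1, 1)]}, seeds={1: (1, 1)},
                          active={(1, 1)})
        out = tm.run_summer(grid, uniform_landscape(4), 0, rng)
        np.testing.assert_array_equal(out.state, grid.state)

    def test_full_season_monotone(self, rng):
        # A 36-step season (the field-calibrated summer length).
        land = tm.generate_landscape(30, rng)
        grid = tm.place_seeds(tm.empty_grid(30), 4, rng)
        counts = [grid.total_termite_cells()]
        for _ in range(36):
            grid = tm.summer_step(grid, land, rng)
            counts.append(grid.total_termite_cells())
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_negative_steps_rejected(self, rng, uniform_landscape):
        grid = tm.empty_grid(4)
        with pytest.raises(ValueError):
            tm.run_summer(grid, uniform_landscape(4), -1, rng)


# ------------------------------------------------------------ winter shrink

def _disc_territory(L=21, radius=6.5):
    center = (L // 2, L // 2)
    cells = [
        (r, c)
        for r in range(L)
        for c in range(L)
        if np.hypot(r - center[0], c - center[1]) <= radius
    ]
    return build_grid(L, territories={1: cells}, seeds={1: center}), cells


class TestWinterShrink:
    def test_retains_exact_fraction(self, rng):
        grid, cells = _disc_territory()
        size = len(cells)
        assert size >= 100
        out = tm.winter_shrink(grid, 20.0, rng)
        expected = max(1, int(np.floor(0.2 * size + 0.5)))
        assert out.total_termite_cells() == expected

    def test_sigma_100_keeps_membership_inactive(self, rng):
        grid, cells = _disc_territory()
        out = tm.winter_shrink(grid, 100.0, rng)
        np.testing.assert_array_equal(out.label, grid.label)
        assert np.all(out.state[out.label == 1] == INACTIVE)

    def test_tiny_territory_floor_guard(self, rng):
        # 3 cells at sigma=10: max(1, round(0.3)) = 1 cell = the seed.
        grid = build_grid(5, territories={1: [(2, 2), (2, 3), (2, 4)]},
                          seeds={1: (2, 2)})
        out = tm.winter_shrink(grid, 10.0, rng)
        assert out.total_termite_cells() == 1
        assert out.label[2, 2] == 1

    def test_survivors_are_nearest_to_seed(self, rng):
        """Brute-force oracle: survivors = the keep smallest distances."""
        grid, cells = _disc_territory(L=13, radius=3.5)  # <= 50 cells
        size = len(cells)
        sigma = 30.0
        out = tm.winter_shrink(grid, sigma, rng)
        keep = max(1, int(np.floor(sigma / 100 * size + 0.5)))
        d_all = np.sort([np.hypot(r - 6, c - 6) for r, c in cells])
        survivors = np.argwhere(out.label == 1)
        d_kept = np.sort(np.hypot(survivors[:, 0] - 6, survivors[:, 1] - 6))
        np.testing.assert_allclose(d_kept, d_all[:keep])

    def test_seed_survives_every_winter(self, rng):
        grid, _ = _disc_territory()
        for sigma in (1.0, 5.0, 20.0, 50.0):
            out = tm.winter_shrink(grid, sigma, rng)
            assert out.label[10, 10] == 1

    def test_per_territory_independence(self, two_territory_grid, rng):
        out = tm.winter_shrink(two_territory_grid, 50.0, rng)
        sizes = tm.territory_sizes(out)
        assert sizes == {1: max(1, round(0.5 * 3)), 2: max(1, round(0.5 * 7))}

    @pytest.mark.parametrize("sigma", [0.0, -5.0, 101.0])
    def test_invalid_sigma(self, sigma, rng):
        grid = tm.empty_grid(3)
        with pytest.raises(ValueError):
            tm.winter_shrink(grid, sigma, rng)


# ------------------------------------------------------------- reactivation

class TestReactivate:
    def test_seed_only_territory_forced(self, rng):
        grid = build_grid(3, territories={1: [(1, 1)]}, seeds={1: (1, 1)})
        out = tm.reactivate(grid, 5, rng)
        assert out.state[1, 1] == ACTIVE

    def test_cardinality_contract(self, two_territory_grid, rng):
        out = tm.reactivate(two_territory_grid, 5, rng)
        active_per = {
            t: int(np.count_nonzero((out.state == ACTIVE) & (out.label == t)))
            for t in (1, 2)
        }
        assert active_per == {1: 3, 2: 5}

    def test_distance_weighted_sampling(self):
        # Cells at distance 1 and 3 from the seed, one pick: weights
        # 1 : 3 -> far cell frequency 3/4.
        grid = build_grid(7, territories={1: [(3, 3), (3, 4), (3, 6)]},
                          seeds={1: (3, 3)})
        rng = np.random.default_rng(5)
        n = 10_000
        far = 0
        for _ in range(n):
            out = tm.reactivate(grid, 1, rng)
            far += out.state[3, 6] == ACTIVE
        assert abs(far / n - 0.75) < 0.02

    def test_rejects_grid_with_active_cells(self, rng):
        grid = build_grid(3, territories={1: [(1, 1)]}, seeds={1: (1, 1)},
                          active={(1, 1)})
        with pytest.raises(ValueError):
            tm.reactivate(grid, 1, rng)


# ----------------------------------------------------------- full simulation

class TestRunSimulation:
    def test_zero_cycles_returns_seeded_grid(self):
        cfg = tm.SimConfig(L=20, N=4, T_summer=3, n_cycles=0, rng_seed=1)
        res = tm.run_simulation(cfg)
        assert res.size_history.shape == (0, 4)
        assert res.cycles_run == 0 and not res.steady
        assert res.final_grid.total_termite_cells() == 4

    def test_bit_reproducible_from_seed(self):
        cfg = tm.SimConfig(L=30, N=5, T_summer=5, sigma=30.0, n_cycles=6,
                           rng_seed=123)
        a, b = tm.run_simulation(cfg), tm.run_simulation(cfg)
        np.testing.assert_array_equal(a.final_grid.state, b.final_grid.state)
        np.testing.assert_array_equal(a.final_grid.label, b.final_grid.label)
        np.testing.assert_array_equal(a.size_history, b.size_history)
        assert a.cycles_run == b.cycles_run and a.steady == b.steady

    def test_produces_n_labeled_territories(self):
        cfg = tm.SimConfig(L=50, N=10, T_summer=10, sigma=30.0, n_cycles=5,
                           rng_seed=7)
        res = tm.run_simulation(cfg)
        sizes = tm.territory_sizes(res.final_grid)
        assert set(sizes) == set(range(1, 11))
        assert all(s >= 1 for s in sizes.values())
        res.final_grid.validate()

    def test_history_matches_final_census(self):
        cfg = tm.SimConfig(L=30, N=5, T_summer=4, sigma=40.0, n_cycles=4,
                           steady_tol=0.0, rng_seed=3)
        res = tm.run_simulation(cfg)
        assert res.size_history.shape == (res.cycles_run, 5)
        np.testing.assert_array_equal(res.size_history[-1], _census(res.final_grid))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            tm.SimConfig(L=10, N=0)
        with pytest.raises(ValueError):
            tm.SimConfig(sigma=0.0)
        with pytest.raises(ValueError):
            tm.SimConfig(n_react=0)
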