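import numpy as np
import pytest

from antagogrid import engine, matrices
from antagogrid.engine import EMPTY, Grid, SimParams


def empty_relation(n):
    return matrices.AntagonismMatrix(adj=np.zeros((n, n), bool))


class TestSeedGrid:
    def test_baseline_seeding_occupies_3900_cells(self):
        for seed in (0, 1, 99):
            grid = engine.seed_grid(
                200, 200, np.full(78, 50), np.random.default_rng(seed)
            )
            occupied = (grid.state != EMPTY).sum()
            assert occupied == 3900
            counts = grid.population_counts(78)
            assert (counts[1:] == 50).all()
            assert counts[0] == 36_100

    def test_zero_counts_gives_empty_grid(self):
        grid = engine.seed_grid(10, 10, [0, 0], np.random.default_rng(0))
        assert (grid.state == EMPTY).all()

    def test_capacity_error(self):
        counts = [50, 51]  # 101 colonies on 100 cells
        with pytest.raises(ValueError, match="cannot place"):
            engine.seed_grid(10, 10, counts, np.random.default_rng(0))


class TestNeighbors:
    def test_interior_cell_has_8(self):
        for boundary in ("torus", "bounded"):
            grid = Grid(np.zeros((5, 5), int), boundary=boundary)
            assert len(engine.neighbors(grid, (2, 2))) == 8

    def test_bounded_corner_has_3(self):
        grid = Grid(np.zeros((5, 5), int), boundary="bounded")
        assert sorted(engine.neighbors(grid, (0, 0))) == [(0, 1), (1, 0), (1, 1)]

    def test_torus_corner_has_8_distinct(self):
        grid = Grid(np.zeros((3, 3), int), boundary="torus")
        nbrs = engine.neighbors(grid, (0, 0))
        assert len(nbrs) == 8 and len(set(nbrs)) == 8


class TestStep:
    def test_all_empty_stays_empty(self):
        grid = Grid(np.zeros((6, 6), int))
        out = engine.step(grid, empty_relation(3), SimParams(), np.random.default_rng(0))
        assert (out.state == EMPTY).all()

    def test_full_peaceful_grid_is_absorbing(self):
        rng = np.random.default_rng(4)
        grid = Grid(rng.integers(1, 4, size=(8, 8)))
        params = SimParams(pd=0.0)
        for seed in range(5):
            out = engine.step(
                grid, empty_relation(3), params, np.random.default_rng(seed)
            )
            assert np.array_equal(out.state, grid.state)

    def test_expected_growth_on_3x3_torus(self):
        # one occupied cell on a 3x3 torus: each of the 8 empty cells sees
        # the occupied cell among its 8 Moore neighbors, so it colonizes
        # with probability 1/8; E[occupied after one step] = 1 + 8/8 = 2
        state = np.zeros((3, 3), int)
        state[1, 1] = 1
        grid = Grid(state)
        params = SimParams(pg=1.0, pd=0.0)
        matrix = empty_relation(1)
        rng = np.random.default_rng(123)
        trials = 100_000
        total = 0
        for _ in range(trials):
            total += (engine.step(grid, matrix, params, rng).state != EMPTY).sum()
        mean = total / trials
        # Var of each colonization Bernoulli(1/8): n*p*(1-p) = 8*7/64
        se = np.sqrt(8 * (1 / 8) * (7 / 8) / trials)
        assert abs(mean - 2.0) < 3 * se

    def test_single_aggressor_kill_probability_is_one_eighth(self):
        # victim at the center of a bounded 3x3 full grid with exactly one
        # aggressor among its 8 neighbors, Pd=0: it is emptied iff it draws
        # the aggressor, probability 1/8
        adj = np.zeros((2, 2), bool)
        adj[0, 1] = True  # strain 1 antagonizes strain 2
        matrix = matrices.AntagonismMatrix(adj=adj)
        state = np.full((3, 3), 2)
        state[0, 0] = 1
        grid = Grid(state, boundary="bounded")
        params = SimParams(pd=0.0)
        rng = np.random.default_rng(5)
        trials = 50_000
        killed = 0
        for _ in range(trials):
            out = engine.step(grid, matrix, params, rng)
            killed += out.state[1, 1] == EMPTY
        p = killed / trials
        se = np.sqrt((1 / 8) * (7 / 8) / trials)
        assert abs(p - 1 / 8) < 3 * se

    def test_no_direct_strain_to_strain_transition(self):
        adj = np.zeros((2, 2), bool)
        adj[0, 1] = True
        matrix = matrices.AntagonismMatrix(adj=adj)
        rng = np.random.default_rng(8)
        grid = Grid(rng.integers(0, 3, size=(10, 10)))
        for seed in range(10):
            out = engine.step(grid, matrix, SimParams(), np.random.default_rng(seed))
            changed = (grid.state != out.state) & (grid.state != EMPTY)
            assert (out.state[changed] == EMPTY).all()

    def test_async_sweep_preserves_peaceful_fixed_point(self):
        rng = np.random.default_rng(4)
        grid = Grid(rng.integers(1, 4, size=(8, 8)))
        params = SimParams(update_mode="asynchronous_sweep", pd=0.0)
        out = engine.step(grid, empty_relation(3), params, np.random.default_rng(1))
        assert np.array_equal(out.state, grid.state)


class TestShuffle:
    def test_population_conservation(self):
        rng = np.random.default_rng(11)
        grid = Grid(rng.integers(0, 5, size=(12, 12)))
        shuffled = engine.shuffle_grid(grid, rng)
        assert np.array_equal(
            np.bincount(grid.state.ravel(), minlength=5),
            np.bincount(shuffled.state.ravel(), minlength=5),
        )

    def test_uniform_grid_unchanged(self):
        grid = Grid(np.full((4, 4), 3))
        shuffled = engine.shuffle_grid(grid, np.random.default_rng(0))
        assert np.array_equal(shuffled.state, grid.state)

    def test_2x2_permutations_uniform(self):
        # 4 distinct labels -> 24 permutations, each with probability 1/24
        grid = Grid(np.array([[1, 2], [3, 4]]))
        rng = np.random.default_rng(99)
        trials = 240_000
        seen = {}
        for _ in range(trials):
            key = tuple(engine.shuffle_grid(grid, rng).state.ravel())
            seen[key] = seen.get(key, 0) + 1
        assert len(seen) == 24
        expected = trials / 24
        for count in seen.values():
            assert abs(count - expected) < 5 * np.sqrt(expected)


class TestRunSimulation:
    def test_zero_steps_returns_initial_grid(self):
        matrix = empty_relation(2)
        params = SimParams(width=10, height=10, steps=0, seed=3)
        result = engine.run_simulation(matrix, params, [5, 5])
        assert result.trajectory.shape == (1, 2)
        assert (result.trajectory[0] == 5).all()
        assert (result.final_grid.state != EMPTY).sum() == 10

    def test_same_seed_bit_identical(self, exp_matrix):
        params = SimParams(width=30, height=30, steps=40, seed=17,
                           shuffle_interval=10, snapshot_steps=(20,))
        counts = np.full(78, 2)
        a = engine.run_simulation(exp_matrix, params, counts)
        b = engine.run_simulation(exp_matrix, params, counts)
        assert np.array_equal(a.trajectory, b.trajectory)
        assert np.array_equal(a.final_grid.state, b.final_grid.state)
        assert np.array_equal(a.snapshots[20], b.snapshots[20])

    def test_population_conservation_every_step(self, exp_matrix):
        params = SimParams(width=25, height=25, steps=30, pd=0.05, seed=2)
        result = engine.run_simulation(exp_matrix, params, np.full(78, 2))
        totals = result.trajectory.sum(axis=1) + result.empty_trajectory
        assert (totals == 25 * 25).all()

    def test_single_peaceful_strain_grows_monotonically_to_fill(self):
        matrix = empty_relation(1)
        params = SimParams(width=12, height=12, steps=60, seed=0)
        result = engine.run_simulation(matrix, params, [4])
        pops = result.trajectory[:, 0]
        assert (np.diff(pops) >= 0).all()
        assert pops[-1] == 144

    def test_unantagonized_strain_never_shrinks_without_mortality(self, exp_matrix):
        # strain ids with in-degree 0 cannot lose cells when Pd = 0
        params = SimParams(width=40, height=40, steps=60, seed=6)
        result = engine.run_simulation(exp_matrix, params, np.full(78, 2))
        immune = np.flatnonzero(exp_matrix.in_degree == 0)
        diffs = np.diff(result.trajectory[:, immune], axis=0)
        assert (diffs >= 0).all()


class TestScaledInitialCounts:
    def test_cap_applied_to_most_populous(self):
        ref = np.array([8000, 4000, 2000])
        counts = engine.scaled_initial_counts(ref, 200, 200)
        assert counts[0] == 400  # 1% of 40,000
        assert counts[1] == 200 and counts[2] == 100

    def test_uniform_reference_all_capped(self):
        counts = engine.scaled_initial_counts(np.full(5, 123.0), 100, 100)
        assert (counts == 100).all()

    def test_floor_protection(self):
        ref = np.array([8000, 1])
        counts = engine.scaled_initial_counts(ref, 200, 200)
        assert counts[1] == 1

    def test_all_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            engine.scaled_initial_counts(np.zeros(3), 10, 10)
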