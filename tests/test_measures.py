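import numpy as np
import pytest

from antagogrid import engine, measures
from antagogrid.engine import Grid
from antagogrid.measures import StationarityRule

from .oracles import flood_fill_patches, spearman_by_hand


class TestPatchSizes:
    def test_uniform_grid_is_one_patch(self):
        grid = Grid(np.full((6, 9), 2))
        report = measures.patch_sizes(grid)
        assert report.sizes == {2: [54]}

    def test_empty_grid_empty_report(self):
        report = measures.patch_sizes(Grid(np.zeros((5, 5), int)))
        assert report.sizes == {}
        assert report.total_cells == 0

    def test_checkerboard_moore8_one_patch_per_strain(self):
        state = np.indices((8, 8)).sum(axis=0) % 2 + 1
        report = measures.patch_sizes(Grid(state), connectivity="moore8")
        assert report.sizes == {1: [32], 2: [32]}

    def test_checkerboard_vonneumann4_all_singletons(self):
        state = np.indices((6, 6)).sum(axis=0) % 2 + 1
        report = measures.patch_sizes(Grid(state), connectivity="vonneumann4")
        assert all(sizes == [1] * 18 for sizes in report.sizes.values())

    @pytest.mark.parametrize("boundary", ["torus", "bounded"])
    @pytest.mark.parametrize("connectivity", ["moore8", "vonneumann4"])
    def test_matches_flood_fill_oracle(self, boundary, connectivity):
        rng = np.random.default_rng(31)
        for _ in range(15):
            state = rng.integers(0, 4, size=rng.integers(1, 9, size=2))
            grid = Grid(state, boundary=boundary)
            report = measures.patch_sizes(grid, connectivity=connectivity)
            oracle = flood_fill_patches(state, boundary, connectivity)
            assert {s: sorted(v, reverse=True) for s, v in report.sizes.items()} \
                == oracle

    def test_torus_wrap_merges_edge_patch(self):
        state = np.zeros((5, 5), int)
        state[0, :] = 1
        state[4, :] = 1  # touches row 0 across the wrap
        report = measures.patch_sizes(Grid(state, boundary="torus"))
        assert report.sizes == {1: [10]}
        bounded = measures.patch_sizes(Grid(state, boundary="bounded"))
        assert bounded.sizes == {1: [5, 5]}

    def test_conservation_and_moore_dominates_vonneumann(self):
        rng = np.random.default_rng(5)
        state = rng.integers(0, 5, size=(20, 20))
        grid = Grid(state)
        m8 = measures.patch_sizes(grid, "moore8")
        v4 = measures.patch_sizes(grid, "vonneumann4")
        occupied = int((state != 0).sum())
        assert m8.total_cells == v4.total_cells == occupied
        for s in m8.sizes:
            assert len(m8.sizes[s]) <= len(v4.sizes[s])
            assert max(m8.sizes[s]) >= max(v4.sizes[s])


class TestPopulationCounts:
    def test_fresh_baseline_grid_counts(self):
        grid = engine.seed_grid(200, 200, np.full(78, 50), np.random.default_rng(1))
        counts, empty = measures.population_counts(grid, 78)
        assert (counts == 50).all()
        assert empty == 36_100

    def test_all_empty(self):
        counts, empty = measures.population_counts(Grid(np.zeros((7, 3), int)), 4)
        assert counts.sum() == 0 and empty == 21

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(2)
        state = rng.integers(0, 6, size=(9, 11))
        counts, empty = measures.population_counts(Grid(state), 5)
        for s in range(1, 6):
            assert counts[s - 1] == sum(
                state[r, c] == s for r in range(9) for c in range(11)
            )
        assert empty == (state == 0).sum()


class TestStationarity:
    def test_constant_trajectory_starts_stationary(self):
        traj = np.full((100, 3), 40.0)
        assert measures.stationarity_step(traj, StationarityRule(window=50)) == 0

    def test_steady_growth_never_stationary(self):
        traj = np.arange(0, 2000, 20, dtype=float)[:, None]
        rule = StationarityRule(window=10, rel_tol=0.01, abs_floor=5)
        assert measures.stationarity_step(traj, rule) is None

    def test_flat_from_constructed_step(self):
        # 5% growth per step (always above the 1% tolerance) until step
        # 137, exactly flat afterwards
        t_axis = np.arange(0, 338)
        traj = (100 * 1.05 ** np.minimum(t_axis, 137))[:, None]
        rule = StationarityRule(window=50, rel_tol=0.01, abs_floor=5)
        assert measures.stationarity_step(traj, rule) == 137

    def test_window_longer_than_trajectory_rejected(self):
        with pytest.raises(ValueError, match="window"):
            measures.stationarity_step(np.zeros((10, 2)), StationarityRule(window=50))

    def test_looser_tolerance_is_earlier_or_equal(self):
        rng = np.random.default_rng(42)
        base = 500 + np.cumsum(rng.normal(0, 4, size=300))
        traj = np.abs(base)[:, None]
        steps = []
        for tol in (0.01, 0.05, 0.2):
            rule = StationarityRule(window=40, rel_tol=tol, abs_floor=1)
            t = measures.stationarity_step(traj, rule)
            steps.append(np.inf if t is None else t)
        assert steps[0] >= steps[1] >= steps[2]


class TestRankCorrelation:
    def test_identity_and_reversal(self):
        x = np.array([3.0, 1.0, 7.0, 5.0])
        assert measures.rank_correlation(x, x) == pytest.approx(1.0)
        assert measures.rank_correlation(x, -x) == pytest.approx(-1.0)

    def test_ties_match_hand_computation(self):
        x = np.array([1, 2, 2, 3, 5, 5, 5, 9], dtype=float)
        y = np.array([4, 4, 1, 7, 2, 8, 8, 3], dtype=float)
        assert measures.rank_correlation(x, y) == pytest.approx(
            spearman_by_hand(x, y)
        )

    def test_constant_vector_returns_none_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert measures.rank_correlation([1, 1, 1], [1, 2, 3]) is None

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho = measures.rank_correlation(x, y)
        assert measures.rank_correlation(np.exp(x), y) == pytest.approx(rho)
        assert measures.rank_correlation(x, y**3) == pytest.approx(rho)


class TestAggregateReplicates:
    def _tiny_results(self, seeds, steps=20):
        from antagogrid import matrices

        adj = np.zeros((3, 3), bool)
        adj[0, 1] = True
        matrix = matrices.AntagonismMatrix(adj=adj)
        out = []
        for s in seeds:
            params = engine.SimParams(width=10, height=10, steps=steps, seed=s)
            out.append(engine.run_simulation(matrix, params, [5, 5, 5]))
        return out

    def test_single_replicate_summary_equals_its_values(self):
        (res,) = self._tiny_results([1])
        summary = measures.aggregate_replicates([res])
        assert np.array_equal(summary.mean_final_pop, res.final_populations)
        assert np.array_equal(summary.median_final_pop, res.final_populations)
        assert np.array_equal(
            summary.survival_count, (res.final_populations > 0).astype(int)
        )

    def test_duplicated_replicate_zero_iqr(self):
        (res,) = self._tiny_results([4])
        summary = measures.aggregate_replicates([res, res])
        assert np.array_equal(summary.q1_final_pop, summary.q3_final_pop)

    def test_means_match_hand_computation(self):
        results = self._tiny_results([1, 2, 3, 4])
        summary = measures.aggregate_replicates(results)
        finals = np.stack([r.final_populations for r in results])
        assert np.allclose(summary.mean_final_pop, finals.mean(axis=0))

    def test_inconsistent_strain_sets_rejected(self):
        results = self._tiny_results([1])
        other = engine.run_simulation(
            np.zeros((2, 2), bool),
            engine.SimParams(width=5, height=5, steps=2, seed=0),
            [2, 2],
        )
        with pytest.raises(ValueError, match="inconsistent"):
            measures.aggregate_replicates(results + [other])
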