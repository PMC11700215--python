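"""SOM primitives: normalisation, BMU competition, decay schedules, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ramansom import som
from ramansom.som import (SOMConfig, SOMGrid, alpha_at, bmu, init_grid,
                          map_observations, neighborhood_weights,
                          normalize_rows, quantization_error, sigma_at,
                          train, train_naive)


def _grid(weights, x_dim, y_dim):
    return SOMGrid(np.asarray(weights, float), x_dim, y_dim)


class TestNormalizeRows:
    def test_three_four_five(self):
        np.testing.assert_allclose(normalize_rows(np.array([[3.0, 4.0]])),
                                   [[0.6, 0.8]])

    def test_unit_row_unchanged(self):
        row = np.array([[1.0, 0.0, 0.0]])
        np.testing.assert_array_equal(normalize_rows(row), row)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_row_norms_are_unit(self, seed):
        m = np.random.default_rng(seed).random((17, 23)) + 0.01
        norms = np.linalg.norm(normalize_rows(m), axis=1)
        np.testing.assert_allclose(norms, 1.0, rtol=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            normalize_rows(np.zeros((2, 4)))


class TestInitGrid:
    def test_reproducible_from_seed(self):
        cfg = SOMConfig(x_dim=6, y_dim=4, seed=3)
        a, b = init_grid(cfg, 10), init_grid(cfg, 10)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_default_lattice_dimensions(self):
        grid = init_grid(SOMConfig(), 1056)
        assert grid.weights.shape == (140, 1056)

    def test_weights_in_unit_interval(self):
        grid = init_grid(SOMConfig(x_dim=5, y_dim=4, seed=0), 64)
        assert grid.weights.min() >= 0.0 and grid.weights.max() < 1.0


class TestBMU:
    def test_exact_node_match(self):
        cfg = SOMConfig(x_dim=7, y_dim=5, seed=1)
        grid = init_grid(cfg, 12)
        target = grid.node_weights(5, 3).copy()
        assert bmu(grid, target) == (5, 3)

    def test_two_node_inspection_case(self):
        grid = _grid([[0.0, 0.0], [1.0, 1.0]], x_dim=2, y_dim=1)
        assert bmu(grid, np.array([0.9, 0.9])) == (1, 0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_exhaustive_minimisation(self, seed):
        rng = np.random.default_rng(seed)
        grid = _grid(rng.random((24, 9)), x_dim=6, y_dim=4)
        v = rng.random(9)
        dists = [np.linalg.norm(grid.node_weights(x, y) - v)
                 for y in range(4) for x in range(6)]
        k = int(np.argmin(dists))
        assert bmu(grid, v) == (k % 6, k // 6)


class TestSchedules:
    def test_sigma_anchors(self):
        cfg = SOMConfig(sigma0=3.0, t_max=10 ** 6)
        assert sigma_at(0, cfg) == 3.0
        assert sigma_at(cfg.t_max, cfg) == pytest.approx(1.0)
        assert sigma_at(5 * 10 ** 5, cfg) == pytest.approx(1.5)

    @pytest.mark.parametrize("sigma0", [1.5, 2.0, 3.0, 8.0])
    def test_sigma_ends_at_one_for_any_start(self, sigma0):
        cfg = SOMConfig(sigma0=sigma0, t_max=12345)
        assert sigma_at(cfg.t_max, cfg) == pytest.approx(1.0)

    def test_alpha_anchors_and_monotonicity(self):
        cfg = SOMConfig(alpha0=0.75, t_max=10 ** 6)
        assert alpha_at(0, cfg) == 0.75
        assert alpha_at(cfg.t_max, cfg) == pytest.approx(0.25)
        ts = np.linspace(0, cfg.t_max, 101)
        vals = [alpha_at(t, cfg) for t in ts]
        assert np.all(np.diff(vals) < 0)


class TestNeighborhood:
    def test_unity_at_bmu_and_closed_form_at_sigma(self):
        grid = init_grid(SOMConfig(x_dim=9, y_dim=7, seed=0), 4)
        h = neighborhood_weights(grid, (4, 3), sigma=2.0)
        k = grid.node_index(4, 3)
        assert h[k] == 1.0
        assert h[grid.node_index(6, 3)] == pytest.approx(np.exp(-0.5))

    def test_strictly_decreasing_with_lattice_distance(self):
        grid = init_grid(SOMConfig(x_dim=9, y_dim=7, seed=0), 4)
        h = neighborhood_weights(grid, (0, 0), sigma=1.5)
        assert h[grid.node_index(1, 0)] > h[grid.node_index(2, 0)] \
            > h[grid.node_index(3, 0)]


class TestTraining:
    def test_single_observation_attracts_all_nodes(self):
        cfg = SOMConfig(x_dim=4, y_dim=3, sigma0=2.0, alpha0=0.5,
                        t_max=2000, seed=0)
        data = normalize_rows(np.random.default_rng(1).random((1, 16)))
        grid = init_grid(cfg, 16)
        trained = train(grid, data, cfg)
        x, y = bmu(trained, data[0])
        assert np.linalg.norm(trained.node_weights(x, y) - data[0]) < 1e-3

    def test_zero_learning_rate_is_identity(self):
        rng = np.random.default_rng(0)
        grid = _grid(rng.random((12, 8)), 4, 3)
        data = normalize_rows(rng.random((5, 8)))
        out = som._train_loop_numpy(grid.weights.copy(), data,
                                    np.zeros(50, int),
                                    np.arange(12, dtype=float) % 4,
                                    np.arange(12, dtype=float) // 4,
                                    3.0, 0.0, 50.0)
        np.testing.assert_array_equal(out, grid.weights)

    def test_single_step_contracts_bmu_toward_sample(self):
        cfg = SOMConfig(x_dim=4, y_dim=3, seed=2, t_max=1)
        rng = np.random.default_rng(3)
        data = normalize_rows(rng.random((6, 10)))
        grid = init_grid(cfg, 10)
        sampled = som._rng(cfg.seed, 1).integers(0, 6, size=1)[0]
        before_bmu = bmu(grid, data[sampled])
        d_before = np.linalg.norm(grid.node_weights(*before_bmu) - data[sampled])
        trained = train(grid, data, cfg, n_steps=1)
        d_after = np.linalg.norm(trained.node_weights(*before_bmu) - data[sampled])
        assert d_after < d_before

    def test_full_training_determinism(self):
        cfg = SOMConfig(x_dim=6, y_dim=4, t_max=500, seed=5)
        data = normalize_rows(np.random.default_rng(7).random((20, 32)))
        grid = init_grid(cfg, 32)
        a = train(grid, data, cfg)
        b = train(grid, data, cfg)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_fast_loop_matches_naive_reference(self):
        """Cross-check: the compiled trainer against an independent,
        primitive-by-primitive reference implementation."""
        cfg = SOMConfig(x_dim=5, y_dim=3, sigma0=2.0, alpha0=0.6,
                        t_max=300, seed=9)
        data = normalize_rows(np.random.default_rng(11).random((12, 8)))
        grid = init_grid(cfg, 8)
        fast = train(grid, data, cfg)
        naive = train_naive(grid, data, cfg)
        np.testing.assert_allclose(fast.weights, naive.weights, rtol=1e-8)
        qe_fast = quantization_error(fast, data)
        qe_naive = quantization_error(naive, data)
        assert abs(qe_fast - qe_naive) <= 0.1 * qe_naive

    def test_empty_data_rejected(self):
        cfg = SOMConfig(x_dim=4, y_dim=3)
        with pytest.raises(ValueError):
            train(init_grid(cfg, 4), np.empty((0, 4)), cfg)


class TestMapObservations:
    def test_hits_sum_to_observation_count(self):
        cfg = SOMConfig(x_dim=6, y_dim=4, t_max=300, seed=1)
        data = normalize_rows(np.random.default_rng(5).random((40, 16)))
        trained = train(init_grid(cfg, 16), data, cfg)
        hits = map_observations(trained, data)
        assert sum(len(v) for v in hits.values()) == 40

    def test_duplicates_share_a_node_and_match_bmu(self):
        cfg = SOMConfig(x_dim=6, y_dim=4, t_max=300, seed=1)
        rng = np.random.default_rng(6)
        data = normalize_rows(rng.random((10, 16)))
        data[7] = data[3]
        trained = train(init_grid(cfg, 16), data, cfg)
        hits = map_observations(trained, data)
        coord_of = {i: c for c, obs in hits.items() for i in obs}
        assert coord_of[3] == coord_of[7]
        for i in range(10):
            assert coord_of[i] == bmu(trained, data[i])


class TestConfigValidation:
    def test_square_lattice_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            SOMConfig(x_dim=10, y_dim=10)

    @pytest.mark.parametrize("kwargs", [
        {"t_max": 0}, {"alpha0": 0.0}, {"alpha0": 1.5}, {"sigma0": 0.5},
        {"x_dim": 1, "y_dim": 2},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SOMConfig(**kwargs)
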