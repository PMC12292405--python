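"""Evolutionary projection search: operators, determinism, convergence."""

import numpy as np
import pytest

from evoslide import (
    EAConfig,
    Population,
    TransformationMatrix,
    crossover,
    evolve,
    fitness,
    init_population,
    load_matrix,
    mutate,
    save_matrix,
    select,
    silhouette,
    transform,
)
from evoslide.projections import pca_projection


def test_config_validation():
    with pytest.raises(ValueError):
        EAConfig(P=1)
    with pytest.raises(ValueError):
        EAConfig(mu=1.5)
    with pytest.raises(ValueError):
        EAConfig(elite_count=5, P=5)
    with pytest.raises(ValueError):
        EAConfig(subsample_fraction=0.0)


class TestInitPopulation:
    def test_population_size_and_determinism(self):
        cfg = EAConfig(P=5, seed=9)
        pop1 = init_population(cfg, d_in=30, d_out=2)
        pop2 = init_population(cfg, d_in=30, d_out=2)
        assert len(pop1.candidates) == 5
        for a, b in zip(pop1.candidates, pop2.candidates):
            np.testing.assert_array_equal(a, b)

    def test_entry_variance_matches_one_over_din(self):
        cfg = EAConfig(P=5, seed=0)
        pop = init_population(cfg, d_in=1024, d_out=2)
        entries = np.concatenate([c.ravel() for c in pop.candidates])
        var = entries.var()
        expected = 1.0 / 1024
        se = expected * np.sqrt(2.0 / (entries.size - 1))
        assert abs(var - expected) < 3 * se

    def test_dout_must_be_smaller_than_din(self):
        with pytest.raises(ValueError):
            init_population(EAConfig(), d_in=4, d_out=4)


class TestSelect:
    def _pop(self, fits):
        return Population(candidates=[np.zeros((2, 1))] * len(fits), fitness=fits)

    def test_top_k_descending(self):
        assert select(self._pop([0.1, 0.9, 0.5]), 2) == [1, 2]

    def test_k_equals_p_returns_everyone(self):
        assert select(self._pop([0.3, 0.2, 0.1]), 3) == [0, 1, 2]

    def test_tie_broken_by_lower_index(self):
        assert select(self._pop([0.5, 0.5]), 1) == [0]

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            select(self._pop([0.1]), 2)


class TestCrossoverMutate:
    def test_crossover_mean_when_rho_one(self, rng):
        child = crossover(np.array([[0.0, 2.0]]), np.array([[4.0, 0.0]]), 1.0, rng)
        np.testing.assert_array_equal(child, [[2.0, 1.0]])

    def test_crossover_copy_when_rho_zero(self, rng):
        p1 = np.array([[1.0, 2.0]])
        child = crossover(p1, np.array([[9.0, 9.0]]), 0.0, rng)
        np.testing.assert_array_equal(child, p1)
        assert child is not p1

    def test_crossover_identical_parents(self, rng):
        p = np.array([[3.0, -1.0]])
        np.testing.assert_array_equal(crossover(p, p, 1.0, rng), p)

    def test_crossover_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            crossover(np.zeros((2, 2)), np.zeros((3, 2)), 0.5, rng)

    def test_mutate_noop_when_mu_or_sigma_zero(self, rng):
        W = np.ones((3, 2))
        np.testing.assert_array_equal(mutate(W, 0.0, 0.1, rng), W)
        np.testing.assert_array_equal(mutate(W, 1.0, 0.0, rng), W)

    def test_mutate_mean_absolute_perturbation_is_half_normal(self):
        rng = np.random.default_rng(5)
        sigma = 0.1
        W = np.zeros((100, 100))
        Wm = mutate(W, 1.0, sigma, rng)
        mean_abs = np.abs(Wm - W).mean()
        expected = sigma * np.sqrt(2 / np.pi)
        sd = sigma * np.sqrt(1 - 2 / np.pi)
        assert abs(mean_abs - expected) < 3 * sd / np.sqrt(W.size)


class TestFitness:
    def test_zero_matrix_gives_zero_fitness(self, lowvar_feature_set):
        X, y = lowvar_feature_set
        assert fitness(np.zeros((20, 2)), X, y) == 0.0

    def test_identity_matrix_equals_raw_silhouette(self, lowvar_feature_set):
        X, y = lowvar_feature_set
        assert fitness(np.eye(20), X, y) == pytest.approx(silhouette(X, y))

    def test_random_matrix_on_no_signal_data(self):
        from evoslide.synthetic import SyntheticFeatureSpec, gen_feature_set

        fm, y = gen_feature_set(
            SyntheticFeatureSpec(n_per_class=200, dim=20, separation_delta=0.0,
                                 seed=1)
        )
        rng = np.random.default_rng(0)
        W = rng.normal(size=(20, 2))
        assert abs(fitness(W, fm.values, y)) < 0.05


class TestEvolve:
    def test_zero_generations_returns_best_initial(self, lowvar_feature_set):
        X, y = lowvar_feature_set
        cfg = EAConfig(P=4, G=0, seed=3)
        W, report = evolve(X, y, cfg, d_out=2)
        assert len(report.best) == 1
        pop = init_population(cfg, 20, 2, rng=np.random.default_rng(3))
        fits = [silhouette(X @ c, y) for c in pop.candidates]
        assert report.best[0] == pytest.approx(max(fits))
        np.testing.assert_array_equal(W.W, pop.candidates[int(np.argmax(fits))])

    def test_trace_monotone_with_elitism(self, lowvar_feature_set):
        X, y = lowvar_feature_set
        for seed in (0, 1, 2):
            _, report = evolve(X, y, EAConfig(P=5, G=30, seed=seed), d_out=2)
            best = np.array(report.best)
            assert (np.diff(best) >= -1e-12).all()

    def test_deterministic_per_seed(self, lowvar_feature_set):
        X, y = lowvar_feature_set
        cfg = EAConfig(P=4, G=20, seed=11)
        W1, r1 = evolve(X, y, cfg, d_out=2)
        W2, r2 = evolve(X, y, cfg, d_out=2)
        np.testing.assert_array_equal(W1.W, W2.W)
        assert r1.best == r2.best

    def test_beats_pca_on_lowvar_family(self, lowvar_feature_set):
        X, y = lowvar_feature_set
        cfg = EAConfig(P=5, G=300, mu=0.8, rho=0.4, sigma=0.1, seed=7)
        W, _ = evolve(X, y, cfg, d_out=2)
        ea_sil = silhouette(transform(X, W), y)
        pca_sil = silhouette(transform(X, pca_projection(X, 2)), y)
        assert ea_sil >= 0.4
        assert ea_sil >= pca_sil + 0.2

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            evolve(np.zeros((10, 4)), np.zeros(10), EAConfig(G=1), d_out=2)


class TestTransform:
    def test_identity_and_zero(self):
        X = np.arange(6.0).reshape(3, 2)
        np.testing.assert_array_equal(transform(X, np.eye(2)), X)
        np.testing.assert_array_equal(transform(X, np.zeros((2, 1))),
                                      np.zeros((3, 1)))

    def test_hand_example(self):
        out = transform(np.array([[1.0, 2.0], [3.0, 4.0]]), np.array([[1.0], [1.0]]))
        np.testing.assert_array_equal(out, [[3.0], [7.0]])

    def test_linearity(self, rng):
        X = rng.normal(size=(5, 4))
        Y = rng.normal(size=(5, 4))
        W = rng.normal(size=(4, 2))
        np.testing.assert_allclose(
            transform(2.0 * X + 3.0 * Y, W),
            2.0 * transform(X, W) + 3.0 * transform(Y, W),
            atol=1e-12,
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            transform(np.zeros((3, 4)), np.zeros((5, 2)))


class TestMatrixIO:
    def test_round_trip_exact(self, tmp_path, rng):
        W = TransformationMatrix(W=rng.normal(size=(6, 2)),
                                 provenance={"method": "test", "seed": 1})
        path = tmp_path / "m.txt"
        save_matrix(W, path)
        loaded = load_matrix(path)
        np.testing.assert_array_equal(loaded.W, W.W)
        assert loaded.provenance == W.provenance

    def test_dim_mismatch_raises(self, tmp_path):
        path = tmp_path / "m.txt"
        save_matrix(TransformationMatrix(W=np.eye(3)[:, :2]), path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # drop a payload row
        with pytest.raises(ValueError, match="do not match"):
            load_matrix(path)

    def test_corrupt_header_raises(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("not json\n1 2\n")
        with pytest.raises(ValueError, match="corrupt"):
            load_matrix(path)
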