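"""Closed-form Gaussian machinery checked against independent routes:
direct-formula evaluation, Monte-Carlo sampling, and grid integration."""

import numpy as np
import pytest

from mdggm import (
    GaussianGraphicalModel,
    VariablePartition,
    condition,
    data_log_likelihood,
    differential_entropy,
    edge_list,
    free_energy,
    kl_divergence,
    load_model,
    log_density,
    sample,
    save_model,
    symmetric_kl,
    write_edges_csv,
)
from conftest import make_random_model
from oracles import direct_log_density, grid_condition_oracle

HALF_LOG_2PI = 0.5 * np.log(2 * np.pi)


def std_normal(n=1):
    return GaussianGraphicalModel(mean=np.zeros(n), precision=np.eye(n))


class TestLogDensity:
    def test_standard_normal_at_mean(self):
        assert log_density(std_normal(), np.zeros(1)) == pytest.approx(-HALF_LOG_2PI)

    def test_at_mean_equals_minus_log_partition(self, rng):
        m = make_random_model(4, 7)
        assert log_density(m, m.mean) == pytest.approx(free_energy(m), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_direct_formula(self, seed):
        m = make_random_model(3, seed)
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=3)
        expected = direct_log_density(m.mean, m.covariance, x)
        assert log_density(m, x) == pytest.approx(expected, abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            log_density(std_normal(2), np.zeros(3))


class TestFreeEnergyAndEntropy:
    def test_scalar_unit_variance(self):
        assert free_energy(std_normal()) == pytest.approx(-HALF_LOG_2PI)
        assert differential_entropy(std_normal()) == pytest.approx(0.5 * np.log(2 * np.pi * np.e))

    def test_bivariate_identity(self):
        assert free_energy(std_normal(2)) == pytest.approx(-np.log(2 * np.pi))
        assert differential_entropy(std_normal(2)) == pytest.approx(np.log(2 * np.pi * np.e))

    def test_entropy_matches_monte_carlo(self):
        m = make_random_model(4, 11)
        draws = sample(m, 100_000, seed=5)
        lp = log_density(m, draws)
        se = np.std(lp, ddof=1) / np.sqrt(lp.shape[0])
        assert differential_entropy(m) == pytest.approx(-np.mean(lp), abs=3 * se)


class TestKL:
    def test_self_divergence_zero(self):
        m = make_random_model(5, 3)
        assert abs(kl_divergence(m, m)) < 1e-12

    def test_unit_mean_shift_scalar(self):
        m0 = std_normal()
        m1 = GaussianGraphicalModel(mean=np.ones(1), precision=np.eye(1))
        assert kl_divergence(m0, m1) == pytest.approx(0.5)
        assert symmetric_kl(m0, m1) == pytest.approx(1.0)

    def test_matches_monte_carlo(self):
        m0 = make_random_model(3, 21)
        m1 = make_random_model(3, 22)
        draws = sample(m0, 200_000, seed=9)
        diff = log_density(m0, draws) - log_density(m1, draws)
        se = np.std(diff, ddof=1) / np.sqrt(diff.shape[0])
        assert kl_divergence(m0, m1) == pytest.approx(np.mean(diff), abs=3 * se)

    def test_nonnegative_and_symmetric_over_random_pairs(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(1, 9))
            a = make_random_model(n, int(rng.integers(2**31)))
            b = make_random_model(n, int(rng.integers(2**31)))
            kl = kl_divergence(a, b)
            assert kl >= -1e-10
            assert symmetric_kl(a, b) == pytest.approx(symmetric_kl(b, a), rel=1e-10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(std_normal(2), std_normal(3))


class TestConditioning:
    def test_diagonal_model_independence(self):
        m = GaussianGraphicalModel(mean=np.array([1.0, 2.0, 3.0]),
                                   precision=np.diag([1.0, 2.0, 4.0]))
        cond = condition(m, VariablePartition(conditioned=(1,), values=np.array([9.0])))
        np.testing.assert_allclose(cond.mean, [1.0, 3.0])
        np.testing.assert_allclose(cond.covariance, np.diag([1.0, 0.25]), atol=1e-12)

    def test_bivariate_textbook_form(self):
        s1, s2, rho = 2.0, 0.5, 0.6
        cov = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
        m = GaussianGraphicalModel.from_covariance(np.array([1.0, -1.0]), cov)
        v = 0.3
        cond = condition(m, VariablePartition(conditioned=(1,), values=np.array([v])))
        assert cond.mean[0] == pytest.approx(1.0 + rho * (s1 / s2) * (v - (-1.0)))
        assert cond.covariance[0, 0] == pytest.approx(s1**2 * (1 - rho**2))

    def test_against_grid_normalization(self, model3):
        v = 1.3
        cond = condition(model3, VariablePartition(conditioned=(1,), values=np.array([v])))
        mu_g, cov_g = grid_condition_oracle(model3.mean, model3.covariance, 1, v)
        np.testing.assert_allclose(cond.mean, mu_g, atol=1e-6)
        np.testing.assert_allclose(cond.covariance, cov_g, atol=1e-6)

    def test_chain_rule(self):
        m = make_random_model(5, 31)
        v_all = np.array([0.2, -0.4])
        both = condition(m, VariablePartition(conditioned=(1, 3), values=v_all))
        first = condition(m, VariablePartition(conditioned=(1,), values=v_all[:1]))
        # after removing index 1, original index 3 sits at position 2
        second = condition(first, VariablePartition(conditioned=(2,), values=v_all[1:]))
        np.testing.assert_allclose(second.mean, both.mean, atol=1e-8)
        np.testing.assert_allclose(second.covariance, both.covariance, atol=1e-8)

    def test_degenerate_partitions_rejected(self):
        m = make_random_model(3, 1)
        with pytest.raises(ValueError):
            condition(m, VariablePartition(conditioned=(), values=np.array([])))
        with pytest.raises(ValueError):
            condition(m, VariablePartition(conditioned=(0, 1, 2), values=np.zeros(3)))


class TestSampling:
    def test_seed_determinism(self):
        m = make_random_model(4, 2)
        np.testing.assert_array_equal(sample(m, 10, seed=3), sample(m, 10, seed=3))

    def test_law_of_large_numbers_mean(self):
        m = make_random_model(3, 13)
        draws = sample(m, 100_000, seed=1)
        sd = np.sqrt(np.diag(m.covariance))
        np.testing.assert_array_less(
            np.abs(draws.mean(axis=0) - m.mean), 4 * sd / np.sqrt(draws.shape[0])
        )

    def test_sample_covariance_converges(self):
        m = make_random_model(3, 14)
        draws = sample(m, 100_000, seed=2)
        emp = np.cov(draws, rowvar=False)
        assert np.max(np.abs(emp - m.covariance)) < 0.05 * np.max(np.abs(m.covariance))

    def test_vanishing_variance_collapses_to_mean(self):
        m = GaussianGraphicalModel(mean=np.array([5.0]), precision=np.array([[1e12]]))
        assert np.max(np.abs(sample(m, 100, seed=0) - 5.0)) < 1e-4


class TestDataLogLikelihood:
    def test_single_frame_at_mean(self):
        m = make_random_model(3, 4)
        ll = data_log_likelihood(m, m.mean[None, :], "total")
        assert ll == pytest.approx(free_energy(m))

    def test_per_frame_is_total_over_t(self, rng):
        m = make_random_model(3, 5)
        data = sample(m, 50, seed=8)
        total = data_log_likelihood(m, data, "total")
        assert data_log_likelihood(m, data, "per_frame") == pytest.approx(total / 50)
        assert data_log_likelihood(m, data, "per_frame_per_dim") == pytest.approx(total / 150)

    def test_own_model_fits_own_data_better(self):
        # mirrors the two-simulation comparison: each dataset is more likely
        # under the model trained on it than under the other model
        from mdggm import CovariateMatrix, EstimationSettings, learn_ggm

        m_a = make_random_model(5, 41, density=0.3)
        m_b = GaussianGraphicalModel(mean=m_a.mean + 2.0,
                                     precision=make_random_model(5, 42, density=0.3).precision)
        data_a = CovariateMatrix(sample(m_a, 2000, seed=1))
        data_b = CovariateMatrix(sample(m_b, 2000, seed=2))
        fit_a = learn_ggm(data_a, EstimationSettings(lambda_=0.05))
        fit_b = learn_ggm(data_b, EstimationSettings(lambda_=0.05))
        assert data_log_likelihood(fit_a, data_a.values, "per_frame") > \
            data_log_likelihood(fit_b, data_a.values, "per_frame")
        assert data_log_likelihood(fit_b, data_b.values, "per_frame") > \
            data_log_likelihood(fit_a, data_b.values, "per_frame")


class TestEdgesAndSerialization:
    def test_edge_list_thresholding(self):
        prec = np.array([[2.0, 0.5, 0.0], [0.5, 2.0, 1e-12], [0.0, 1e-12, 2.0]])
        m = GaussianGraphicalModel(mean=np.zeros(3), precision=prec)
        assert edge_list(m) == [(0, 1, 0.5)]
        assert edge_list(m, threshold=1e-13) == [(0, 1, 0.5), (1, 2, 1e-12)]

    def test_json_round_trip(self, tmp_path):
        m = make_random_model(4, 6)
        path = tmp_path / "model.json"
        save_model(m, path, lam=0.1)
        loaded = load_model(path)
        np.testing.assert_allclose(loaded.mean, m.mean)
        np.testing.assert_allclose(loaded.precision, m.precision)
        np.testing.assert_allclose(loaded.covariance, m.covariance, atol=1e-10)
        assert loaded.labels == m.labels

    def test_edges_csv(self, tmp_path):
        m = GaussianGraphicalModel(mean=np.zeros(2),
                                   precision=np.array([[2.0, -0.7], [-0.7, 2.0]]),
                                   labels=("ALA1", "GLY2"))
        df = write_edges_csv(m, tmp_path / "edges.csv")
        assert list(df.columns) == ["i_label", "j_label", "weight"]
        assert df.iloc[0].tolist() == ["ALA1", "GLY2", -0.7]

    def test_invalid_precision_rejected(self):
        with pytest.raises(ValueError):
            GaussianGraphicalModel(mean=np.zeros(2), precision=np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError):
            GaussianGraphicalModel(mean=np.zeros(2), precision=np.array([[1.0, 0.5], [0.4, 1.0]]))

    def test_natural_param_identity(self):
        m = make_random_model(4, 8)
        np.testing.assert_allclose(m.natural_param, m.precision @ m.mean, atol=1e-10)
        np.testing.assert_allclose(m.covariance @ m.precision, np.eye(4), atol=1e-8)
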