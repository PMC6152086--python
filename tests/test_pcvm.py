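"""Probabilistic classification vector machine: kernel, link, EM fit."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import ppilm as P
from ppilm.pcvm import truncated_normal_mean, default_theta_grid
from conftest import make_blobs, BLOB_THETA


class TestKernel:
    def test_unit_diagonal(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        K = P.kernel_matrix(X, X, theta=0.7)
        assert np.allclose(np.diag(K), 1.0)
        assert np.allclose(K, K.T)

    def test_wide_kernel_limit_is_one(self):
        rng = np.random.default_rng(1)
        K = P.kernel_matrix(rng.normal(size=(4, 2)), rng.normal(size=(5, 2)), theta=1e8)
        assert np.allclose(K, 1.0, atol=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        X, Z = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
        theta = 1.3
        K = P.kernel_matrix(X, Z, theta)
        for i in range(4):
            for j in range(5):
                expected = np.exp(-np.sum((X[i] - Z[j]) ** 2) / theta**2)
                assert K[i, j] == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            P.kernel_matrix(np.zeros((2, 2)), np.zeros((2, 2)), theta=0.0)


class TestProbit:
    def test_symmetry_at_zero(self):
        assert P.probit(0.0) == pytest.approx(0.5)

    def test_complement_identity(self):
        x = np.linspace(-6, 6, 25)
        assert np.allclose(P.probit(x) + P.probit(-x), 1.0, atol=1e-14)

    def test_matches_density_quadrature(self):
        oracle, _ = quad(norm.pdf, -np.inf, 1.96, epsabs=1e-12)
        assert P.probit(1.96) == pytest.approx(oracle, abs=1e-9)


class TestTruncatedNormalMean:
    """The E-step posterior mean of the augmented probit response."""

    @pytest.mark.parametrize("z,y", [(0.0, 1), (1.2, 1), (-0.7, 1), (0.5, -1), (-2.0, -1)])
    def test_matches_monte_carlo_oracle(self, z, y):
        rng = np.random.default_rng(abs(hash((z, y))) % 2**31)
        draws = z + rng.standard_normal(1_000_000)
        kept = draws[draws > 0] if y > 0 else draws[draws < 0]
        assert truncated_normal_mean(z, y) == pytest.approx(kept.mean(), abs=1e-2)

    def test_deep_tail_is_finite_and_signed(self):
        val = truncated_normal_mean(np.array([-30.0]), np.array([1.0]))
        assert np.isfinite(val[0]) and val[0] > 0

    def test_gamma_posterior_precision_mean_matches_sampling(self):
        # E[a | w] under Gamma(c, d) hyperprior is (2c+1)/(2d+w^2):
        # cross-checked by sampling the conjugate posterior directly.
        rng = np.random.default_rng(99)
        c, d, w = 2.0, 1.5, 0.8
        samples = rng.gamma(shape=c + 0.5, scale=1.0 / (d + w**2 / 2), size=1_000_000)
        assert (2 * c + 1) / (2 * d + w**2) == pytest.approx(samples.mean(), rel=1e-2)


class TestFitOnBlobs:
    def test_separable_blobs_high_accuracy(self, blob_task, blob_fit):
        X_train, y_train, X_test, y_test = blob_task
        assert np.mean(blob_fit.predict(X_train) == y_train) == 1.0
        assert np.mean(blob_fit.predict(X_test) == y_test) >= 0.95

    def test_blob_auc(self, blob_task, blob_fit):
        _, _, X_test, y_test = blob_task
        auc, _, _ = P.roc_auc(y_test, blob_fit.predict_proba(X_test))
        assert auc >= 0.99

    def test_sign_constraint_on_retained_weights(self, blob_task, blob_fit):
        _, y_train, _, _ = blob_task
        assert np.all(y_train[blob_fit.basis_ids] * blob_fit.weights >= 0)

    def test_sparsity(self, blob_task, blob_fit):
        assert blob_fit.n_basis < len(blob_task[1])

    def test_label_flip_negates_decision(self, blob_task, blob_fit):
        X_train, y_train, X_test, _ = blob_task
        flipped = P.PCVM(-y_train, X_train).fit(theta=BLOB_THETA)
        p = blob_fit.predict_proba(X_test)
        q = flipped.predict_proba(X_test)
        assert np.max(np.abs(p - (1 - q))) < 1e-6

    def test_em_objective_monotone(self, blob_fit):
        diffs = np.diff(blob_fit.objective_path)
        assert np.all(diffs >= -1e-8)

    def test_reproducibility_bit_identical(self, blob_task, blob_fit):
        X_train, y_train, _, _ = blob_task
        again = P.PCVM(y_train, X_train).fit(theta=BLOB_THETA)
        assert np.array_equal(again.weights, blob_fit.weights)
        assert again.bias == blob_fit.bias
        assert np.array_equal(again.basis_ids, blob_fit.basis_ids)

    def test_sparsity_stable_across_seeds(self):
        sizes = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X, y = make_blobs(60, rng)
            sizes.append(P.PCVM(y, X).fit(theta=BLOB_THETA).n_basis)
        sizes = np.array(sizes)
        assert np.all(np.abs(sizes - sizes.mean()) <= 0.2 * sizes.mean())

    def test_balanced_mean_probability(self, blob_task, blob_fit):
        _, _, X_test, _ = blob_task
        p = blob_fit.predict_proba(X_test)
        assert np.all(np.isfinite(p)) and np.all((p >= 0) & (p <= 1))
        assert 0.25 <= p.mean() <= 0.75


class TestPredict:
    def test_zero_model_predicts_half(self, blob_task):
        X_train, y_train, X_test, _ = blob_task
        res = P.PCVM(y_train, X_train).fit(theta=BLOB_THETA)
        zeroed = P.PCVMResults(
            model=None, basis_ids=res.basis_ids, basis_points=res.basis_points,
            weights=np.zeros_like(res.weights), bias=0.0, theta=res.theta,
            n_iter=1, converged=True, objective_path=np.zeros(1),
        )
        assert np.allclose(zeroed.predict_proba(X_test), 0.5)

    def test_probability_monotone_in_score(self, blob_fit, blob_task):
        _, _, X_test, _ = blob_task
        s = blob_fit.decision_function(X_test)
        p = blob_fit.predict_proba(X_test)
        order = np.argsort(s)
        assert np.all(np.diff(p[order]) >= 0)

    def test_feature_width_mismatch_rejected(self, blob_fit):
        with pytest.raises(ValueError, match="width"):
            blob_fit.predict(np.zeros((3, 5)))

    def test_json_roundtrip(self, blob_fit, blob_task, tmp_path):
        _, _, X_test, _ = blob_task
        blob_fit.save(tmp_path / "model.json")
        back = P.PCVMResults.load(tmp_path / "model.json")
        assert np.allclose(back.predict_proba(X_test), blob_fit.predict_proba(X_test))


class TestFitValidation:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            P.PCVM(np.ones(10), np.zeros((10, 2)))

    def test_nonfinite_features_rejected(self):
        X = np.zeros((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            P.PCVM(np.array([1, -1, 1, -1]), X)

    def test_nonconvergence_warns_but_returns(self, blob_task):
        X_train, y_train, _, _ = blob_task
        with pytest.warns(UserWarning, match="did not converge"):
            res = P.PCVM(y_train, X_train).fit(theta=BLOB_THETA, adapt_iter=2, max_iter=4)
        assert res.n_basis >= 1


class TestSelectInitialization:
    def test_report_shape_and_median(self, blob_task):
        X_train, y_train, _, _ = blob_task
        report = P.select_initialization(X_train, y_train, seed=0)
        assert report.accuracy.shape == (5, 9)
        assert report.fold_winners.size == 5
        assert report.chosen_theta == np.median(report.fold_winners)

    def test_degenerate_all_equal_grid(self, blob_task):
        X_train, y_train, _, _ = blob_task
        report = P.select_initialization(X_train, y_train, candidates=[1.0] * 9, seed=0)
        assert report.chosen_theta == 1.0

    def test_single_usable_candidate_is_chosen(self, blob_task):
        # extreme widths (degenerate kernels) score near chance; the one
        # width matched to the data wins every fold
        X_train, y_train, _, _ = blob_task
        cands = [1e-8] * 4 + [BLOB_THETA] + [1e8] * 4
        report = P.select_initialization(X_train, y_train, candidates=cands, seed=0)
        assert report.chosen_theta == BLOB_THETA

    def test_wrong_candidate_count_rejected(self, blob_task):
        X_train, y_train, _, _ = blob_task
        with pytest.raises(ValueError, match="9 candidate"):
            P.select_initialization(X_train, y_train, candidates=[1.0, 2.0], seed=0)

    def test_default_grid_spans_decades(self):
        grid = default_theta_grid()
        assert grid.size == 9
        assert grid[0] == pytest.approx(1e-2)
        assert grid[-1] == pytest.approx(1e2)
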