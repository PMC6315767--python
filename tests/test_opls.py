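"""OPLS-DA engine: oracle equivalence, decomposition bookkeeping,
cross-validated Q2 and the VIP identities."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from metabomark import (
    compute_vip,
    evaluate_fit,
    fit_oplsda,
    fit_pca,
    hotelling_outliers,
    select_n_ortho,
)


def random_problem(seed, n=20, p=50):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.array([-1.0, 1.0]).repeat(n // 2)
    return X, rng.permutation(y)


class TestFitOplsda:
    def test_zero_ortho_matches_pls1_oracle(self):
        """Independent NIPALS-PLS1 oracle: with no orthogonal components the
        predictive scores equal the first PLS component (up to sign)."""
        for seed in range(10):
            X, y = random_problem(seed)
            m = fit_oplsda(X, y, n_ortho=0)
            t_sk = PLSRegression(n_components=1, scale=False).fit(X, y).x_scores_[:, 0]
            dev = min(np.abs(m.t - t_sk).max(), np.abs(m.t + t_sk).max())
            assert dev < 1e-8

    def test_scores_orthogonal(self):
        X, y = random_problem(3)
        m = fit_oplsda(X, y, n_ortho=2)
        for k in range(m.n_ortho):
            assert abs(m.t @ m.t_ortho[k]) < 1e-8

    def test_weights_unit_norm(self):
        X, y = random_problem(4)
        m = fit_oplsda(X, y, n_ortho=2)
        assert np.linalg.norm(m.w) == pytest.approx(1.0)
        for k in range(m.n_ortho):
            assert np.linalg.norm(m.w_ortho[k]) == pytest.approx(1.0)

    def test_separable_toy_classes_split_by_score_sign(self):
        X = np.array([[1.0, 0.2, 0.1], [1.2, 0.1, 0.0], [-1.0, 0.0, 0.2], [-1.1, 0.3, 0.1]])
        y = np.array(["pos", "pos", "neg", "neg"])
        m = fit_oplsda(X, y, n_ortho=0)
        signs = np.sign(m.t)
        assert len(set(signs[:2])) == 1 and len(set(signs[2:])) == 1
        assert signs[0] != signs[2]

    def test_decomposition_completeness(self):
        """X = t pᵀ + Σ to poᵀ + E with ‖E‖² = (1 − R2X(cum))·‖X‖²."""
        X, y = random_problem(5)
        m = fit_oplsda(X, y, n_ortho=2)
        Xc = X - X.mean(axis=0)
        E = Xc - np.outer(m.t, m.p)
        for k in range(m.n_ortho):
            E -= np.outer(m.t_ortho[k], m.p_ortho[k])
        assert (E**2).sum() == pytest.approx((1 - m.r2x_cum) * m.ss_x, abs=1e-8)

    def test_affine_label_recoding_invariant(self):
        X, _ = random_problem(6)
        y01 = np.array([0, 1] * 10)
        ypm = np.array([-1, 1] * 10)
        ylab = np.array(["ctrl", "case"] * 10)
        t_ref = fit_oplsda(X, ypm, n_ortho=1).t
        for y in (y01, ylab):
            t = fit_oplsda(X, y, n_ortho=1).t
            assert np.allclose(t, t_ref) or np.allclose(t, -t_ref)

    def test_rejects_more_than_two_classes(self):
        X, _ = random_problem(7)
        y = np.array(["a", "b", "c", "a"] * 5)
        with pytest.raises(ValueError, match="two-class"):
            fit_oplsda(X, y)

    def test_rejects_degenerate_y(self):
        X, _ = random_problem(8)
        with pytest.raises(ValueError):
            fit_oplsda(X, np.ones(20))

    def test_coefficients_reproduce_predictions(self):
        X, y = random_problem(9)
        m = fit_oplsda(X, y, n_ortho=2)
        yhat = m.predict(X)
        via_b = (X - m.x_mean) @ m.coefficients + m.y_mean
        assert np.allclose(yhat, via_b)


class TestEvaluateFit:
    def test_noise_free_signal_recovered(self):
        rng = np.random.default_rng(0)
        y = np.array([-1.0, 1.0] * 11)
        X = np.column_stack([y, rng.normal(size=(22, 9)) * 0.01])
        fit = evaluate_fit(X, y, n_ortho=0)
        assert fit.r2y >= 0.99
        assert fit.q2 >= 0.9

    def test_q2_definition_identity(self):
        X, y = random_problem(11)
        fit = evaluate_fit(X, y, n_ortho=1)
        assert fit.q2 == pytest.approx(1 - fit.press / fit.ss_total)

    def test_null_q2_nonpositive_on_average(self):
        """Monte-Carlo null calibration: pure-noise X with permuted labels
        must not appear predictive under cross-validation."""
        q2s = [evaluate_fit(*random_problem(s, n=22, p=60), n_ortho=1).q2 for s in range(30)]
        assert np.mean(q2s) <= 0

    def test_q2_at_most_r2_on_synthetic_suite(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = np.array([-1.0, 1.0]).repeat(11)
            X = rng.normal(size=(22, 40)) + 0.8 * y[:, None] * rng.uniform(size=40)
            fit = evaluate_fit(X, y, n_ortho=1)
            assert fit.q2 <= fit.r2y

    def test_fold_coefficient_shape_and_bounds(self):
        X, y = random_problem(12)
        fit = evaluate_fit(X, y, n_ortho=1, n_folds=7)
        assert fit.fold_coefficients.shape == (7, X.shape[1])
        with pytest.raises(ValueError):
            evaluate_fit(X, y, n_folds=1)

    def test_select_n_ortho_returns_small_count(self):
        X, y = random_problem(13)
        k = select_n_ortho(X, y, max_ortho=2)
        assert 0 <= k <= 2


class TestVip:
    def test_mean_square_identities(self):
        X, y = random_problem(20)
        for n_ortho in (0, 1, 2):
            v = compute_vip(fit_oplsda(X, y, n_ortho=n_ortho))
            assert (v.vip_pred**2).mean() == pytest.approx(1.0, abs=1e-10)
            assert (v.vip_total**2).mean() == pytest.approx(1.0, abs=1e-10)
            if n_ortho:
                assert (v.vip_ortho**2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_equal_weights_give_unit_vip(self):
        # y loads identically on every feature -> all VIPpred = 1
        y = np.array([-1.0, 1.0] * 8)
        rng = np.random.default_rng(1)
        X = y[:, None] + rng.normal(scale=1e-9, size=(16, 5))
        v = compute_vip(fit_oplsda(X, y, n_ortho=0))
        assert np.allclose(v.vip_pred, 1.0, atol=1e-3)

    def test_feature_permutation_equivariance(self):
        X, y = random_problem(21)
        perm = np.random.default_rng(2).permutation(X.shape[1])
        v = compute_vip(fit_oplsda(X, y, n_ortho=1))
        vp = compute_vip(fit_oplsda(X[:, perm], y, n_ortho=1))
        assert np.allclose(v.vip_total.to_numpy()[perm], vp.vip_total.to_numpy())


class TestPca:
    def test_rank_one_matrix_single_component(self):
        u = np.arange(1.0, 9.0)[:, None]
        X = u @ np.array([[1.0, 2.0, 3.0]]) + 5
        m = fit_pca(X, 1)
        assert m.explained_ratio[0] == pytest.approx(1.0)

    def test_scores_orthogonal_and_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 4))
        m = fit_pca(X, 4)
        gram = m.scores.T @ m.scores
        assert np.allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)
        assert np.allclose(m.scores @ m.loadings.T + m.mean, X, atol=1e-8)

    def test_components_beyond_rank_rejected(self):
        X = np.outer(np.arange(5.0), np.ones(3))
        with pytest.raises(ValueError):
            fit_pca(X, 2)

    def test_hotelling_flags_gross_outlier(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(30, 2))
        scores[0] = [25.0, 25.0]
        flags = hotelling_outliers(scores)
        assert flags[0] and flags[1:].sum() <= 2
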