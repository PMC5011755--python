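"""PPCA: EM and closed-form fits, projections, reconstruction, likelihood."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from mscancer import (
    LatentScores,
    choose_q_by_cumvar,
    fit_pca,
    fit_ppca_closed_form,
    fit_ppca_em,
    generate_latent_gaussian,
    log_likelihood,
    reconstruct,
    transform,
)


@pytest.fixture
def toy_anisotropic(rng):
    """N=400 samples, d=8, dominant variance along the first two axes."""
    return rng.standard_normal((400, 8)) @ np.diag([4.0, 2.5, 1, 1, 1, 1, 1, 1])


class TestEMFit:
    def test_identical_rows_drive_sigma2_to_zero(self):
        X = np.tile([1.0, 2.0, 3.0, 4.0], (10, 1))
        model = fit_ppca_em(X, 1, seed=0, max_iter=50)
        assert model.sigma2 < 1e-12
        # all L values equal once the degenerate optimum is hit
        assert np.ptp(model.loglik_trace[1:]) <= 1e-6 * abs(model.loglik_trace[-1]) \
            or model.n_iter <= 2

    def test_loglik_trace_non_decreasing(self, toy_anisotropic):
        model = fit_ppca_em(toy_anisotropic, 2, seed=3, tol=1e-9, max_iter=1000)
        diffs = np.diff(model.loglik_trace)
        slack = 1e-8 * np.maximum(1.0, np.abs(model.loglik_trace[:-1]))
        assert np.all(diffs >= -slack)
        assert model.converged

    def test_parameter_recovery_from_generative_model(self):
        S, truth = generate_latent_gaussian(2000, 20, 3, W_norm=2.0,
                                            sigma2=0.5, seed=7)
        model = fit_ppca_em(S, 3, tol=1e-8, max_iter=1000, seed=11)
        assert model.sigma2 == pytest.approx(0.5, rel=0.10)
        angle = np.degrees(subspace_angles(model.W, truth["W"]).max())
        assert angle < 5.0

    def test_dimension_validation(self, rng):
        X = rng.standard_normal((5, 4))
        with pytest.raises(ValueError, match="q"):
            fit_ppca_em(X, 4, seed=0)
        with pytest.raises(ValueError, match="finite"):
            fit_ppca_em(np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]]), 1, seed=0)


class TestClosedForm:
    def test_known_eigenstructure(self, rng):
        # diag(4, 1, 1) covariance at large N: sigma2 -> 1, ||W||^2 -> 3
        X = rng.standard_normal((200000, 3)) * np.sqrt([4.0, 1.0, 1.0])
        model = fit_ppca_closed_form(X, 1)
        assert model.sigma2 == pytest.approx(1.0, rel=0.02)
        assert float((model.W.T @ model.W).item()) == pytest.approx(3.0, rel=0.03)
        direction = np.abs(model.W[:, 0]) / np.linalg.norm(model.W)
        np.testing.assert_allclose(direction, [1, 0, 0], atol=0.05)

    def test_q_dminus1_sigma2_is_smallest_eigenvalue(self, rng):
        X = rng.standard_normal((500, 4))
        model = fit_ppca_closed_form(X, 3)
        lam = np.sort(np.linalg.eigvalsh(np.cov(X.T, bias=True)))
        assert model.sigma2 == pytest.approx(lam[0], rel=1e-8)

    def test_global_optimum_dominates_em(self, toy_anisotropic):
        em = fit_ppca_em(toy_anisotropic, 2, seed=5, tol=1e-9, max_iter=2000)
        cf = fit_ppca_closed_form(toy_anisotropic, 2)
        L_em = log_likelihood(em, toy_anisotropic)
        L_cf = log_likelihood(cf, toy_anisotropic)
        assert L_cf >= L_em - 1e-6 * abs(L_cf)

    @pytest.mark.parametrize("d,q,seed", [(8, 2, 0), (20, 4, 1), (30, 5, 2)])
    def test_em_agrees_with_closed_form_oracle(self, d, q, seed):
        rng = np.random.default_rng(seed)
        scales = np.concatenate([np.linspace(4.0, 2.5, q), np.full(d - q, 0.7)])
        X = rng.standard_normal((300, d)) * scales
        em = fit_ppca_em(X, q, seed=seed + 50, tol=1e-10, max_iter=5000)
        cf = fit_ppca_closed_form(X, q)
        assert em.sigma2 == pytest.approx(cf.sigma2, rel=1e-4)
        assert subspace_angles(em.W, cf.W).max() < 1e-3


class TestTransformReconstruct:
    @pytest.fixture
    def model(self, toy_anisotropic):
        return fit_ppca_closed_form(toy_anisotropic, 2)

    def test_mean_row_maps_to_zero(self, model):
        for mode in ("posterior-mean", "adjoint"):
            z = transform(model, model.mu[None, :], mode=mode).Z
            np.testing.assert_allclose(z, 0.0, atol=1e-10)

    def test_posterior_mean_matches_explicit_solve(self, rng):
        X = rng.standard_normal((40, 5))
        model = fit_ppca_closed_form(X, 2)
        Z = transform(model, X, mode="posterior-mean").Z
        M = model.W.T @ model.W + model.sigma2 * np.eye(2)
        expected = np.linalg.solve(M, model.W.T @ (X - model.mu).T).T
        np.testing.assert_allclose(Z, expected, atol=1e-10)

    def test_modes_coincide_for_orthonormal_w_zero_noise(self):
        W = np.linalg.qr(np.random.default_rng(0).standard_normal((6, 2)))[0]
        from mscancer import PPCAModel
        model = PPCAModel(W=W, mu=np.zeros(6), sigma2=0.0, q=2)
        X = np.random.default_rng(1).standard_normal((10, 6))
        z9 = transform(model, X, mode="adjoint").Z
        zpm = transform(model, X, mode="posterior-mean").Z
        np.testing.assert_allclose(z9, zpm, atol=1e-10)

    def test_zero_scores_reconstruct_to_mean(self, model):
        S = reconstruct(model, LatentScores(Z=np.zeros((3, 2)), mode="adjoint"))
        np.testing.assert_allclose(S, np.tile(model.mu, (3, 1)), atol=1e-12)

    def test_in_span_points_reconstruct_exactly(self, rng):
        # noise-free data lying in mu + span(W): projection returns it unchanged
        W = rng.standard_normal((7, 2))
        mu = rng.standard_normal(7)
        X = rng.standard_normal((30, 2)) @ W.T + mu
        model = fit_ppca_closed_form(X, 2)
        scores = transform(model, X, mode="adjoint")
        np.testing.assert_allclose(reconstruct(model, scores), X, atol=1e-8)

    def test_reconstruction_error_non_increasing_in_q(self, toy_anisotropic):
        errs = []
        for q in (1, 2, 4, 6):
            m = fit_ppca_closed_form(toy_anisotropic, q)
            s = transform(m, toy_anisotropic, mode="adjoint")
            errs.append(np.linalg.norm(toy_anisotropic - reconstruct(m, s)))
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_dimension_mismatch(self, model):
        with pytest.raises(ValueError, match="columns"):
            transform(model, np.zeros((2, 3)))


class TestLogLikelihood:
    def test_gaussian_entropy_rate(self):
        # standard-normal 1-D data under an isotropic model: L/N ~ -(ln 2pi + 1)/2
        rng = np.random.default_rng(42)
        X = rng.standard_normal((10000, 2))
        model = fit_ppca_closed_form(X, 1)
        expected = -0.5 * 2 * (np.log(2 * np.pi) + 1)
        assert log_likelihood(model, X) / 10000 == pytest.approx(expected, rel=0.02)

    def test_additivity_over_duplicated_samples(self, rng):
        X = rng.standard_normal((50, 6))
        model = fit_ppca_closed_form(X, 2)
        L1 = log_likelihood(model, X)
        L2 = log_likelihood(model, np.vstack([X, X]))
        assert L2 == pytest.approx(2 * L1, rel=1e-9)

    def test_stable_form_matches_naive_dxd(self, rng):
        X = rng.standard_normal((100, 30)) * np.linspace(2, 0.5, 30)
        model = fit_ppca_closed_form(X, 4)
        C = model.W @ model.W.T + model.sigma2 * np.eye(30)
        dev = X - model.mu
        U = dev.T @ dev / 100
        sign, logdet = np.linalg.slogdet(C)
        naive = -0.5 * 100 * (30 * np.log(2 * np.pi) + logdet
                              + np.trace(np.linalg.solve(C, U)))
        assert log_likelihood(model, X) == pytest.approx(naive, rel=1e-6)

    def test_zero_noise_with_residual_flags_minus_inf(self, rng):
        from mscancer import PPCAModel
        W = np.array([[1.0], [0.0], [0.0]])
        model = PPCAModel(W=W, mu=np.zeros(3), sigma2=0.0, q=1)
        X = rng.standard_normal((5, 3))
        assert log_likelihood(model, X) == -np.inf


class TestPCA:
    def test_line_data_has_one_component(self):
        t = np.linspace(-1, 1, 50)
        X = np.outer(t, [1.0, 2.0, -1.0])
        model = fit_pca(X, 2)
        assert model.eigenvalues[0] > 0
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)

    def test_components_orthonormal(self, toy_anisotropic):
        model = fit_pca(toy_anisotropic, 4)
        np.testing.assert_allclose(model.components.T @ model.components,
                                   np.eye(4), atol=1e-8)

    def test_ppca_small_noise_limit_spans_pca_subspace(self, rng):
        X = rng.standard_normal((300, 6)) * np.array([5, 3, 0.1, 0.1, 0.1, 0.1])
        pca = fit_pca(X, 2)
        ppca = fit_ppca_closed_form(X, 2)
        assert subspace_angles(pca.components, ppca.W).max() < 1e-3

    def test_gram_route_matches_direct_for_wide_data(self, rng):
        # d >> N: eigenvectors from the Gram/SVD path equal the d x d path
        X = rng.standard_normal((15, 200))
        model = fit_pca(X, 3)
        U = np.cov(X.T, bias=True)
        lam, V = np.linalg.eigh(U)
        lam, V = lam[::-1], V[:, ::-1]
        np.testing.assert_allclose(model.eigenvalues, lam[:3], rtol=1e-8)
        assert subspace_angles(model.components, V[:, :3]).max() < 1e-6


class TestChooseQ:
    @pytest.mark.parametrize("eigs,thr,expected", [
        ((9.0, 1.0), 0.9, 1),
        ((9.0, 1.0), 0.91, 2),
        ((1.0, 1.0, 1.0, 1.0), 0.9999, 4),
        ((5.0, 3.0, 2.0), 1.0, 3),
    ])
    def test_smallest_qualifying_q(self, eigs, thr, expected):
        assert choose_q_by_cumvar(np.array(eigs), thr) == expected

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            choose_q_by_cumvar(np.zeros(3), 0.9)

    def test_increasing_eigenvalues_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            choose_q_by_cumvar(np.array([1.0, 2.0]), 0.9)
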