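"""Probabilistic PCA: closed-form, conditional-Gaussian and optimizer oracles."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from caseus import PPCA, ProfileMatrix, fit_ppca
from caseus.ppca import PPCAError


def _complete_data(rng, n=60, p=8, q=3, noise=0.4):
    W = rng.standard_normal((p, q))
    return rng.standard_normal((n, q)) @ W.T + 2.0 + noise * rng.standard_normal((n, p))


@pytest.fixture(scope="module")
def complete_fit(rng):
    X = _complete_data(rng)
    return X, fit_ppca(X, 3, tol=1e-10)


class TestCompleteDataClosedForm:
    """With no missing entries the ML solution is the eigendecomposition
    closed form: W = U_q (L_q - s^2 I)^(1/2), s^2 = mean of trailing
    eigenvalues of the sample covariance."""

    def _closed_form(self, X, q):
        mu = X.mean(axis=0)
        Xc = X - mu
        S = Xc.T @ Xc / X.shape[0]
        evals, evecs = np.linalg.eigh(S)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        sigma2 = evals[q:].mean()
        W = evecs[:, :q] * np.sqrt(evals[:q] - sigma2)
        return W, mu, sigma2

    def test_loglik_matches_to_1e6(self, complete_fit):
        X, res = complete_fit
        W, mu, s2 = self._closed_form(X, res.q)
        C = W @ W.T + s2 * np.eye(X.shape[1])
        ll = multivariate_normal(mean=mu, cov=C).logpdf(X).sum()
        assert res.loglike == pytest.approx(ll, abs=1e-6)

    def test_subspace_equals_classical_pca(self, complete_fit):
        X, res = complete_fit
        W, _, _ = self._closed_form(X, res.q)
        assert subspace_angles(res.W, W).max() < 1e-6

    def test_sigma2_matches(self, complete_fit):
        X, res = complete_fit
        _, _, s2 = self._closed_form(X, res.q)
        assert res.sigma2 == pytest.approx(s2, rel=1e-6)


class TestTinyMissingInstanceOptimizerOracle:
    def test_em_matches_direct_likelihood_maximization(self):
        """EM on a 6 x 3 matrix with 2 missing cells agrees with a generic
        numerical maximizer of the observed-data likelihood over (W, mu, s2)
        to within 1e-6 in log-likelihood."""
        rng = np.random.default_rng(5)
        X = _complete_data(rng, n=6, p=3, q=1, noise=0.5)
        X[1, 2] = np.nan
        X[4, 0] = np.nan
        res = fit_ppca(X, 1, tol=1e-12, max_iter=5000)

        mask = ~np.isnan(X)

        def negll(theta):
            w = theta[:3].reshape(3, 1)
            mu = theta[3:6]
            s2 = np.exp(theta[6])
            C = w @ w.T + s2 * np.eye(3)
            total = 0.0
            for i in range(X.shape[0]):
                o = mask[i]
                total += multivariate_normal(
                    mean=mu[o], cov=C[np.ix_(o, o)]
                ).logpdf(X[i, o])
            return -total

        # independent starting points: data-derived plus random restarts
        col_mean = np.array([X[mask[:, j], j].mean() for j in range(3)])
        Ximp = np.where(mask, X, col_mean)
        S = np.cov(Ximp, rowvar=False, ddof=0)
        ev, U = np.linalg.eigh(S)
        start0 = np.concatenate([U[:, -1] * np.sqrt(ev[-1]), col_mean, [np.log(ev[:2].mean())]])
        best = np.inf
        starts = [start0] + [start0 + rng.normal(scale=0.5, size=7) for _ in range(6)]
        for s in starts:
            out = minimize(negll, s, method="L-BFGS-B",
                           options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
            best = min(best, out.fun)
        assert res.loglike == pytest.approx(-best, abs=1e-6)


class TestDegenerateCases:
    def test_noiseless_line_recovers_direction_and_zero_noise(self):
        rng = np.random.default_rng(8)
        direction = np.array([1.0, -2.0, 0.5])
        X = np.outer(rng.standard_normal(40), direction) + 1.0
        res = fit_ppca(X, 1, tol=1e-12, max_iter=3000)
        assert res.sigma2 < 1e-8
        assert subspace_angles(res.W, direction[:, None]).max() < 1e-6

    def test_q_out_of_range_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(PPCAError):
            PPCA(X, 4)
        with pytest.raises(PPCAError):
            PPCA(X, 0)

    def test_variable_with_single_observation_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        X[1:, 0] = np.nan
        with pytest.raises(PPCAError, match="fewer than 2"):
            PPCA(X, 1)


class TestEMMonotonicity:
    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_loglik_nondecreasing_under_block_missingness(self, default_dataset):
        from caseus import fit_scaler, transform

        t = transform(fit_scaler(default_dataset), default_dataset)
        res = fit_ppca(t, 5, tol=1e-8, max_iter=300)
        inc = np.diff(res.ll_trace)
        assert inc.min() >= -1e-8 * (1 + abs(res.loglike))


@pytest.fixture(scope="module")
def score_fit(rng):
    X = _complete_data(rng, n=80, p=6, q=2)
    X[::7, 0] = np.nan
    return fit_ppca(X, 2, tol=1e-10), X


@pytest.fixture(scope="module")
def recon_fit(rng):
    X = _complete_data(rng, n=70, p=5, q=2)
    Xm = X.copy()
    Xm[::6, 1] = np.nan
    return fit_ppca(Xm, 2, tol=1e-10), Xm


class TestScores:
    @pytest.fixture()
    def fitted(self, score_fit):
        return score_fit

    def test_sample_at_mu_scores_zero(self, fitted):
        res, _ = fitted
        z = res.scores(res.mu[None, :]).scores
        assert np.allclose(z, 0.0, atol=1e-10)

    def test_fully_missing_sample_scores_at_prior_mean(self, fitted):
        res, _ = fitted
        z = res.scores(np.full((1, 6), np.nan)).scores
        assert np.array_equal(z, np.zeros((1, 2)))

    def test_partial_sample_matches_conditional_gaussian_oracle(self, fitted):
        """Posterior mean from the joint covariance restricted to observed
        coordinates: E[z|x_o] = W_o' C_oo^-1 (x_o - mu_o)."""
        res, X = fitted
        x = X[21].copy()
        x[[1, 4]] = np.nan
        o = ~np.isnan(x)
        C = res.W @ res.W.T + res.sigma2 * np.eye(6)
        expected = res.W[o].T @ np.linalg.solve(C[np.ix_(o, o)], x[o] - res.mu[o])
        got = res.scores(x[None, :]).scores[0]
        assert np.allclose(got, expected, atol=1e-10)

    def test_explained_variance_fractions_descending_in_unit_interval(self, fitted):
        res, _ = fitted
        f = res.explained_variance_fraction
        assert np.all(f[:-1] >= f[1:])
        assert np.all((f >= 0) & (f <= 1))
        assert f.sum() <= 1.0 + 1e-9


class TestReconstruct:
    @pytest.fixture()
    def fitted(self, recon_fit):
        return recon_fit

    def test_complete_input_returned_unchanged(self, fitted):
        res, Xm = fitted
        complete_rows = Xm[~np.isnan(Xm).any(axis=1)]
        out = res.reconstruct(complete_rows)
        assert np.array_equal(out, complete_rows)

    def test_fully_missing_sample_reconstructed_as_mu(self, fitted):
        res, _ = fitted
        out = res.reconstruct(np.full((1, 5), np.nan))
        assert np.allclose(out[0], res.mu, atol=1e-12)

    def test_single_missing_cell_matches_conditional_mean_formula(self, fitted):
        """E[x_m|x_o] = mu_m + C_mo C_oo^-1 (x_o - mu_o) from the 5 x 5 model
        covariance."""
        res, Xm = fitted
        x = Xm[3].copy()
        assert not np.isnan(x).any()
        x[2] = np.nan
        o = ~np.isnan(x)
        C = res.W @ res.W.T + res.sigma2 * np.eye(5)
        expected = res.mu[2] + C[2, o] @ np.linalg.solve(C[np.ix_(o, o)], x[o] - res.mu[o])
        out = res.reconstruct(x[None, :])
        assert out[0, 2] == pytest.approx(expected, abs=1e-10)
        assert np.array_equal(out[0, o], x[o])

    def test_profile_matrix_output_mask_all_observed(self, small_dataset):
        from caseus import fit_scaler, transform

        t = transform(fit_scaler(small_dataset), small_dataset)
        res = fit_ppca(t, 3, tol=1e-8, max_iter=500)
        out = res.reconstruct(t)
        assert out.mask.all()
        m = t.mask
        assert np.allclose(out.values[m], t.values[m])


class TestLoadingsAndRotation:
    def test_loadings_table_one_row_per_variable(self, small_dataset):
        from caseus import fit_scaler, transform

        t = transform(fit_scaler(small_dataset), small_dataset)
        res = fit_ppca(t, 3, tol=1e-8, max_iter=500)
        table = res.loadings_frame()
        assert len(table) == t.n_variables
        assert list(table.columns) == ["variable", "role", "PC1", "PC2"]

    def test_sign_convention_largest_loading_positive(self, complete_fit):
        _, res = complete_fit
        for k in range(res.q):
            j = np.argmax(np.abs(res.W[:, k]))
            assert res.W[j, k] > 0

    def test_rotated_gram_matrix_diagonal_descending(self, complete_fit):
        _, res = complete_fit
        G = res.W.T @ res.W
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8
        d = np.diag(G)
        assert np.all(d[:-1] >= d[1:] - 1e-12)

    def test_construction_consistency_of_loading_signs(self):
        """A variable built to load positively on the leading latent axis gets
        a positive PC1 loading at large n."""
        rng = np.random.default_rng(3)
        n, p = 4000, 6
        W_true = np.zeros((p, 2))
        W_true[:, 0] = [3.0, 1.5, 1.0, 0.5, -0.5, 0.2]
        W_true[:, 1] = [0.0, 0.3, -0.4, 0.8, 0.1, -0.2]
        X = rng.standard_normal((n, 2)) @ W_true.T + 0.3 * rng.standard_normal((n, p))
        res = fit_ppca(X, 2, tol=1e-8)
        # variable 0 dominates PC1 -> its loading is positive by convention
        assert res.W[0, 0] > 0
        # and variable 4, built opposite to it, is negative
        assert res.W[4, 0] < 0


class TestMissingAtRandomRobustness:
    def test_subspace_recovery_degrades_gracefully(self):
        rng = np.random.default_rng(17)
        n, p, q = 300, 20, 3
        W_true = rng.standard_normal((p, q))
        X = rng.standard_normal((n, q)) @ W_true.T + 0.3 * rng.standard_normal((n, p))
        angles = []
        for frac in (0.0, 0.2):
            Xm = X.copy()
            drop = rng.random(X.shape) < frac
            Xm[drop] = np.nan
            res = fit_ppca(Xm, q, tol=1e-8, max_iter=1000)
            angles.append(subspace_angles(res.W, W_true).max())
        assert angles[0] < 0.15
        assert angles[1] < 0.35
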