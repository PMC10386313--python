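"""Probabilistic principal component analysis fitted by EM under missing data.

The model is the standard isotropic Gaussian latent-variable form

    x = W z + mu + eps,      z ~ N(0, I_q),   eps ~ N(0, sigma^2 I_p),

whose marginal is x ~ N(mu, W W' + sigma^2 I). With complete data its maximum
likelihood solution coincides with classical PCA (W spans the leading
principal subspace); with missing entries the observed-data likelihood

    sum_i log N(x_{o_i}; mu_{o_i}, W_{o_i} W_{o_i}' + sigma^2 I)

is maximised by EM, where the E-step computes each sample's latent posterior
given only its observed coordinates and the M-step updates (W, mu) jointly in
closed form followed by sigma^2. Missing cells are afterwards imputed by the
conditional mean E[x_miss | x_obs], which is how the model doubles as an
imputation engine for block-missing fatty-acid profiles.

Rows that are entirely missing carry no likelihood information and are
excluded from fitting, but they can still be scored (at the prior mean) and
reconstructed (at mu).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .core import ProfileMatrix

_LOG2PI = np.log(2.0 * np.pi)
_SIGMA2_FLOOR = 1e-12


class PPCAError(ValueError):
    pass


def _coerce(data, mask) -> tuple[np.ndarray, np.ndarray, list[str] | None, list[str] | None]:
    if isinstance(data, ProfileMatrix):
        return data.values, data.mask, list(data.var_names), list(data.var_roles)
    X = np.asarray(data, dtype=float)
    if mask is None:
        mask = ~np.isnan(X)
    return X, np.asarray(mask, bool), None, None


def _patterns(mask: np.ndarray):
    """Group rows by identical observation pattern (fully-missing excluded)."""
    keep = mask.any(axis=1)
    rows = np.flatnonzero(keep)
    if rows.size == 0:
        return []
    pats, inv = np.unique(mask[rows], axis=0, return_inverse=True)
    return [
        (np.flatnonzero(pats[g]), rows[inv == g])  # (observed cols, sample rows)
        for g in range(pats.shape[0])
    ]


def _observed_loglik(X, groups, W, mu, sigma2) -> float:
    # per-pattern eigendecomposition of C_o = W_o W_o' + sigma2 I; squaring
    # the rotated coordinates before dividing by the eigenvalues stays
    # accurate even as sigma2 -> 0 (the Woodbury form cancels catastrophically
    # there)
    ll = 0.0
    for obs, rows in groups:
        d = obs.size
        Wo = W[obs]
        gam, U = np.linalg.eigh(Wo @ Wo.T)
        lam = np.clip(gam, 0.0, None) + sigma2
        Xc = X[np.ix_(rows, obs)] - mu[obs]
        T = Xc @ U  # (n_g, d) coordinates in the eigenbasis
        quad = np.sum(T * T / lam)
        logdet = np.sum(np.log(lam))
        ll += -0.5 * (rows.size * (d * _LOG2PI + logdet) + quad)
    return ll


class PPCA:
    """Probabilistic PCA model specification.

    Parameters
    ----------
    data : ProfileMatrix or ndarray
        Samples x variables. For a bare array, NaN marks missing entries
        unless an explicit boolean ``mask`` (True = observed) is given.
    n_components : int
        Latent dimension q, with 1 <= q < p.
    """

    def __init__(self, data, n_components: int, mask: np.ndarray | None = None):
        X, m, names, roles = _coerce(data, mask)
        if X.ndim != 2:
            raise PPCAError("data must be 2-D")
        n, p = X.shape
        if not 1 <= n_components < p:
            raise PPCAError(f"need 1 <= n_components < p, got q={n_components}, p={p}")
        per_var = m.sum(axis=0)
        if (per_var < 2).any():
            bad = np.flatnonzero(per_var < 2)
            raise PPCAError(f"variables observed in fewer than 2 samples: {bad.tolist()}")
        self.X = X
        self.mask = m
        self.q = int(n_components)
        self.var_names = names
        self.var_roles = roles

    @classmethod
    def from_profile_matrix(cls, matrix: ProfileMatrix, n_components: int) -> "PPCA":
        return cls(matrix, n_components)

    # ------------------------------------------------------------------
    def _initial(self, init: str, seed):
        X, m, q = self.X, self.mask, self.q
        p = X.shape[1]
        col_mean = np.array([X[m[:, j], j].mean() for j in range(p)])
        if init == "random":
            rng = np.random.default_rng(seed)
            W0 = rng.standard_normal((p, q))
            return W0, col_mean, 1.0
        # deterministic default: eigendecomposition of the mean-imputed
        # sample covariance; for complete data this is already the ML solution
        Ximp = np.where(m, X, col_mean)
        Xc = Ximp - Ximp.mean(axis=0)
        S = (Xc.T @ Xc) / Xc.shape[0]
        evals, evecs = np.linalg.eigh(S)
        order = np.argsort(evals)[::-1]
        evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
        sigma2 = float(np.mean(evals[q:])) if q < p else 1.0
        sigma2 = max(sigma2, _SIGMA2_FLOOR, 1e-12 * max(evals[0], 1.0))
        W0 = evecs[:, :q] * np.sqrt(np.clip(evals[:q] - sigma2, 1e-12, None))
        return W0, col_mean, sigma2

    def fit(
        self,
        tol: float = 1e-8,
        max_iter: int = 2000,
        init: str = "eig",
        seed: int | None = None,
    ) -> "PPCAResults":
        """Run EM until the relative log-likelihood change drops below tol."""
        X, mask, q = self.X, self.mask, self.q
        p = X.shape[1]
        groups = _patterns(mask)
        n_fit = sum(rows.size for _, rows in groups)
        if n_fit == 0:
            raise PPCAError("no rows with observed entries to fit on")
        total_var = float(sum(np.var(X[mask[:, j], j], ddof=0) for j in range(p)))
        # noise floor scaled to the data so that likelihood eigen-noise
        # (~eps * ||W||^2) stays far below sigma^2 even for noiseless input
        sigma2_floor = max(_SIGMA2_FLOOR, 1e-9 * total_var / p)
        n_obs_cells = sum(obs.size * rows.size for obs, rows in groups)
        # per-variable membership signature -> shared normal-equation matrix
        obs_sets = [set(obs.tolist()) for obs, _ in groups]
        sig_of_var: dict[tuple[int, ...], list[int]] = {}
        for j in range(p):
            sig = tuple(g for g in range(len(groups)) if j in obs_sets[g])
            sig_of_var.setdefault(sig, []).append(j)

        W, mu, sigma2 = self._initial(init, seed)
        Iq = np.eye(q)
        ll_trace: list[float] = []
        converged = False
        ll_prev = -np.inf
        for it in range(max_iter):
            # E-step, accumulated as sufficient statistics per pattern
            A_g = []  # (q+1, q+1) second moments of augmented latent [z; 1]
            B = np.zeros((q + 1, p))
            estep = []  # (Ez, Czz) per pattern, reused for the sigma2 update
            for obs, rows in groups:
                Wo = W[obs]
                M = Wo.T @ Wo + sigma2 * Iq
                cf = cho_factor(M, lower=True)
                Xc = X[np.ix_(rows, obs)] - mu[obs]
                Ez = cho_solve(cf, Wo.T @ Xc.T).T  # (n_g, q)
                Czz = sigma2 * cho_solve(cf, Iq)
                n_g = rows.size
                A = np.empty((q + 1, q + 1))
                A[:q, :q] = n_g * Czz + Ez.T @ Ez
                A[:q, q] = Ez.sum(axis=0)
                A[q, :q] = A[:q, q]
                A[q, q] = n_g
                A_g.append(A)
                Zt = np.hstack([Ez, np.ones((n_g, 1))])
                B[:, obs] += Zt.T @ X[np.ix_(rows, obs)]
                estep.append((Ez, Czz, Zt))
            # M-step: joint (W, mu) solve per signature, then sigma2
            Wt = np.zeros((q + 1, p))
            for sig, cols in sig_of_var.items():
                A = sum(A_g[g] for g in sig)
                Wt[:, cols] = np.linalg.solve(A, B[:, cols])
            W_new = Wt[:q].T.copy()
            mu_new = Wt[q].copy()
            ss = 0.0
            for (obs, rows), (Ez, Czz, Zt) in zip(groups, estep):
                fitted = Zt @ Wt[:, obs]
                resid = X[np.ix_(rows, obs)] - fitted
                ss += np.sum(resid * resid)
                Wo_new = W_new[obs]
                ss += rows.size * np.einsum("ij,jk,ik->", Wo_new, Czz, Wo_new)
            W, mu = W_new, mu_new
            sigma2 = max(ss / n_obs_cells, sigma2_floor)
            ll = _observed_loglik(X, groups, W, mu, sigma2)
            ll_trace.append(ll)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (1.0 + abs(ll)):
                converged = True
                break
            ll_prev = ll
        if not converged:
            last = (
                abs(ll_trace[-1] - ll_trace[-2]) / (1.0 + abs(ll_trace[-1]))
                if len(ll_trace) > 1
                else np.inf
            )
            warnings.warn(
                f"PPCA EM did not converge in {max_iter} iterations "
                f"(last rel. change {last:.2e})",
                RuntimeWarning,
                stacklevel=2,
            )
        W, order_flip = _rotate_to_principal_axes(W)
        return PPCAResults(
            W=W,
            mu=mu,
            sigma2=float(sigma2),
            q=q,
            ll_trace=np.asarray(ll_trace),
            converged=converged,
            n_iter=len(ll_trace),
            n_samples_fit=n_fit,
            total_variance=total_var,
            init=init,
            seed=seed,
            var_names=self.var_names,
            var_roles=self.var_roles,
        )


def _rotate_to_principal_axes(W: np.ndarray):
    """Rotate W so W'W is diagonal descending; largest-|loading| entry positive.

    The marginal covariance W W' + sigma^2 I is invariant to right-multiplying
    W by an orthogonal matrix, so this is a pure reparameterisation.
    """
    U, s, _ = np.linalg.svd(W, full_matrices=False)
    Wr = U * s
    flips = np.ones(W.shape[1])
    for k in range(W.shape[1]):
        jmax = np.argmax(np.abs(Wr[:, k]))
        if Wr[jmax, k] < 0:
            Wr[:, k] = -Wr[:, k]
            flips[k] = -1.0
    return Wr, flips


@dataclass
class ScoreSet:
    """Posterior-mean latent coordinates plus per-component explained variance."""

    scores: np.ndarray
    explained_variance_fraction: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]


@dataclass
class PPCAResults:
    """Fitted probabilistic PCA parameters and diagnostics.

    ``W`` is rotated so that ``W.T @ W`` is diagonal with descending entries
    (ordered principal axes) and each column's largest-magnitude loading is
    positive.
    """

    W: np.ndarray
    mu: np.ndarray
    sigma2: float
    q: int
    ll_trace: np.ndarray
    converged: bool
    n_iter: int
    n_samples_fit: int
    total_variance: float
    init: str = "eig"
    seed: int | None = None
    var_names: list[str] | None = None
    var_roles: list[str] | None = None

    @property
    def loglike(self) -> float:
        return float(self.ll_trace[-1])

    @property
    def component_variances(self) -> np.ndarray:
        """Eigenvalues of W W' (squared column norms of the rotated W)."""
        return np.sum(self.W**2, axis=0)

    @property
    def explained_variance_fraction(self) -> np.ndarray:
        """Per-component share of the calibration observed-data total variance."""
        if self.total_variance <= 0:
            return np.zeros(self.q)
        return self.component_variances / self.total_variance

    # ------------------------------------------------------------------
    def _posterior(self, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Posterior mean of z per row given that row's observed coordinates."""
        n = X.shape[0]
        Ez = np.zeros((n, self.q))
        Iq = np.eye(self.q)
        for obs, rows in _patterns(mask):
            Wo = self.W[obs]
            M = Wo.T @ Wo + self.sigma2 * Iq
            cf = cho_factor(M, lower=True)
            Xc = X[np.ix_(rows, obs)] - self.mu[obs]
            Ez[rows] = cho_solve(cf, Wo.T @ Xc.T).T
        return Ez  # fully-missing rows stay at the prior mean 0

    def scores(self, data, mask: np.ndarray | None = None) -> ScoreSet:
        """Posterior-mean latent scores for new (possibly incomplete) samples."""
        X, m, names, _ = _coerce(data, mask)
        self._check_vars(names, X.shape[1])
        return ScoreSet(
            scores=self._posterior(X, m),
            explained_variance_fraction=self.explained_variance_fraction,
        )

    def reconstruct(self, data, mask: np.ndarray | None = None):
        """Replace missing cells by E[x_miss | x_obs]; observed cells kept.

        Returns a ProfileMatrix (all-observed mask) when given one, else an
        ndarray.
        """
        X, m, names, _ = _coerce(data, mask)
        self._check_vars(names, X.shape[1])
        Ez = self._posterior(X, m)
        Xhat = self.mu[None, :] + Ez @ self.W.T
        filled = np.where(m, X, Xhat)
        if isinstance(data, ProfileMatrix):
            return data.with_values_mask(filled, np.ones_like(m))
        return filled

    def _check_vars(self, names, p: int) -> None:
        if p != self.W.shape[0]:
            raise PPCAError(f"variable count {p} != fitted model's {self.W.shape[0]}")
        if names is not None and self.var_names is not None and names != self.var_names:
            raise PPCAError("variable names do not match the fitted model")

    def loadings_frame(
        self, var_names=None, var_roles=None, n_axes: int = 2
    ) -> pd.DataFrame:
        """Per-variable loading table on the first axes, for biplot export."""
        p = self.W.shape[0]
        names = list(var_names) if var_names is not None else (self.var_names or [f"V{j:03d}" for j in range(p)])
        roles = list(var_roles) if var_roles is not None else (self.var_roles or ["?"] * p)
        n_axes = min(n_axes, self.q)
        out = pd.DataFrame({"variable": names, "role": roles})
        for k in range(n_axes):
            out[f"PC{k + 1}"] = self.W[:, k]
        return out

    def summary(self) -> str:
        evf = self.explained_variance_fraction
        lines = [
            "Probabilistic PCA (EM over observed entries)",
            "=" * 48,
            f"components (q)      : {self.q}",
            f"samples fitted      : {self.n_samples_fit}",
            f"noise variance s^2  : {self.sigma2:.6g}",
            f"log-likelihood      : {self.loglike:.6f}",
            f"EM iterations       : {self.n_iter} (converged={self.converged})",
            "component variance / explained fraction:",
        ]
        for k, (v, f) in enumerate(zip(self.component_variances, evf), start=1):
            lines.append(f"  PC{k:<2d}  {v:10.4f}   {100 * f:6.2f}%")
        return "\n".join(lines)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "W": self.W.tolist(),
            "mu": self.mu.tolist(),
            "sigma2": self.sigma2,
            "q": self.q,
            "ll_trace": self.ll_trace.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_samples_fit": self.n_samples_fit,
            "total_variance": self.total_variance,
            "init": self.init,
            "seed": self.seed,
            "var_names": self.var_names,
            "var_roles": self.var_roles,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PPCAResults":
        d = dict(d)
        d["W"] = np.asarray(d["W"], float)
        d["mu"] = np.asarray(d["mu"], float)
        d["ll_trace"] = np.asarray(d["ll_trace"], float)
        return cls(**d)


def fit_ppca(
    matrix,
    n_components: int,
    tol: float = 1e-8,
    max_iter: int = 2000,
    init: str = "eig",
    seed: int | None = None,
    mask: np.ndarray | None = None,
) -> PPCAResults:
    """Convenience wrapper: build a :class:`PPCA` model and fit it."""
    return PPCA(matrix, n_components, mask=mask).fit(
        tol=tol, max_iter=max_iter, init=init, seed=seed
    )
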