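"""Probabilistic PCA (PPCA) and classical PCA.

PPCA is the Gaussian latent-variable model

    S = W x + mu + eps,     x ~ N(0, I_q),  eps ~ N(0, sigma^2 I_d),

so the observations are marginally N(mu, C) with C = W W^T + sigma^2 I.
Unlike classical PCA it carries an explicit noise variance sigma^2,
estimated from the variance of the d - q discarded directions, and a
proper log-likelihood

    L = -(N/2) [ d ln 2pi + ln|C| + tr(C^{-1} U) ],

with U the sample covariance.  Maximum-likelihood estimates of (W, sigma^2)
are obtained either by EM on the covariance form (:func:`fit_ppca_em`) or
in closed form from the eigendecomposition of U (:func:`fit_ppca_closed_form`),
which attains the global maximum of L and serves as the oracle for the EM
route.

All covariance-level algebra is routed through the N x N Gram matrix when
d >> N, so a 15,000-dimensional fit on a few hundred samples runs in
seconds with O(Nd + dq) memory; C is never materialized (determinant lemma
and Woodbury identity give ln|C| and tr(C^{-1}U) through the q x q matrix
M = W^T W + sigma^2 I).

Two projection modes are provided.  ``"posterior-mean"`` (default) is the
posterior expectation E[x|S] = M^{-1} W^T (S - mu).  ``"adjoint"`` is the
plain adjoint projection W^T (S - mu), i.e. the posterior mean without the
M^{-1} factor; some published pipelines use this literal form, so it is
kept available and recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PPCAModel",
    "PCAModel",
    "LatentScores",
    "fit_ppca_em",
    "fit_ppca_closed_form",
    "transform",
    "reconstruct",
    "log_likelihood",
    "fit_pca",
    "choose_q_by_cumvar",
]

#: slack allowed when asserting EM log-likelihood monotonicity
_MONOTONE_SLACK = 1e-8


@dataclass
class PPCAModel:
    """Fitted PPCA parameters plus fit diagnostics."""

    W: np.ndarray               # d x q factor loading matrix
    mu: np.ndarray              # d-vector mean
    sigma2: float               # isotropic noise variance, >= 0
    q: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = float(self.sigma2)
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        d, q = self.W.shape
        if q != self.q or self.mu.size != d:
            raise ValueError("inconsistent W / mu / q dimensions")
        if q >= d:
            raise ValueError("latent dimension q must be < d")

    @property
    def d(self) -> int:
        return int(self.W.shape[0])

    def M(self) -> np.ndarray:
        """q x q matrix M = W^T W + sigma^2 I (derived, not stored)."""
        return self.W.T @ self.W + self.sigma2 * np.eye(self.q)


@dataclass
class PCAModel:
    """Classical PCA: orthonormal components and explained variances."""

    components: np.ndarray      # d x q, orthonormal columns
    mu: np.ndarray
    eigenvalues: np.ndarray     # q-vector, non-increasing, >= 0

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)

    @property
    def q(self) -> int:
        return int(self.components.shape[1])

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mu) @ self.components


@dataclass
class LatentScores:
    """N x q latent coordinates plus the projection mode that produced them."""

    Z: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.mode not in ("posterior-mean", "adjoint"):
            raise ValueError(f"unknown projection mode {self.mode!r}")


def _validate_X(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


class _CovOps:
    """Products with the sample covariance U = (1/N) Xc^T Xc without forming U.

    For d <= N the d x d covariance is formed once; for d > N everything is
    computed through the centered data matrix (Gram route).
    """

    def __init__(self, X: np.ndarray):
        X = _validate_X(X)
        self.N, self.d = X.shape
        self.mu = X.mean(axis=0)
        self.Xc = X - self.mu
        self.trace = float(np.sum(self.Xc ** 2)) / self.N
        self._U = (self.Xc.T @ self.Xc) / self.N if self.d <= self.N else None

    def dot(self, W: np.ndarray) -> np.ndarray:
        """U @ W, O(Ndq)."""
        if self._U is not None:
            return self._U @ W
        return self.Xc.T @ (self.Xc @ W) / self.N

    def quad(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        """A^T U B as a small matrix."""
        if self._U is not None:
            return A.T @ self._U @ B
        return (self.Xc @ A).T @ (self.Xc @ B) / self.N

    def eig_top(self, q: int) -> tuple[np.ndarray, np.ndarray]:
        """Top-q eigenvalues/eigenvectors of U (SVD/Gram route for d > N)."""
        # economical SVD of the centered data gives both routes in one call
        _, s, Vt = np.linalg.svd(self.Xc, full_matrices=False)
        lam = s ** 2 / self.N
        return lam[:q], Vt[:q].T


def _loglik_from_parts(N: int, d: int, q: int, sigma2: float,
                       M: np.ndarray, WtUW: np.ndarray, trU: float) -> float:
    """L = -(N/2)[d ln 2pi + ln|C| + tr(C^-1 U)] via the q x q form.

    ln|C| = (d-q) ln sigma2 + ln|M|;
    tr(C^-1 U) = (tr U - tr(M^-1 W^T U W)) / sigma2.
    """
    if sigma2 <= 0:
        return -np.inf
    sign, logdetM = np.linalg.slogdet(M)
    if sign <= 0:
        return -np.inf
    logdetC = (d - q) * np.log(sigma2) + logdetM
    trCinvU = (trU - float(np.trace(np.linalg.solve(M, WtUW)))) / sigma2
    return -0.5 * N * (d * np.log(2.0 * np.pi) + logdetC + trCinvU)


def fit_ppca_em(X: np.ndarray, q: int, *, tol: float = 1e-7,
                max_iter: int = 500, seed: int | np.random.Generator = 0) -> PPCAModel:
    """Fit PPCA by EM on the covariance form.

    The covariance-form updates (with U the sample covariance and
    M = W^T W + sigma^2 I) are

        W_new      = U W (sigma^2 I + M^{-1} W^T U W)^{-1}
        sigma2_new = (1/d) tr(U - U W M^{-1} W_new^T)

    iterated from a seeded random Gaussian W until the relative change of
    the log-likelihood L falls below ``tol`` or ``max_iter`` is reached.
    The per-iteration L values are recorded in ``loglik_trace`` and are
    non-decreasing (EM monotonicity).

    Parameters
    ----------
    X : (N, d) array
        Observations, one sample per row.
    q : int
        Latent dimension, 1 <= q < min(N, d).
    tol : float
        Relative log-likelihood convergence tolerance.
    max_iter : int
        Iteration cap.
    seed : int or Generator
        Seed for the random initialization of W (required for
        reproducibility; recorded nowhere else).
    """
    X = _validate_X(X)
    N, d = X.shape
    if N < 2:
        raise ValueError("need at least 2 samples")
    if not 1 <= q < min(N, d):
        raise ValueError(f"q must satisfy 1 <= q < min(N, d) = {min(N, d)}")
    rng = np.random.default_rng(seed)
    cov = _CovOps(X)

    # seeded standard-normal init scaled to the data's overall std dev
    scale = np.sqrt(max(cov.trace / d, np.finfo(float).tiny))
    W = rng.standard_normal((d, q)) * scale
    sigma2 = max(cov.trace / d, np.finfo(float).tiny)

    trace: list[float] = []
    converged = False
    # relative floor keeps sigma2 away from exact zero, where the
    # likelihood is unbounded and the q-form algebra loses all precision
    eps = max(cov.trace / d * 1e-12, np.finfo(float).tiny)
    for _ in range(max_iter):
        M = W.T @ W + sigma2 * np.eye(q)
        UW = cov.dot(W)                     # d x q
        WtUW = W.T @ UW                     # q x q
        L = _loglik_from_parts(N, d, q, sigma2, M, WtUW, cov.trace)
        if trace and L < trace[-1] - _MONOTONE_SLACK * max(1.0, abs(trace[-1])):
            raise RuntimeError(
                f"EM log-likelihood decreased ({trace[-1]:.10g} -> {L:.10g}); "
                "internal-consistency failure"
            )
        # update
        inner = sigma2 * np.eye(q) + np.linalg.solve(M, WtUW)
        W_new = np.linalg.solve(inner.T, UW.T).T    # U W inner^{-1}
        # tr(U W M^{-1} W_new^T) = tr(M^{-1} W^T U W_new^{T->}): use solve
        tr_red = float(np.trace(np.linalg.solve(M, UW.T @ W_new)))
        sigma2_new = max((cov.trace - tr_red) / d, eps)
        stop = bool(trace) and abs(L - trace[-1]) <= tol * max(1.0, abs(trace[-1]))
        trace.append(L)
        W, sigma2 = W_new, sigma2_new
        if stop:
            converged = True
            break

    return PPCAModel(W=W, mu=cov.mu, sigma2=sigma2, q=q,
                     loglik_trace=np.asarray(trace), n_iter=len(trace),
                     converged=converged)


def fit_ppca_closed_form(X: np.ndarray, q: int) -> PPCAModel:
    """Maximum-likelihood PPCA via the eigendecomposition of the covariance.

    sigma^2 is the mean of the d - q smallest covariance eigenvalues and
    W = U_q (Lambda_q - sigma^2 I)^{1/2} with U_q, Lambda_q the top-q
    eigenvectors/values.  This attains the global maximum of the PPCA
    log-likelihood and is the independent oracle for :func:`fit_ppca_em`.
    """
    X = _validate_X(X)
    N, d = X.shape
    if N < 2:
        raise ValueError("need at least 2 samples")
    if not 1 <= q < min(N, d):
        raise ValueError(f"q must satisfy 1 <= q < min(N, d) = {min(N, d)}")
    cov = _CovOps(X)
    lam, Uq = cov.eig_top(q)
    # eigenvalues beyond rank(Xc) are zero; the residual mean uses the trace
    sigma2 = max((cov.trace - float(np.sum(lam))) / (d - q), 0.0)
    W = Uq * np.sqrt(np.maximum(lam - sigma2, 0.0))
    M = W.T @ W + sigma2 * np.eye(q)
    WtUW = cov.quad(W, W)
    L = _loglik_from_parts(N, d, q, sigma2, M, WtUW, cov.trace)
    return PPCAModel(W=W, mu=cov.mu, sigma2=sigma2, q=q,
                     loglik_trace=np.asarray([L]), n_iter=1, converged=True)


def transform(model: PPCAModel, X: np.ndarray, mode: str = "posterior-mean") -> LatentScores:
    """Project observations into the latent space.

    ``"posterior-mean"``: z = M^{-1} W^T (S - mu), the posterior
    expectation E[x|S].  ``"adjoint"``: z = W^T (S - mu), the same
    projection without the M^{-1} factor.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.d:
        raise ValueError(f"X has {X.shape[1]} columns, model expects {model.d}")
    Wt_dev = (X - model.mu) @ model.W           # N x q
    if mode == "adjoint":
        Z = Wt_dev
    elif mode == "posterior-mean":
        Z = np.linalg.solve(model.M(), Wt_dev.T).T
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    return LatentScores(Z=Z, mode=mode)


def reconstruct(model: PPCAModel, scores: LatentScores) -> np.ndarray:
    """Map latent scores back to observation space.

    S_hat = W (W^T W)^{-1} z + mu.  For ``"adjoint"`` scores this is the
    orthogonal projection of S onto mu + span(W).
    """
    Z = scores.Z
    if Z.shape[1] != model.q:
        raise ValueError(f"scores have {Z.shape[1]} columns, model expects {model.q}")
    G = model.W.T @ model.W
    rank = int(np.linalg.matrix_rank(G))
    if rank < model.q:
        raise np.linalg.LinAlgError(
            f"W^T W is rank-deficient (effective rank {rank} < q = {model.q})"
        )
    return Z @ np.linalg.solve(G, model.W.T) + model.mu


def log_likelihood(model: PPCAModel, X: np.ndarray) -> float:
    """PPCA log-likelihood of X under the model, evaluated stably.

    Uses the determinant lemma and Woodbury identity through the q x q
    matrix M; the d x d covariance C is never materialized.  Returns
    ``-inf`` (a flag, not a crash) when sigma^2 = 0 and residual variance
    remains outside span(W).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.d:
        raise ValueError(f"X has {X.shape[1]} columns, model expects {model.d}")
    N, d = X.shape
    dev = X - model.mu
    trU = float(np.sum(dev ** 2)) / N
    WtUW = (dev @ model.W).T @ (dev @ model.W) / N
    return _loglik_from_parts(N, d, model.q, model.sigma2, model.M(), WtUW, trU)


def fit_pca(X: np.ndarray, q: int) -> PCAModel:
    """Classical PCA via SVD of the centered data (Gram route for d >> N)."""
    X = _validate_X(X)
    N, d = X.shape
    if N < 2:
        raise ValueError("need at least 2 samples")
    if not 1 <= q <= min(N - 1, d):
        raise ValueError(f"q must satisfy 1 <= q <= min(N-1, d) = {min(N - 1, d)}")
    cov = _CovOps(X)
    lam, Uq = cov.eig_top(q)
    return PCAModel(components=Uq, mu=cov.mu, eigenvalues=lam)


def pca_eigenvalues(X: np.ndarray) -> np.ndarray:
    """All sample-covariance eigenvalues (at most min(N-1, d) nonzero)."""
    cov = _CovOps(X)
    lam, _ = cov.eig_top(min(cov.N, cov.d))
    return lam


def choose_q_by_cumvar(eigenvalues: np.ndarray, threshold: float = 0.9999) -> int:
    """Smallest q whose cumulative variance fraction reaches ``threshold``."""
    lam = np.asarray(eigenvalues, dtype=float)
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if np.any(lam < -1e-12 * max(1.0, float(np.max(lam, initial=0.0)))):
        raise ValueError("eigenvalues must be non-negative")
    if np.any(np.diff(lam) > 1e-12 * max(1.0, float(np.max(lam, initial=0.0)))):
        raise ValueError("eigenvalues must be non-increasing")
    total = float(np.sum(lam))
    if total <= 0:
        raise ValueError("all eigenvalues are zero")
    frac = np.cumsum(lam) / total
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)
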