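"""Kronecker-structured Brownian-motion likelihood and GLS correlation.

For p traits observed on n species related by a tree with covariance C, the
random-walk (Brownian) model says the stacked trait vector is multivariate
normal with mean (alpha_1 1, ..., alpha_p 1) and covariance Sigma (x) C_lambda,
where Sigma is the p x p evolutionary rate matrix (variances sigma_k^2, and
for p = 2 an evolutionary correlation rho) and C_lambda is C with its
off-diagonal entries scaled by Pagel's lambda.  The Kronecker structure lets
the 2n-dimensional density be evaluated from a single n x n Cholesky factor:

    log L = -1/2 [ n p log 2 pi + p log|C| + n log|Sigma|
                   + tr(Sigma^-1 X' C^-1 X) ]

with X the n x p matrix of residuals from the ancestral means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["BMParams", "bm_loglik", "bm_bivariate_loglik", "gls_correlation"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class BMParams:
    """Parameters of the (bivariate) Brownian trait model."""

    ancestral_mean: tuple[float, ...]  # alpha per trait
    rate: tuple[float, ...]  # sigma^2 per trait
    rho: float = 0.0  # evolutionary correlation, (-1, 1)
    lam: float = 1.0  # Pagel's lambda, [0, 1]

    def __post_init__(self) -> None:
        if len(self.ancestral_mean) != len(self.rate):
            raise ValueError("ancestral_mean and rate must have equal length")
        if any(s <= 0 for s in self.rate):
            raise ValueError("rates sigma^2 must be positive")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (-1, 1)")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")

    @property
    def n_traits(self) -> int:
        return len(self.ancestral_mean)

    def sigma_matrix(self) -> np.ndarray:
        s = np.sqrt(np.asarray(self.rate))
        if self.n_traits == 1:
            return np.array([[self.rate[0]]])
        S = np.diag(np.asarray(self.rate, dtype=float))
        S[0, 1] = S[1, 0] = self.rho * s[0] * s[1]
        return S


def _chol(C: np.ndarray, jitter_scale: float = 1e-8):
    """Cholesky with a small diagonal jitter retry for near-singular C.

    Zero-length branches (polytomy ties) can make C_lambda exactly singular
    at lambda = 1; the jitter is 1e-8 x tree depth, far below any biological
    signal.
    """
    try:
        return linalg.cholesky(C, lower=True, check_finite=False)
    except linalg.LinAlgError:
        depth = float(np.max(np.diag(C)))
        bumped = C + np.eye(C.shape[0]) * (jitter_scale * max(depth, 1.0))
        try:
            return linalg.cholesky(bumped, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(
                "phylogenetic covariance is singular even after jitter; "
                "check for duplicated tips or an all-zero tree"
            ) from exc


def bm_loglik(traits: np.ndarray, params: BMParams, C_lambda: np.ndarray) -> float:
    """Log-likelihood of an n x p trait matrix under Sigma (x) C_lambda.

    ``C_lambda`` is the already-lambda-scaled n x n species covariance.  The
    2n x 2n Kronecker product is never materialised.
    """
    X = np.atleast_2d(np.asarray(traits, dtype=float))
    if X.ndim == 1 or X.shape[1] != params.n_traits:
        X = X.reshape(-1, params.n_traits)
    n, p = X.shape
    if C_lambda.shape != (n, n):
        raise ValueError(f"covariance is {C_lambda.shape}, traits have n={n}")

    L = _chol(C_lambda)
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(L))))
    R = X - np.asarray(params.ancestral_mean)[None, :]
    Z = linalg.solve_triangular(L, R, lower=True, check_finite=False)
    M = Z.T @ Z  # = R' C^-1 R, p x p

    S = params.sigma_matrix()
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise linalg.LinAlgError("rate matrix Sigma is not positive definite")
    quad = float(np.trace(np.linalg.solve(S, M)))
    return -0.5 * (n * p * _LOG_2PI + p * logdet_C + n * logdet_S + quad)


def bm_bivariate_loglik(
    traits: np.ndarray, params: BMParams, C_lambda: np.ndarray
) -> float:
    """Bivariate special case of :func:`bm_loglik` (p must be 2)."""
    if params.n_traits != 2:
        raise ValueError("bm_bivariate_loglik requires exactly 2 traits")
    return bm_loglik(traits, params, C_lambda)


def gls_correlation(traits: np.ndarray, C_lambda: np.ndarray) -> float:
    """Maximum-likelihood evolutionary correlation at fixed lambda.

    Generalised-least-squares estimate: ancestral means are the GLS means,
    and rho is the correlation of the phylogenetically whitened residuals.
    With C = I this reduces to the ordinary Pearson correlation.
    """
    X = np.asarray(traits, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("traits must be an n x 2 matrix")
    n = X.shape[0]
    L = _chol(C_lambda)
    ones = np.ones((n, 1))
    Zx = linalg.solve_triangular(L, X, lower=True, check_finite=False)
    Z1 = linalg.solve_triangular(L, ones, lower=True, check_finite=False)
    denom = float((Z1.T @ Z1)[0, 0])
    alpha = (Z1.T @ Zx).ravel() / denom  # GLS ancestral means
    R = Zx - Z1 @ alpha[None, :]
    cross = R.T @ R
    d = np.sqrt(np.diag(cross))
    if np.any(d == 0):
        raise ValueError("a trait has zero phylogenetic variance")
    return float(cross[0, 1] / (d[0] * d[1]))
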