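"""Hidden expression factors (PEER-style) for TWAS covariates.

Latent confounders are estimated from the standardized expression matrix by
Bayesian factor analysis with automatic relevance determination (ARD):
an EM iteration on the probabilistic-PCA model whose loading columns carry
ARD precision priors, so superfluous factors shrink toward zero.  The
factor count is fixed (10 by default, matching common practice for a few
hundred lines); a plain PCA fallback is available by configuration and is
used automatically if the EM fails to converge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class HiddenFactors:
    scores: pd.DataFrame  # lines x factors, column-standardized
    method: str  # "ard" or "pca"
    n_iter: int


def _standardize(E: np.ndarray) -> np.ndarray:
    mu = E.mean(axis=0)
    sd = E.std(axis=0)
    sd[sd == 0] = 1.0
    return (E - mu) / sd


def _pca_scores(X: np.ndarray, k: int) -> np.ndarray:
    from sklearn.decomposition import PCA

    return PCA(n_components=k, svd_solver="randomized", random_state=0).fit_transform(X)


def hidden_factors(
    E: pd.DataFrame,
    n_factors: int = 10,
    method: str = "ard",
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> HiddenFactors:
    """Estimate hidden factors from a lines x genes abundance matrix.

    The matrix is gene-standardized first.  Deterministic: EM is
    initialized from the PCA solution (``seed`` is accepted for interface
    stability; no randomness is consumed).
    """
    n, p = E.shape
    if n_factors >= n:
        raise ValueError("n_factors must be smaller than the number of lines")
    if n_factors == 0:
        return HiddenFactors(
            scores=pd.DataFrame(index=E.index), method=method, n_iter=0
        )
    X = _standardize(E.to_numpy(float))
    if method == "pca":
        Z = _pca_scores(X, n_factors)
        return _finish(Z, E.index, "pca", 0)
    if method != "ard":
        raise ValueError(f"unknown factor method {method!r}")

    k = n_factors
    # EM for PPCA with ARD priors on loading columns (deterministic init).
    W = np.linalg.svd(X, full_matrices=False)[2][:k].T  # (p, k)
    W = W * X.std()
    sigma2 = 1.0
    alpha = np.ones(k)
    XtX_diag_sum = float(np.sum(X * X))
    ll_prev = -np.inf
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        M = W.T @ W + sigma2 * np.eye(k)
        Minv = np.linalg.inv(M)
        EZ = X @ W @ Minv  # (n, k)
        EZZ = n * sigma2 * Minv + EZ.T @ EZ
        W = np.linalg.solve(
            (EZZ + sigma2 * np.diag(alpha)).T, (X.T @ EZ).T
        ).T
        alpha = p / np.maximum(np.einsum("ij,ij->j", W, W), 1e-8)
        sigma2 = (
            XtX_diag_sum
            - 2.0 * float(np.einsum("ij,ij->", X @ W, EZ))
            + float(np.einsum("ij,ji->", EZZ, W.T @ W))
        ) / (n * p)
        sigma2 = max(sigma2, 1e-10)
        ll = -0.5 * n * p * np.log(sigma2)  # monotone surrogate
        if abs(ll - ll_prev) < tol * (abs(ll_prev) + 1.0):
            converged = True
            break
        ll_prev = ll
    if not converged and it >= max_iter:
        warnings.warn("ARD factor EM did not converge; falling back to PCA")
        return _finish(_pca_scores(X, k), E.index, "pca", it)
    M = W.T @ W + sigma2 * np.eye(k)
    Z = X @ W @ np.linalg.inv(M)
    return _finish(Z, E.index, "ard", it)


def _finish(Z: np.ndarray, index, method: str, n_iter: int) -> HiddenFactors:
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Z - Z.mean(axis=0)) / sd
    scores = pd.DataFrame(
        Z, index=index, columns=[f"factor{i+1}" for i in range(Z.shape[1])]
    )
    return HiddenFactors(scores=scores, method=method, n_iter=n_iter)
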