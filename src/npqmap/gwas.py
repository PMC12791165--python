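"""Genotype preparation and Q+K linear mixed-model association.

The association model per SNP is y = W a + x b + u + e with u ~ N(0,
sigma_g^2 K) for a centered cross-product kinship K and covariates W
(intercept + genotype principal components, the count chosen by BIC).  The
variance ratio is profiled by 1-D REML on the eigendecomposition of K under
the null (no-SNP) model; each SNP is then tested by an exact F (Wald) test
in the rotated regression, which collapses to ordinary least squares when
K = I.  Multivariate (combined-trait) scans rotate each trait separately
and combine per-trait Wald z-scores through the null trait-residual
correlation matrix into a chi-square statistic; this
fixed-variance-component approximation is calibrated on null simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------- filtering

def filter_mac(G: np.ndarray, variants: pd.DataFrame, mac_min: int = 20):
    """Drop SNPs with minor allele count below ``mac_min``."""
    alt = G.sum(axis=0)
    mac = np.minimum(alt, 2 * G.shape[0] - alt)
    keep = mac >= mac_min
    if not keep.any():
        raise ValueError("all SNPs removed by the MAC filter")
    return G[:, keep], variants.loc[keep].reset_index(drop=True)


def _r2_matrix(G: np.ndarray) -> np.ndarray:
    Gc = G - G.mean(axis=0)
    sd = Gc.std(axis=0)
    sd[sd == 0] = np.inf
    C = (Gc / sd).T @ (Gc / sd) / G.shape[0]
    return C**2


def ld_prune(
    G: np.ndarray,
    variants: pd.DataFrame,
    window: int = 50,
    step: int = 10,
    r2_max: float = 0.9,
):
    """Greedy windowed LD pruning (plink --indep-pairwise semantics).

    Within each 50-SNP window (advanced by 10), while any remaining pair
    has r^2 > ``r2_max`` the member with the smaller MAF is removed (the
    later SNP on ties).
    """
    m = G.shape[1]
    if m < 2:
        raise ValueError("need at least 2 SNPs to prune")
    alt = G.sum(axis=0)
    maf = np.minimum(alt, 2 * G.shape[0] - alt) / (2 * G.shape[0])
    keep = np.ones(m, dtype=bool)
    start = 0
    while True:
        idx = np.arange(start, min(start + window, m))
        idx = idx[keep[idx]]
        if idx.size >= 2:
            r2 = _r2_matrix(G[:, idx])
            np.fill_diagonal(r2, 0.0)
            while True:
                i, j = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[i, j] <= r2_max:
                    break
                # drop the smaller-MAF member; later position on ties
                gi, gj = idx[i], idx[j]
                drop = (
                    i
                    if maf[gi] < maf[gj]
                    else (j if maf[gj] < maf[gi] else max(i, j))
                )
                keep[idx[drop]] = False
                r2[drop, :] = 0.0
                r2[:, drop] = 0.0
        if start + window >= m:
            break
        start += step
    return G[:, keep], variants.loc[keep].reset_index(drop=True)


# ----------------------------------------------------- kinship / covariates

def kinship(G: np.ndarray) -> np.ndarray:
    """Centered cross-product kinship, normalized to mean diagonal 1."""
    Gc = G - G.mean(axis=0)
    var = Gc.var(axis=0)
    if (var == 0).any():
        warnings.warn(f"ignoring {(var == 0).sum()} zero-variance SNPs in kinship")
        Gc = Gc[:, var > 0]
    K = Gc @ Gc.T
    K /= np.trace(K) / K.shape[0]
    return K


def genotype_pcs(G: np.ndarray, n_pcs: int = 5) -> np.ndarray:
    """Principal components of the centered dosage matrix."""
    from sklearn.decomposition import PCA

    n = min(n_pcs, min(G.shape) - 1)
    return PCA(n_components=n, svd_solver="randomized", random_state=0).fit_transform(
        G - G.mean(axis=0)
    )


def select_pcs(y: np.ndarray, PCs: np.ndarray, k_max: int = 5) -> int:
    """Number of leading PCs minimizing BIC of the null covariate model."""
    n = y.size
    best_k, best_bic = 0, np.inf
    for k in range(0, min(k_max, PCs.shape[1]) + 1):
        X = np.column_stack([np.ones(n), PCs[:, :k]])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        bic = n * np.log(max(rss, 1e-300) / n) + (k + 1) * np.log(n)
        if bic < best_bic:
            best_k, best_bic = k, bic
    return best_k


# ------------------------------------------------------------------- LMM

@dataclass
class _Rotation:
    """Whitening transform for V = sigma^2 (lambda K + I)."""

    U: np.ndarray  # eigenvectors of K
    d: np.ndarray  # eigenvalues of K
    lam: float  # sigma_g^2 / sigma_e^2

    def apply(self, M: np.ndarray) -> np.ndarray:
        w = 1.0 / np.sqrt(self.lam * self.d + 1.0)
        return (self.U.T @ M) * (w[:, None] if M.ndim == 2 else w)


def _reml_lambda(y: np.ndarray, W: np.ndarray, U: np.ndarray, d: np.ndarray) -> float:
    """Profile REML over lambda = sigma_g^2/sigma_e^2 (log-scale search)."""
    n, c = W.shape[0], W.shape[1]
    Uy = U.T @ y
    UW = U.T @ W

    def neg_reml(loglam: float) -> float:
        lam = np.exp(loglam)
        v = lam * d + 1.0
        WtViW = (UW / v[:, None]).T @ UW
        try:
            beta = np.linalg.solve(WtViW, (UW / v[:, None]).T @ Uy)
        except np.linalg.LinAlgError:
            return 1e12
        r = Uy - UW @ beta
        rss = float(np.sum(r * r / v))
        sign, logdetW = np.linalg.slogdet(WtViW)
        if sign <= 0:
            return 1e12
        return 0.5 * (
            (n - c) * np.log(rss) + np.sum(np.log(v)) + logdetW
        )

    grid = np.linspace(np.log(1e-5), np.log(1e5), 40)
    vals = [neg_reml(g) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(np.exp(res.x))


def _rotate_and_residualize(y, W, G, rot: _Rotation):
    """Whiten by the fitted V and project out covariates (FWL)."""
    yt = rot.apply(y)
    Wt = rot.apply(W)
    Gt = rot.apply(G)
    Q, _ = np.linalg.qr(Wt)
    y_r = yt - Q @ (Q.T @ yt)
    G_r = Gt - Q @ (Q.T @ Gt)
    return y_r, G_r


def gwas_lmm(
    y: np.ndarray,
    G: np.ndarray,
    variants: pd.DataFrame,
    K: np.ndarray,
    PCs: np.ndarray | None = None,
    n_pcs: int | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Univariate Q+K mixed-model scan; exact F test per SNP.

    ``n_pcs=None`` selects the PC count by BIC (up to the supplied PCs).
    Returns a table (snp_id, chrom, pos, beta, se, p, p_fdr).
    """
    n = y.size
    if eig is None:
        d, U = np.linalg.eigh(K)
        d = np.maximum(d, 0.0)
    else:
        d, U = eig
    if PCs is None:
        W = np.ones((n, 1))
    else:
        k = select_pcs(y, PCs) if n_pcs is None else min(n_pcs, PCs.shape[1])
        W = np.column_stack([np.ones(n), PCs[:, :k]])
    lam = _reml_lambda(y, W, U, d)
    rot = _Rotation(U, d, lam)
    y_r, G_r = _rotate_and_residualize(y, W, G, rot)

    xx = np.einsum("ij,ij->j", G_r, G_r)
    xy = G_r.T @ y_r
    dof = n - W.shape[1] - 1
    zero = xx <= 1e-12 * max(float(xx.max()), 1.0)
    xx_safe = np.where(zero, 1.0, xx)
    beta = xy / xx_safe
    rss = np.maximum(float(y_r @ y_r) - beta * xy, 1e-300)
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / xx_safe)
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.where(zero, 1.0, p)
    beta = np.where(zero, 0.0, beta)
    se = np.where(zero, np.inf, se)

    out = variants[["snp_id", "chrom", "pos"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def gwas_mvlmm(
    Y: np.ndarray,
    G: np.ndarray,
    variants: pd.DataFrame,
    K: np.ndarray,
    PCs: np.ndarray | None = None,
    n_pcs: int | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Multivariate (combined-trait) scan: joint null beta = 0 across traits.

    Each trait is whitened with its own null-model variance ratio; per-SNP
    Wald z-scores are combined via the null residual correlation across
    traits into a chi-square statistic with one degree of freedom per
    trait.
    """
    Y = np.asarray(Y, float)
    n, T = Y.shape
    if T < 2:
        raise ValueError("combined-trait scan needs at least 2 traits")
    if (Y.std(axis=0) == 0).any():
        raise ValueError("singular trait covariance (constant trait)")
    corr = np.corrcoef(Y, rowvar=False)
    if np.linalg.matrix_rank(corr, tol=1e-10) < T:
        raise ValueError("singular trait covariance (duplicate trait?)")
    if eig is None:
        d, U = np.linalg.eigh(K)
        d = np.maximum(d, 0.0)
    else:
        d, U = eig

    zs, resids = [], []
    for t in range(T):
        y = Y[:, t]
        if PCs is None:
            W = np.ones((n, 1))
        else:
            k = select_pcs(y, PCs) if n_pcs is None else min(n_pcs, PCs.shape[1])
            W = np.column_stack([np.ones(n), PCs[:, :k]])
        lam = _reml_lambda(y, W, U, d)
        rot = _Rotation(U, d, lam)
        y_r, G_r = _rotate_and_residualize(y, W, G, rot)
        xx = np.einsum("ij,ij->j", G_r, G_r)
        xx = np.where(xx <= 1e-12, np.inf, xx)
        beta = (G_r.T @ y_r) / xx
        dof = n - W.shape[1] - 1
        # null-model residual variance (SNP excluded)
        sigma2 = max(float(y_r @ y_r), 1e-300) / dof
        z = beta * np.sqrt(xx) / np.sqrt(sigma2)
        zs.append(z)
        resids.append(y_r)
    Z = np.column_stack(zs)  # (m, T)
    Rmat = np.corrcoef(np.column_stack(resids), rowvar=False)
    Ri = np.linalg.inv(Rmat)
    stat = np.einsum("mt,ts,ms->m", Z, Ri, Z)
    p = stats.chi2.sf(stat, df=T)

    out = variants[["snp_id", "chrom", "pos"]].copy()
    out["stat"] = stat
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
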