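"""Transcriptome-wide association: per-gene trait vs expression GLMs.

For each gene the accession-level trait value is regressed on the gene's
abundance with hidden expression factors and genotype PCs as covariates;
the expression coefficient's t-test p-value is reported along with a
Bonferroni-adjusted column (monotone in p, so rankings are unchanged).
Covariates are projected out once (Frisch-Waugh), making the per-gene scan
a vectorized simple regression that is numerically identical to the full
OLS fit.  The combined-trait variant tests the expression coefficient
jointly across traits with Pillai's trace (exact F for a single-df
hypothesis).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def filter_expression(
    E: pd.DataFrame,
    min_fraction: float = 0.5,
    expressed_threshold: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove genes expressed in fewer than ``min_fraction`` of lines.

    A gene is "expressed" in a line when its abundance exceeds
    ``expressed_threshold``.  Returns ``(filtered, removal_log)``.
    """
    if E.empty:
        raise ValueError("empty expression matrix")
    frac = (E > expressed_threshold).mean(axis=0)
    keep = frac >= min_fraction
    log = pd.DataFrame(
        {"gene_id": E.columns[~keep], "expressed_fraction": frac[~keep].to_numpy()}
    )
    return E.loc[:, keep], log


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    # SVD-based projection so exactly collinear covariate columns are inert
    U, s, _ = np.linalg.svd(C, full_matrices=False)
    U = U[:, s > s[0] * 1e-10]
    return M - U @ (U.T @ M)


def _covariates(n: int, factors: np.ndarray | None, PCs: np.ndarray | None):
    parts = [np.ones((n, 1))]
    if factors is not None and factors.size:
        parts.append(factors)
    if PCs is not None and PCs.size:
        parts.append(PCs)
    C = np.column_stack(parts)
    rank = np.linalg.matrix_rank(C)
    return C, rank


def twas_glm(
    y: pd.Series,
    E: pd.DataFrame,
    factors: pd.DataFrame | None = None,
    PCs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene association of one trait with expression.

    ``y`` is indexed by line id; lines are intersected with the expression
    matrix (and covariates) before fitting.  Returns a table
    (gene_id, beta, se, p, p_bonferroni, n).
    """
    lines = E.index.intersection(y.dropna().index)
    if factors is not None:
        lines = lines.intersection(factors.index)
    if PCs is not None:
        lines = lines.intersection(PCs.index)
    if len(lines) < 10:
        raise ValueError("too few matched lines for TWAS")
    yv = y.loc[lines].to_numpy(float)
    Ev = E.loc[lines].to_numpy(float)
    Fv = factors.loc[lines].to_numpy(float) if factors is not None else None
    Pv = PCs.loc[lines].to_numpy(float) if PCs is not None else None
    n = len(lines)
    C, rank = _covariates(n, Fv, Pv)

    y_r = _residualize(yv[:, None], C)[:, 0]
    E_r = _residualize(Ev, C)
    xx = np.einsum("ij,ij->j", E_r, E_r)
    dof = n - rank - 1
    skip = xx <= 1e-12 * max(float(np.max(xx)), 1.0)
    xx_safe = np.where(skip, 1.0, xx)
    beta = (E_r.T @ y_r) / xx_safe
    rss = np.maximum(float(y_r @ y_r) - beta**2 * xx_safe, 1e-300)
    se = np.sqrt(rss / dof / xx_safe)
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.where(skip, np.nan, np.clip(p, np.finfo(float).tiny, 1.0))
    out = pd.DataFrame(
        {
            "gene_id": E.columns,
            "beta": np.where(skip, np.nan, beta),
            "se": np.where(skip, np.nan, se),
            "p": p,
            "n": n,
        }
    )
    m = int((~np.isnan(p)).sum())
    out["p_bonferroni"] = np.clip(out["p"] * m, None, 1.0)
    return out


def twas_multitrait(
    Y: pd.DataFrame,
    E: pd.DataFrame,
    factors: pd.DataFrame | None = None,
    PCs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Joint (Pillai trace) test of expression across a combined-trait set.

    With a single response column this reduces exactly to :func:`twas_glm`.
    Returns (gene_id, pillai, p, p_bonferroni, n).
    """
    if Y.shape[1] == 1:
        out = twas_glm(Y.iloc[:, 0], E, factors, PCs)
        out = out.rename(columns={"beta": "pillai"})
        out["pillai"] = np.nan
        return out[["gene_id", "pillai", "p", "n", "p_bonferroni"]]

    lines = E.index.intersection(Y.dropna().index)
    if factors is not None:
        lines = lines.intersection(factors.index)
    if PCs is not None:
        lines = lines.intersection(PCs.index)
    Yv = Y.loc[lines].to_numpy(float)
    Ev = E.loc[lines].to_numpy(float)
    Fv = factors.loc[lines].to_numpy(float) if factors is not None else None
    Pv = PCs.loc[lines].to_numpy(float) if PCs is not None else None
    n, T = Yv.shape
    C, rank = _covariates(n, Fv, Pv)
    # standardize responses: the joint test is invariant to per-trait affine
    # scaling, and the singularity check must mean collinearity, not scale
    sd = Yv.std(axis=0)
    if (sd == 0).any():
        raise ValueError("singular response covariance (constant trait)")
    Yv = (Yv - Yv.mean(axis=0)) / sd
    corr = np.corrcoef(Yv, rowvar=False)
    if np.linalg.matrix_rank(corr, tol=1e-10) < T:
        raise ValueError("singular response covariance (duplicate trait?)")

    Y_r = _residualize(Yv, C)
    E_r = _residualize(Ev, C)
    E0 = Y_r.T @ Y_r  # error SSCP under the null (x excluded)
    ve = n - rank - 1
    xx = np.einsum("ij,ij->j", E_r, E_r)
    skip = xx <= 1e-12 * max(float(np.max(xx)), 1.0)
    xx_safe = np.where(skip, 1.0, xx)
    B = (E_r.T @ Y_r) / xx_safe[:, None]  # per-gene coefficient vectors (m, T)
    # Hypothesis SSCP for gene j is H_j = outer(b_j) * xx_j and H + E1 = E0,
    # so Pillai's trace is V = tr(H E0^-1) = xx * b' E0^-1 b  (s = 1).
    E0_inv = np.linalg.inv(E0)
    V = np.einsum("mt,ts,ms->m", B, E0_inv, B) * xx_safe
    V = np.clip(V, 0.0, 1.0 - 1e-12)
    F = (V / (1.0 - V)) * ((ve - T + 1) / T)
    p = stats.f.sf(F, T, ve - T + 1)
    p = np.where(skip, np.nan, np.clip(p, np.finfo(float).tiny, 1.0))
    out = pd.DataFrame({"gene_id": E.columns, "pillai": np.where(skip, np.nan, V),
                        "p": p, "n": n})
    m = int((~np.isnan(p)).sum())
    out["p_bonferroni"] = np.clip(out["p"] * m, None, 1.0)
    return out
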