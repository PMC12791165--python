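"""REML mixed models for the field trial, BLUPs and heritability.

Single-year model:  y = 1 mu + Z1 g + Z2 s + Z3 b + e
Joint model:        y = 1 mu + X t + Z1 g + Z2 s + Z3 b + Z4 gt + e

with random genotype (g), set (s), block-within-set (b) and, in the joint
model, a fixed environment term (t) and random genotype-by-environment
interaction (gt).  The residual e is either independent or carries a
separable first-order autoregressive correlation over field rows and
columns (AR1xAR1), one field per environment with shared correlation
parameters; the structure can be chosen by AIC.

Variance components are estimated by profile REML over log-variances and
atanh-correlations with a quasi-Newton optimizer (numeric gradients).
BLUPs, their prediction error variances (PEV) and the generalized
heritability H2 = 1 - mean(PEV) / sigma_g^2 follow from the converged fit.
Outliers are filtered by the median/MAD re-scaled residual method with
Bonferroni-Holm control, and the model is refit once without them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from statsmodels.stats.multitest import multipletests

from npqmap.traits import MULTI_TRAIT_SCORE_TRAITS

_VAR_FLOOR_FACTOR = 1e-8
_RHO_MAX = 0.98


@dataclass
class MixedModelSpec:
    """Model specification: response column, design columns, residual type."""

    response: str
    genotype: str = "accession"
    set_col: str = "set"
    block_col: str = "block"
    row_col: str = "row"
    col_col: str = "col"
    env_col: str | None = None  # joint (multi-environment) model when set
    residual: str = "aic"  # "ar1ar1" | "independent" | "aic"

    def __post_init__(self) -> None:
        if self.residual not in ("ar1ar1", "independent", "aic"):
            raise ValueError(f"unknown residual structure {self.residual!r}")


@dataclass
class VarianceComponents:
    sigma2: dict[str, float]  # per random term (g, s, b, gt)
    resid: float
    rho_row: float
    rho_col: float
    loglik: float
    aic: float
    structure: str
    converged: bool


@dataclass
class TrialFit:
    spec: MixedModelSpec
    vc: VarianceComponents
    mu: float
    blups: pd.DataFrame  # accession, blup, adjusted_mean, pev
    residuals: pd.Series  # conditional residuals, aligned to input index
    n_obs: int
    outliers: list = field(default_factory=list)


def _incidence(labels: pd.Series) -> tuple[np.ndarray, list]:
    codes, levels = pd.factorize(labels, sort=True)
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), codes] = 1.0
    return Z, list(levels)


def _ar1_power(dist: np.ndarray, rho: float) -> np.ndarray:
    """rho**dist for integer distances, valid for negative rho."""
    if rho == 0.0:
        return (dist == 0).astype(float)
    mag = np.abs(rho) ** dist
    if rho < 0:
        return np.where(dist % 2 == 1, -mag, mag)
    return mag


def _build_terms(data: pd.DataFrame, spec: MixedModelSpec):
    """Fixed design X, random-term incidence products, residual metadata."""
    n = len(data)
    if spec.env_col is None:
        X = np.ones((n, 1))
        g_lab = data[spec.genotype].astype(str)
        s_lab = data[spec.set_col].astype(str)
        b_lab = data[spec.set_col].astype(str) + ":" + data[spec.block_col].astype(str)
        terms = {"g": g_lab, "s": s_lab, "b": b_lab}
        env = pd.Series("all", index=data.index)
    else:
        env = data[spec.env_col].astype(str)
        env_d = pd.get_dummies(env, drop_first=True, dtype=float)
        X = np.column_stack([np.ones(n), env_d.to_numpy()])
        g_lab = data[spec.genotype].astype(str)
        s_lab = env + ":" + data[spec.set_col].astype(str)
        b_lab = s_lab + ":" + data[spec.block_col].astype(str)
        gt_lab = env + ":" + g_lab
        terms = {"g": g_lab, "s": s_lab, "b": b_lab, "gt": gt_lab}
    Z = {}
    levels = {}
    for name, lab in terms.items():
        Z[name], levels[name] = _incidence(lab)
    ZZt = {name: Zi @ Zi.T for name, Zi in Z.items()}
    return X, Z, ZZt, levels, env


def _resid_dists(data: pd.DataFrame, spec: MixedModelSpec, env: pd.Series):
    """Per-pair row/col integer distances, +inf across environments."""
    rows = data[spec.row_col].to_numpy(float)
    cols = data[spec.col_col].to_numpy(float)
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    same_env = (env.to_numpy()[:, None] == env.to_numpy()[None, :])
    return dr, dc, same_env


class _REMLProblem:
    def __init__(self, y, X, ZZt, dr=None, dc=None, same_env=None, ar1=False):
        self.y = y
        self.X = X
        self.ZZt = ZZt
        self.names = list(ZZt)
        self.n = y.size
        self.ar1 = ar1
        self.dr, self.dc, self.same_env = dr, dc, same_env
        self.vy = max(float(np.var(y)), 1e-12)

    # theta = [log sig2 per term..., log sig2_resid, (atanh rho_r, atanh rho_c)]
    def n_par(self) -> int:
        return len(self.names) + 1 + (2 if self.ar1 else 0)

    def build_V(self, theta: np.ndarray) -> np.ndarray:
        k = len(self.names)
        V = np.zeros((self.n, self.n))
        for i, name in enumerate(self.names):
            V += np.exp(theta[i]) * self.ZZt[name]
        s2e = np.exp(theta[k])
        if self.ar1:
            rho_r = np.tanh(theta[k + 1])
            rho_c = np.tanh(theta[k + 2])
            R = _ar1_power(self.dr, rho_r) * _ar1_power(self.dc, rho_c)
            R = np.where(self.same_env, R, 0.0)
            np.fill_diagonal(R, 1.0)
            V += s2e * R
        else:
            V[np.diag_indices(self.n)] += s2e
        return V

    def neg_reml(self, theta: np.ndarray) -> float:
        V = self.build_V(theta)
        try:
            c, low = cho_factor(V, check_finite=False)
        except np.linalg.LinAlgError:
            return 1e12
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        Vi_y = cho_solve((c, low), self.y, check_finite=False)
        Vi_X = cho_solve((c, low), self.X, check_finite=False)
        XtViX = self.X.T @ Vi_X
        try:
            cx, lowx = cho_factor(XtViX, check_finite=False)
        except np.linalg.LinAlgError:
            return 1e12
        logdetX = 2.0 * np.sum(np.log(np.diag(cx)))
        beta = cho_solve((cx, lowx), self.X.T @ Vi_y, check_finite=False)
        yPy = float(self.y @ Vi_y - (self.X.T @ Vi_y) @ beta)
        return 0.5 * (logdetV + logdetX + yPy)

    def fit(self, theta0: np.ndarray | None = None):
        k = len(self.names)
        if theta0 is None:
            v0 = self.vy / (k + 1)
            theta0 = np.full(self.n_par(), np.log(v0))
            if self.ar1:
                theta0[k + 1 :] = 0.0
        lo = np.log(_VAR_FLOOR_FACTOR * self.vy)
        hi = np.log(1e4 * self.vy)
        bounds = [(lo, hi)] * (k + 1)
        if self.ar1:
            bounds += [(np.arctanh(-_RHO_MAX), np.arctanh(_RHO_MAX))] * 2
        res = minimize(
            self.neg_reml,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-10, "gtol": 1e-7},
        )
        return res


def fit_reml(data: pd.DataFrame, spec: MixedModelSpec) -> TrialFit:
    """Fit the mixed model by REML and compute BLUPs, PEV and residuals.

    ``data`` holds one row per plot (disc values averaged upstream).  When
    ``spec.residual == "aic"`` both the independent and the AR1xAR1 residual
    fits are run and the lower-AIC structure is reported.
    """
    needed = [spec.response, spec.genotype, spec.set_col, spec.block_col]
    if spec.env_col:
        needed.append(spec.env_col)
    data = data.dropna(subset=[spec.response]).copy()
    if data.empty:
        raise ValueError("no observations")
    for col in needed:
        if data[col].isna().any():
            raise ValueError(f"missing values in design column {col!r}")
    if spec.env_col is not None and data[spec.env_col].nunique() < 2:
        raise ValueError("joint model requires at least two environments")

    y_raw = data[spec.response].to_numpy(float)
    # center the response so estimates are exactly shift-invariant
    y_shift = float(y_raw.mean())
    y = y_raw - y_shift
    X, Z, ZZt, levels, env = _build_terms(data, spec)

    fits = {}
    if spec.residual in ("independent", "aic"):
        prob = _REMLProblem(y, X, ZZt)
        fits["independent"] = (prob, prob.fit())
    if spec.residual in ("ar1ar1", "aic"):
        dr, dc, same_env = _resid_dists(data, spec, env)
        prob = _REMLProblem(y, X, ZZt, dr, dc, same_env, ar1=True)
        theta0 = None
        if "independent" in fits:
            prev = fits["independent"][1].x
            theta0 = np.concatenate([prev, [0.0, 0.0]])
        fits["ar1ar1"] = (prob, prob.fit(theta0))

    best_name, (prob, res) = min(
        fits.items(), key=lambda kv: 2 * kv[1][0].n_par() + 2 * kv[1][1].fun
    )
    if not res.success and res.status != 1:  # status 1: maxiter, still usable
        warnings.warn(f"REML optimizer reported: {res.message}")

    theta = res.x
    k = len(prob.names)
    sigma2 = {name: float(np.exp(theta[i])) for i, name in enumerate(prob.names)}
    s2e = float(np.exp(theta[k]))
    rho_r = float(np.tanh(theta[k + 1])) if prob.ar1 else 0.0
    rho_c = float(np.tanh(theta[k + 2])) if prob.ar1 else 0.0
    loglik = -float(res.fun)
    aic = 2.0 * prob.n_par() - 2.0 * loglik
    vc = VarianceComponents(
        sigma2=sigma2,
        resid=s2e,
        rho_row=rho_r,
        rho_col=rho_c,
        loglik=loglik,
        aic=aic,
        structure=best_name,
        converged=bool(res.success or res.status == 1),
    )

    # BLUPs, PEV and conditional residuals at the converged components.
    V = prob.build_V(theta)
    c, low = cho_factor(V, check_finite=False)
    Vi_y = cho_solve((c, low), y, check_finite=False)
    Vi_X = cho_solve((c, low), X, check_finite=False)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    Vi_r = cho_solve((c, low), r, check_finite=False)

    Zg = Z["g"]
    s2g = sigma2["g"]
    u_g = s2g * (Zg.T @ Vi_r)
    # PEV = sigma_g^2 I - sigma_g^4 Zg' P Zg  (P the REML projection matrix)
    Vi_Zg = cho_solve((c, low), Zg, check_finite=False)
    XtViZg = X.T @ Vi_Zg
    P_Zg = Vi_Zg - Vi_X @ np.linalg.solve(XtViX, XtViZg)
    pev = s2g - s2g**2 * np.einsum("ij,ij->j", Zg, P_Zg)
    pev = np.maximum(pev, 0.0)

    mu = float(np.mean(X @ beta)) + y_shift
    blups = pd.DataFrame(
        {
            "accession": levels["g"],
            "blup": u_g,
            "adjusted_mean": mu + u_g,
            "pev": pev,
        }
    )

    fitted_random = np.zeros_like(y)
    for name, Zi in Z.items():
        s2i = sigma2[name]
        fitted_random += Zi @ (s2i * (Zi.T @ Vi_r))
    resid = pd.Series(y - X @ beta - fitted_random, index=data.index)

    return TrialFit(
        spec=spec, vc=vc, mu=mu, blups=blups, residuals=resid, n_obs=len(y)
    )


def detect_outliers(residuals: pd.Series, alpha: float = 0.05) -> list:
    """Outlying observations by the median/re-scaled-MAD residual method.

    Residuals are standardized by their median and 1.4826*MAD; two-sided
    normal tail p-values are tested with Bonferroni-Holm control at
    ``alpha``.  Returns the index labels of flagged observations.
    """
    r = residuals.to_numpy(float)
    mad = np.median(np.abs(r - np.median(r)))
    if mad == 0:
        warnings.warn("MAD of residuals is zero; no outliers flagged")
        return []
    z = (r - np.median(r)) / (1.4826 * mad)
    p = 2.0 * stats.norm.sf(np.abs(z))
    reject = multipletests(p, alpha=alpha, method="holm")[0]
    if reject.mean() > 0.2:
        # a normal-tail rule flagging this much of the data signals a
        # collapsed MAD / grossly non-normal residual scale, not outliers
        warnings.warn("outlier rule flagged >20% of residuals; ignoring flags")
        return []
    return list(residuals.index[reject])


def fit_trait(
    data: pd.DataFrame,
    spec: MixedModelSpec,
    outlier_alpha: float = 0.05,
) -> TrialFit:
    """Fit, remove Bonferroni-Holm MAD outliers, and refit once."""
    fit = fit_reml(data, spec)
    out = detect_outliers(fit.residuals, alpha=outlier_alpha)
    if out:
        try:
            refit = fit_reml(data.drop(index=out), spec)
        except ValueError as err:  # e.g. removal emptied an environment
            warnings.warn(f"outlier refit failed ({err}); keeping original fit")
            return fit
        refit.outliers = out
        return refit
    return fit


def heritability(fit: TrialFit) -> float:
    """Generalized heritability H2 = 1 - mean(PEV) / sigma_g^2.

    Reported as 0.0 when the genetic variance is estimated at (or below)
    its boundary, where H2 is undefined.
    """
    s2g = fit.vc.sigma2["g"]
    if s2g <= 10 * _VAR_FLOOR_FACTOR * max(fit.vc.resid, 1e-12):
        warnings.warn("sigma_g^2 at boundary; heritability undefined, set to 0")
        return 0.0
    return float(1.0 - fit.blups["pev"].mean() / s2g)


def plot_means(trait_records: pd.DataFrame, design: pd.DataFrame,
               traits: list[str]) -> pd.DataFrame:
    """Average disc-level trait records per plot and join design columns."""
    per_plot = trait_records.groupby("plot")[traits].mean().reset_index()
    cols = ["plot", "row", "col", "block", "set", "accession", "year"]
    return design[cols].drop_duplicates("plot").merge(per_plot, on="plot")


def trait_correlations(
    blup_wide: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of accession-matched BLUPs.

    Returns ``(r, p_raw, p_holm)`` matrices; the Holm step-down adjustment
    runs across all distinct pairs.  Pairs involving a constant trait are
    NaN.
    """
    cols = list(blup_wide.columns)
    m = len(cols)
    r = pd.DataFrame(np.eye(m), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((m, m)), index=cols, columns=cols)
    pairs, pvals = [], []
    for i in range(m):
        for j in range(i + 1, m):
            sub = blup_wide[[cols[i], cols[j]]].dropna()
            if len(sub) < 3 or sub.iloc[:, 0].std() == 0 or sub.iloc[:, 1].std() == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(sub.iloc[:, 0], sub.iloc[:, 1])
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
            if not np.isnan(pij):
                pairs.append((i, j))
                pvals.append(pij)
    p_holm = p.copy()
    if pvals:
        adj = multipletests(pvals, method="holm")[1]
        for (i, j), a in zip(pairs, adj):
            p_holm.iloc[i, j] = p_holm.iloc[j, i] = a
    return r, p, p_holm


def multi_trait_score(blup_wide: pd.DataFrame) -> pd.DataFrame:
    """Composite score: sum of z-standardized max NPQ, relaxation k and PI.

    Accessions missing any of the three traits are excluded.  Returns a
    table sorted by descending score with a 1-based rank column.
    """
    needed = list(MULTI_TRAIT_SCORE_TRAITS)
    missing = [t for t in needed if t not in blup_wide.columns]
    if missing:
        raise ValueError(f"missing traits for Multi-trait Score: {missing}")
    sub = blup_wide[needed].dropna()
    z = (sub - sub.mean()) / sub.std(ddof=1)
    score = z.sum(axis=1)
    out = pd.DataFrame({"score": score}).sort_values("score", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
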