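"""Photoprotection traits from per-disc chlorophyll-fluorescence traces.

From each trace the module derives NPQ(t) = (Fm - Fm')/Fm', PhiPSII(t) =
(Fm' - F)/Fm' and Fv/Fm = (Fm - Fo)/Fm.  During the dark relaxation phase
the steady-state fluorescence F relaxes to Fo', so the measured PhiPSII
equals the light-adapted maximum efficiency Fv'/Fm'; the photoprotection
index therefore compares the final dark PhiPSII with the Fv'/Fm' predicted
from residual NPQ alone.  The module then fits

* NPQ induction  (light):  y = a (1 - exp(-k t))
* NPQ relaxation (dark):   y = a exp(-k t) + b
* PhiPSII recovery (dark): y = a (1 - exp(-k t)) + b

by bounded nonlinear least squares using variable projection: for a fixed
rate constant the amplitude/offset solve a linear least-squares problem, so
the fit reduces to a deterministic one-dimensional search over k (coarse
log-grid then local refinement) -- no random restarts.  Derived traits (max
NPQ, initial slopes over the first 60 s, NPQf at the final dark point, the
photoprotection index, Fv/Fm) complete the 14-trait record per disc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from npqmap import traits as T

K_MIN, K_MAX = 1e-3, 50.0
_K_GRID = np.geomspace(0.01, 40.0, 45)
SLOPE_WINDOW_MIN = 1.0  # first 60 s of a phase


@dataclass
class KineticFit:
    """One exponential fit: amplitude, rate constant (min^-1), offset."""

    amplitude: float
    k: float
    offset: float
    rss: float
    r2: float
    converged: bool


def _r2(y: np.ndarray, rss: float) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - rss / tss if tss > 0 else np.nan


def _varpro_fit(t: np.ndarray, y: np.ndarray, basis, with_offset: bool) -> KineticFit:
    """Variable-projection fit of ``y ~ a*basis(k, t) [+ b]`` over k.

    For a fixed k the linear coefficients have closed forms (1x1 or 2x2
    normal equations), so the grid stage is vectorized over all candidate
    rates and the refinement is a bounded scalar search.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = t.size
    syy = float(y @ y)
    sy = float(y.sum())

    def solve(k):
        """Coefficients and RSS at rate k (k may be a 1-D array)."""
        f = basis(np.atleast_1d(k)[:, None], t[None, :])  # (m, n)
        sff = np.einsum("ij,ij->i", f, f)
        sfy = f @ y
        if with_offset:
            sf = f.sum(axis=1)
            det = sff * n - sf * sf
            # Near-collinear basis (k so large that f ~ constant): fall back
            # to the offset-only fit instead of amplifying roundoff.
            degenerate = det <= 1e-9 * (sff * n + 1e-300)
            safe_det = np.where(degenerate, 1.0, det)
            a = np.where(degenerate, 0.0, (n * sfy - sf * sy) / safe_det)
            b = np.where(degenerate, sy / n, (sff * sy - sf * sfy) / safe_det)
            resid = y[None, :] - a[:, None] * f - b[:, None]
        else:
            degenerate = sff <= 1e-300
            a = np.where(degenerate, 0.0, sfy / np.where(degenerate, 1.0, sff))
            b = np.zeros_like(a)
            resid = y[None, :] - a[:, None] * f
        rss = np.einsum("ij,ij->i", resid, resid)
        return a, b, rss

    def sse(logk: float) -> float:
        return float(solve(np.exp(logk))[2][0])

    grid_sse = solve(_K_GRID)[2]
    i = int(np.argmin(grid_sse))
    lo = np.log(_K_GRID[max(i - 1, 0)] if i > 0 else K_MIN)
    hi = np.log(_K_GRID[min(i + 1, _K_GRID.size - 1)] if i < _K_GRID.size - 1 else K_MAX)
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    k = float(np.exp(res.x))
    a_arr, b_arr, rss_arr = solve(k)
    a, b, rss = float(a_arr[0]), float(b_arr[0]), float(rss_arr[0])

    scale = max(float(np.max(np.abs(y))), 1e-12)
    converged = True
    # (near-)flat series: amplitude indistinguishable from 0, k unidentifiable
    if float(np.max(np.abs(y))) < 1e-12 or abs(a) < 1e-4 * scale:
        converged = False
    if k <= K_MIN * 1.01 or k >= K_MAX * 0.99:  # rate at the search bound
        converged = False
    return KineticFit(a, k, b, rss, _r2(y, rss), converged)


def fit_induction(t, y) -> KineticFit:
    """Fit the light-phase NPQ induction curve ``a (1 - exp(-k t))``."""
    if len(t) < 4:
        raise ValueError("need at least 4 light-phase points")
    order = np.argsort(t)
    return _varpro_fit(np.asarray(t)[order], np.asarray(y)[order],
                       lambda k, tt: 1.0 - np.exp(-k * tt), with_offset=False)


def fit_relaxation(t, y) -> KineticFit:
    """Fit the dark-phase NPQ relaxation curve ``a exp(-k t) + b``.

    ``t`` must be re-zeroed at lights-off.
    """
    if len(t) < 4:
        raise ValueError("need at least 4 dark-phase points")
    order = np.argsort(t)
    return _varpro_fit(np.asarray(t)[order], np.asarray(y)[order],
                       lambda k, tt: np.exp(-k * tt), with_offset=True)


def fit_recovery(t, y) -> KineticFit:
    """Fit the dark-phase PhiPSII recovery curve ``a (1 - exp(-k t)) + b``."""
    if len(t) < 4:
        raise ValueError("need at least 4 dark-phase points")
    order = np.argsort(t)
    return _varpro_fit(np.asarray(t)[order], np.asarray(y)[order],
                       lambda k, tt: 1.0 - np.exp(-k * tt), with_offset=True)


def initial_slope(t, y, anchor_origin: bool = False) -> float:
    """OLS slope (min^-1) over the first 60 s of a phase.

    For NPQ induction an anchor point (t=0, NPQ=0) is included, since NPQ is
    zero by construction at lights-on.  Returns NaN (undefined) when fewer
    than 3 points fall in the window.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    sel = t <= SLOPE_WINDOW_MIN + 1e-9
    tw, yw = t[sel], y[sel]
    if anchor_origin:
        tw = np.concatenate([[0.0], tw])
        yw = np.concatenate([[0.0], yw])
    if tw.size < 3:
        return np.nan
    return float(np.polyfit(tw, yw, 1)[0])


def predicted_fvpfmp(fvfm: float, npqf: float) -> float:
    """Fv'/Fm' predicted from residual NPQ alone (no photoinhibition)."""
    q = (1.0 - fvfm) * (1.0 + npqf)
    return 1.0 - q / (fvfm + q)


def photoprotection_index(fvfm: float, fvpfmp_f: float, npqf: float) -> float:
    """PI = observed final Fv'/Fm' over the value predicted from NPQf.

    PI ~ 1 means the drop in Fv'/Fm' is fully explained by residual NPQ;
    values below 1 indicate photoinhibition.  Undefined (NaN) when the
    predicted value is non-positive.
    """
    if not 0 < fvfm < 1:
        raise ValueError("Fv/Fm must lie in (0, 1)")
    if npqf < 0:
        raise ValueError("NPQf must be >= 0")
    pred = predicted_fvpfmp(fvfm, npqf)
    if pred <= 0:
        return np.nan
    return fvpfmp_f / pred


def derive_series(disc: pd.DataFrame) -> dict:
    """NPQ, PhiPSII and Fv'/Fm' series for one disc's trace rows.

    Raises ``ValueError`` (with a reason) for non-positive fluorescence.
    """
    disc = disc.sort_values("time_min")
    fm = float(disc["Fm"].iloc[0])
    fo = float(disc["Fo"].iloc[0])
    if fm <= 0 or fo <= 0 or fm <= fo:
        raise ValueError("invalid_dark_reference")
    light = disc[disc["phase"] == "light"]
    dark = disc[disc["phase"] == "dark"]
    if (light["Fm_prime"] <= 0).any() or (dark["Fm_prime"] <= 0).any():
        raise ValueError("nonpositive_fluorescence")
    fvfm = (fm - fo) / fm

    t_light = light["time_min"].to_numpy()
    fmp_l = light["Fm_prime"].to_numpy()
    npq_light = (fm - fmp_l) / fmp_l

    lights_off = t_light.max() if t_light.size else 0.0
    t_dark = dark["time_min"].to_numpy() - lights_off
    fmp_d = dark["Fm_prime"].to_numpy()
    f_d = dark["F"].to_numpy()
    npq_dark = (fm - fmp_d) / fmp_d
    phi_dark = (fmp_d - f_d) / fmp_d
    # In darkness F relaxes to Fo', so measured PhiPSII == Fv'/Fm'.
    fvpfmp_dark = phi_dark

    return {
        "fvfm": fvfm,
        "t_light": t_light,
        "npq_light": npq_light,
        "t_dark": t_dark,
        "npq_dark": npq_dark,
        "phi_dark": phi_dark,
        "fvpfmp_dark": fvpfmp_dark,
    }


def extract_traits(traces: pd.DataFrame) -> pd.DataFrame:
    """Per-disc trait records (no QC filtering; see :func:`qc_filter`).

    Returns one row per disc with the 14 traits plus fit-quality columns
    (r2/converged per fit and a ``reject_reason`` for invalid traces).
    """
    records = []
    meta_cols = [c for c in ("accession", "plot", "replicate", "year")
                 if c in traces.columns]
    for disc_id, disc in traces.groupby("disc_id", sort=False):
        rec: dict = {"disc_id": disc_id}
        for c in meta_cols:
            rec[c] = disc[c].iloc[0]
        try:
            s = derive_series(disc)
        except ValueError as err:
            rec["reject_reason"] = str(err)
            records.append(rec)
            continue
        rec["reject_reason"] = ""
        rec[T.FVFM] = s["fvfm"]
        rec[T.MAX_NPQ] = float(np.max(s["npq_light"]))
        rec[T.IND_SLOPE] = initial_slope(s["t_light"], s["npq_light"],
                                         anchor_origin=True)
        rec[T.REL_SLOPE] = initial_slope(s["t_dark"], s["npq_dark"])

        ind = fit_induction(s["t_light"], s["npq_light"])
        rel = fit_relaxation(s["t_dark"], s["npq_dark"])
        rec_fit = fit_recovery(s["t_dark"], s["phi_dark"])
        rec[T.IND_K], rec[T.IND_AMP] = ind.k, ind.amplitude
        rec[T.REL_K], rec[T.REL_AMP] = rel.k, rel.amplitude
        rec[T.REL_INTERCEPT] = rel.offset
        rec[T.REC_K], rec[T.REC_AMP] = rec_fit.k, rec_fit.amplitude
        rec[T.REC_INTERCEPT] = rec_fit.offset
        rec[T.NPQF] = float(s["npq_dark"][-1])  # observed, not fitted
        rec[T.PI] = photoprotection_index(
            s["fvfm"], float(s["fvpfmp_dark"][-1]), rec[T.NPQF]
        )
        for name, fit in (("ind", ind), ("rel", rel), ("rec", rec_fit)):
            rec[f"{name}_r2"] = fit.r2
            rec[f"{name}_converged"] = fit.converged
        records.append(rec)
    return pd.DataFrame(records)


def qc_filter(
    trait_records: pd.DataFrame,
    fvfm_min: float = 0.65,
    fit_r2_min: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quality filtering of per-disc trait records.

    Discs with Fv/Fm strictly below ``fvfm_min`` are excluded (a disc at
    exactly the threshold is retained); discs whose exponential fits fail
    the R2 floor or did not converge lose *all* traits.  Returns
    ``(retained, exclusion_log)``.
    """
    if not (0 < fvfm_min < 1 and 0 < fit_r2_min <= 1):
        raise ValueError("QC thresholds must lie in (0, 1)")
    if trait_records.empty:
        import warnings

        warnings.warn("qc_filter received no discs")
        return trait_records, pd.DataFrame(columns=["disc_id", "reason"])

    reasons = pd.Series("", index=trait_records.index, dtype=object)
    bad_trace = trait_records["reject_reason"].fillna("") != ""
    reasons[bad_trace] = trait_records.loc[bad_trace, "reject_reason"]

    low_fvfm = (~bad_trace) & (trait_records[T.FVFM] < fvfm_min)
    reasons[low_fvfm] = "fvfm_below_threshold"

    fit_ok = np.ones(len(trait_records), dtype=bool)
    for name in ("ind", "rel", "rec"):
        r2 = trait_records[f"{name}_r2"].to_numpy(dtype=float)
        conv = trait_records[f"{name}_converged"].astype(bool).to_numpy()
        fit_ok &= conv & (np.nan_to_num(r2, nan=-np.inf) >= fit_r2_min)
    bad_fit = (~bad_trace) & (~low_fvfm) & (~fit_ok)
    reasons[bad_fit] = "fit_quality"

    excluded = reasons != ""
    log = pd.DataFrame(
        {"disc_id": trait_records.loc[excluded, "disc_id"],
         "reason": reasons[excluded]}
    ).reset_index(drop=True)
    return trait_records.loc[~excluded].reset_index(drop=True), log
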