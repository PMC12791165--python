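"""Per-disc fluorescence trace simulation.

NPQ during the light period follows ``a_npq_i * (1 - exp(-k_ind t))``, NPQ in
the dark follows ``a_npq_r * exp(-k_rel t) + b_npq``, and PhiPSII in the dark
recovers as ``a_phi * (1 - exp(-k_rec t)) + b_phi``.  The series are emitted
as fluorescence values back-computed on a fixed Fm = 1 scale:
``Fm'(t) = Fm / (1 + NPQ(t))``, ``F(t) = Fm'(t) * (1 - PhiPSII(t))`` and
``Fo = (1 - Fv/Fm) * Fm``, so that ``NPQ = Fm/Fm' - 1`` reproduces the
simulated series exactly.  Any positive rescaling of the fluorescence values
yields identical NPQ and PhiPSII, so the Fm = 1 convention is lossless.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from npqmap.sim.schedule import MeasurementSchedule
from npqmap.traits import KINETIC_PARAMS

TRACE_COLUMNS = [
    "disc_id",
    "accession",
    "plot",
    "replicate",
    "year",
    "time_min",
    "phase",
    "F",
    "Fm_prime",
    "Fo",
    "Fm",
]

_META_DEFAULTS = {
    "disc_id": "disc0",
    "accession": "ACC0000",
    "plot": "P0000",
    "replicate": 1,
    "year": "2017",
}


def npq_induction(t: np.ndarray, a: float | np.ndarray, k: float | np.ndarray):
    """NPQ light-induction curve ``a * (1 - exp(-k t))``."""
    return a * (1.0 - np.exp(-k * t))


def npq_relaxation(t, a, k, b):
    """NPQ dark-relaxation curve ``a * exp(-k t) + b``."""
    return a * np.exp(-k * t) + b


def phipsii_recovery(t, a, k, b):
    """PhiPSII dark-recovery curve ``a * (1 - exp(-k t)) + b``."""
    return a * (1.0 - np.exp(-k * t)) + b


def pure_npq_params(
    params: Mapping[str, float],
    schedule: MeasurementSchedule | None = None,
) -> dict[str, float]:
    """Adjust PhiPSII recovery so the trace carries no photoinhibition.

    Sets the recovery amplitude such that the final-dark-point PhiPSII
    equals the Fv'/Fm' predicted from residual NPQ alone; a noiseless trace
    built from the returned parameters has a photoprotection index of
    exactly 1.
    """
    from npqmap.kinetics import predicted_fvpfmp

    if schedule is None:
        schedule = MeasurementSchedule()
    t_f = schedule.dark_times[-1]
    npq_f = npq_relaxation(t_f, params["a_npq_r"], params["k_rel"], params["b_npq"])
    pred = predicted_fvpfmp(params["fvfm"], float(npq_f))
    k_rec, t = params["k_rec"], float(t_f)
    a_phi = (pred - params["b_phi"]) / (1.0 - np.exp(-k_rec * t))
    if a_phi <= 0:
        raise ValueError("b_phi too large for a pure-NPQ trace")
    out = dict(params)
    out["a_phi"] = float(a_phi)
    return out


def simulate_trace_batch(
    disc_params: pd.DataFrame,
    schedule: MeasurementSchedule | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate traces for every row (disc) of ``disc_params``.

    ``disc_params`` must carry the kinetic parameter columns
    (:data:`npqmap.traits.KINETIC_PARAMS`); disc metadata columns
    (disc_id, accession, plot, replicate, year) are passed through when
    present.  ``noise_sd`` is the Gaussian SD added to the NPQ series
    (PhiPSII noise is scaled down tenfold to match its narrower range).
    Deterministic for a given seed.
    """
    if schedule is None:
        schedule = MeasurementSchedule()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    p = disc_params
    for col in KINETIC_PARAMS:
        if col not in p.columns:
            raise ValueError(f"disc_params missing kinetic column {col!r}")
    for rate in ("k_ind", "k_rel", "k_rec"):
        if (p[rate] <= 0).any():
            raise ValueError(f"non-positive rate constant in column {rate!r}")

    n = len(p)
    rng = np.random.default_rng(seed)
    t_l = np.asarray(schedule.light_times)
    t_d = np.asarray(schedule.dark_times)
    nl, nd = t_l.size, t_d.size

    a_i = p["a_npq_i"].to_numpy()[:, None]
    k_i = p["k_ind"].to_numpy()[:, None]
    a_r = p["a_npq_r"].to_numpy()[:, None]
    k_r = p["k_rel"].to_numpy()[:, None]
    b_n = p["b_npq"].to_numpy()[:, None]
    a_p = p["a_phi"].to_numpy()[:, None]
    k_p = p["k_rec"].to_numpy()[:, None]
    b_p = p["b_phi"].to_numpy()[:, None]
    fvfm = p["fvfm"].to_numpy()

    npq_l = npq_induction(t_l[None, :], a_i, k_i)
    npq_d = npq_relaxation(t_d[None, :], a_r, k_r, b_n)
    phi_d = phipsii_recovery(t_d[None, :], a_p, k_p, b_p)
    phi_l = np.broadcast_to(b_p, (n, nl)).copy()
    if noise_sd > 0:
        npq_l = npq_l + rng.normal(0.0, noise_sd, npq_l.shape)
        npq_d = npq_d + rng.normal(0.0, noise_sd, npq_d.shape)
        phi_d = phi_d + rng.normal(0.0, noise_sd / 10.0, phi_d.shape)
        phi_l = phi_l + rng.normal(0.0, noise_sd / 10.0, phi_l.shape)
    npq_l = np.clip(npq_l, 0.0, None)
    npq_d = np.clip(npq_d, 0.0, None)
    phi_d = np.clip(phi_d, 1e-3, 0.999)
    phi_l = np.clip(phi_l, 1e-3, 0.999)

    fm = 1.0
    fo = (1.0 - fvfm) * fm

    npq = np.concatenate([npq_l, npq_d], axis=1)
    phi = np.concatenate([phi_l, phi_d], axis=1)
    fm_prime = fm / (1.0 + npq)
    f_val = fm_prime * (1.0 - phi)

    n_samp = 1 + nl + nd  # dark0 row + light + dark samples
    times = np.concatenate([[0.0], t_l, 10.0 + t_d])
    phases = np.array(["dark0"] + ["light"] * nl + ["dark"] * nd)

    out = {}
    for col, default in _META_DEFAULTS.items():
        vals = p[col].to_numpy() if col in p.columns else np.repeat(default, n)
        out[col] = np.repeat(vals, n_samp)
    out["time_min"] = np.tile(times, n)
    out["phase"] = np.tile(phases, n)
    out["F"] = np.column_stack([fo, f_val]).ravel()  # dark0 row: F = Fo
    out["Fm_prime"] = np.column_stack([np.full(n, fm), fm_prime]).ravel()
    out["Fo"] = np.repeat(fo, n_samp)
    out["Fm"] = np.repeat(fm, n * n_samp)
    return pd.DataFrame(out)[TRACE_COLUMNS]


def simulate_trace(
    params: Mapping[str, float],
    schedule: MeasurementSchedule | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    **meta,
) -> pd.DataFrame:
    """Simulate a single disc trace from a kinetic parameter mapping."""
    row = {**{k: params[k] for k in KINETIC_PARAMS}, **_META_DEFAULTS, **meta}
    return simulate_trace_batch(
        pd.DataFrame([row]), schedule=schedule, noise_sd=noise_sd, seed=seed
    )
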