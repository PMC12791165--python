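"""Trait registry for the photoprotection screen.

Fourteen per-disc traits are derived from each fluorescence trace: the three
exponential fits (NPQ induction ``y = a(1 - exp(-k t))``, NPQ dark relaxation
``y = a exp(-k t) + b``, PhiPSII dark recovery ``y = a(1 - exp(-k t)) + b``)
contribute amplitudes, rate constants and intercepts; the remainder are read
directly from the series (max NPQ, initial slopes, NPQf, Fv/Fm) or computed
from them (photoprotection index).

Four combined-trait sets (CT1-CT4) group covarying traits for multivariate
association: CT1-CT3 span the quickly-vs-slowly-relaxing NPQ axis, CT4 the
photoprotection-vs-photodamage axis.
"""

from __future__ import annotations

# Canonical trait column names (per-disc and per-accession tables).
MAX_NPQ = "max_npq"
IND_SLOPE = "ind_slope"
REL_SLOPE = "rel_slope"
IND_K = "ind_k"
IND_AMP = "ind_amp"
REL_K = "rel_k"
REL_AMP = "rel_amp"
REL_INTERCEPT = "rel_intercept"
NPQF = "npqf"
REC_K = "rec_k"
REC_AMP = "rec_amp"
REC_INTERCEPT = "rec_intercept"
PI = "pi"
FVFM = "fvfm"

#: All 14 single traits, in reporting order.
TRAITS: tuple[str, ...] = (
    MAX_NPQ,
    IND_SLOPE,
    REL_SLOPE,
    IND_K,
    IND_AMP,
    REL_K,
    REL_AMP,
    REL_INTERCEPT,
    NPQF,
    REC_K,
    REC_AMP,
    REC_INTERCEPT,
    PI,
    FVFM,
)

#: Combined-trait sets for multivariate GWAS/TWAS.
TRAIT_COMBOS: dict[str, tuple[str, ...]] = {
    "CT1": (MAX_NPQ, IND_AMP, IND_K, REL_K),
    "CT2": (IND_AMP, IND_K, REL_K),
    "CT3": (MAX_NPQ, IND_K, REL_K),
    "CT4": (PI, REC_AMP, REC_K),
}

#: Model-year tags: the two single-environment models and the joint model.
MODEL_YEARS: tuple[str, ...] = ("2017", "2019", "joint")

#: Expression tissues: shoot growing point and base of third leaf.
TISSUES: tuple[str, ...] = ("GP", "3L")

#: Traits entering the composite Multi-trait Score (standardized and summed).
MULTI_TRAIT_SCORE_TRAITS: tuple[str, ...] = (MAX_NPQ, REL_K, PI)

#: Kinetic parameter names used by the trace simulator (accession-level truth).
KINETIC_PARAMS: tuple[str, ...] = (
    "a_npq_i",
    "k_ind",
    "a_npq_r",
    "k_rel",
    "b_npq",
    "a_phi",
    "k_rec",
    "b_phi",
    "fvfm",
)
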