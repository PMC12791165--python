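"""Ground-truth specification for the synthetic study.

The defaults emulate the two-year sorghum field screen the pipeline targets:
861 accessions in an augmented block design, exponential NPQ kinetics with
accession-level genetic variation and genotype-by-year interaction, AR1xAR1
spatially correlated plot residuals, and optional planted causal SNPs and
causal transcripts whose effects enter the accession-level kinetic
parameters additively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from npqmap.traits import KINETIC_PARAMS

#: Panel-level kinetic parameter means (joint-model adjusted-mean scale).
DEFAULT_KINETIC_MEANS: dict[str, float] = {
    "a_npq_i": 2.80,  # NPQ induction amplitude ~ max NPQ
    "k_ind": 0.58,  # NPQ induction rate constant (min^-1)
    "a_npq_r": 1.91,  # NPQ relaxation amplitude
    "k_rel": 5.09,  # NPQ relaxation rate constant (min^-1)
    "b_npq": 0.89,  # residual NPQ offset ~ NPQf
    "a_phi": 0.30,  # PhiPSII recovery amplitude
    "k_rec": 5.08,  # PhiPSII recovery rate constant (min^-1)
    "b_phi": 0.20,  # PhiPSII offset at lights-off
    "fvfm": 0.75,  # dark-adapted Fv/Fm
}

#: Accession-level (polygenic) genetic SDs, scaled so adjusted-mean ranges
#: across a ~900-accession panel match the observed trait ranges.
DEFAULT_GENETIC_SD: dict[str, float] = {
    "a_npq_i": 0.12,
    "k_ind": 0.09,
    "a_npq_r": 0.12,
    "k_rel": 0.60,
    "b_npq": 0.08,
    "a_phi": 0.02,
    "k_rec": 0.50,
    "b_phi": 0.02,
    "fvfm": 0.008,
}

_RATE_PARAMS = ("k_ind", "k_rel", "k_rec")


def _scaled(base: Mapping[str, float], factor: float) -> dict[str, float]:
    return {k: v * factor for k, v in base.items()}


@dataclass(frozen=True)
class TruthSpec:
    """All parameters of the synthetic study, with planted truth.

    ``causal_snps`` maps a SNP index to per-kinetic-parameter additive
    effects (per alt-allele dose); ``causal_genes`` maps a gene index to
    per-kinetic-parameter effects of the gene's standardized expression
    latent.  All random components are drawn from substreams of ``seed``.
    """

    n_accessions: int = 861
    n_years: int = 2
    kinetic_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KINETIC_MEANS)
    )
    genetic_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENETIC_SD)
    )
    gxe_sd: Mapping[str, float] = field(
        default_factory=lambda: _scaled(DEFAULT_GENETIC_SD, 1.0)
    )
    set_sd: Mapping[str, float] = field(
        default_factory=lambda: _scaled(DEFAULT_GENETIC_SD, 0.3)
    )
    block_sd: Mapping[str, float] = field(
        default_factory=lambda: _scaled(DEFAULT_GENETIC_SD, 0.3)
    )
    resid_sd: Mapping[str, float] = field(
        default_factory=lambda: _scaled(DEFAULT_GENETIC_SD, 1.2)
    )
    disc_sd: Mapping[str, float] = field(
        default_factory=lambda: _scaled(DEFAULT_GENETIC_SD, 1.0)
    )
    spatial_rho_row: float = 0.4
    spatial_rho_col: float = 0.4
    causal_snps: Sequence[tuple[int, Mapping[str, float]]] = ()
    causal_genes: Sequence[tuple[int, Mapping[str, float]]] = ()
    n_hidden_factors: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years not in (1, 2):
            raise ValueError("n_years must be 1 or 2")
        for name in (
            "genetic_sd",
            "gxe_sd",
            "set_sd",
            "block_sd",
            "resid_sd",
            "disc_sd",
        ):
            sds = getattr(self, name)
            missing = set(KINETIC_PARAMS) - set(sds)
            if missing:
                raise ValueError(f"{name} missing parameters: {sorted(missing)}")
            if any(v < 0 for v in sds.values()):
                raise ValueError(f"{name} must be non-negative")
        if not abs(self.spatial_rho_row) < 1 or not abs(self.spatial_rho_col) < 1:
            raise ValueError("AR1 correlations must lie in (-1, 1)")
        for p in _RATE_PARAMS:
            if self.kinetic_means[p] <= 0:
                raise ValueError(f"mean rate constant {p} must be positive")
        if not 0 < self.kinetic_means["fvfm"] < 1:
            raise ValueError("mean Fv/Fm must lie in (0, 1)")
        if self.n_hidden_factors < 0:
            raise ValueError("n_hidden_factors must be >= 0")


def default_truth(**overrides) -> TruthSpec:
    """A :class:`TruthSpec` with study-scale defaults, fields overridable."""
    return TruthSpec(**overrides)
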