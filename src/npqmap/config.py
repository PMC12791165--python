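"""Pipeline configuration: one declarative object, serialized into outputs.

Every analysis threshold defaults to the published protocol value
(Fv/Fm >= 0.65 QC, MAC >= 20, LD pruning 50/10/0.9, 500 kb block window,
D' CI bounds 0.70/0.98, top fractions 0.05%/1%/1%, candidate rules >= 8
analyses or >= 10 traits, 10 hidden factors, 5 genotype PCs).  Simulation
sizes default to a desk-scale study; the full-panel scale (861 accessions,
960 plots) can be requested explicitly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # --- synthetic study dimensions -------------------------------------
    n_accessions: int = 200
    n_checks: int = 3
    n_blocks: int = 8
    blocks_per_set: int = 4
    rows: int = 18
    cols: int = 12
    years: tuple[str, ...] = ("2017", "2019")
    discs_per_plot: int = 4
    trace_noise_sd: float = 0.03
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    block_size_range: tuple[int, int] = (4, 12)
    n_chrom: int = 2
    n_extra_genes: int = 450
    expression_line_fraction: float = 0.75
    n_hidden_factors_truth: int = 10
    expression_sparse_fraction: float = 0.1
    # --- planted truth ---------------------------------------------------
    n_causal: int = 5
    snp_effect_sd: float = 1.5  # per-allele effect, units of genetic SD
    expr_effect_sd: float = 2.0  # per-latent-SD effect, units of genetic SD
    spatial_rho_row: float = 0.4
    spatial_rho_col: float = 0.4
    # --- trait extraction ------------------------------------------------
    fvfm_min: float = 0.65
    fit_r2_min: float = 0.8
    # --- mixed model -----------------------------------------------------
    residual_structure: str = "aic"  # ar1ar1 | independent | aic
    outlier_alpha: float = 0.05
    # --- GWAS ------------------------------------------------------------
    mac_min: int = 20
    prune_window: int = 50
    prune_step: int = 10
    prune_r2: float = 0.9
    n_pcs: int = 5
    select_pcs_by_bic: bool = True
    # --- LD blocks -------------------------------------------------------
    block_max_kb: float = 500.0
    block_min_maf: float = 0.001
    dprime_ci_low: float = 0.70
    dprime_ci_high: float = 0.98
    ld_r2_prefilter: float = 0.2
    # --- TWAS ------------------------------------------------------------
    n_hidden_factors: int = 10
    factor_method: str = "ard"  # ard | pca
    expression_min_fraction: float = 0.5
    # --- ensemble --------------------------------------------------------
    top_gwas_fraction: float = 0.0005
    top_twas_fraction: float = 0.01
    top_fct_fraction: float = 0.01
    fct_gwas_fraction: float = 0.10
    analyses_min: int = 8
    traits_min: int = 10
    # --- misc ------------------------------------------------------------
    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate",
        "traces",
        "blups",
        "gwas",
        "twas",
        "candidates",
    )

    def __post_init__(self) -> None:
        def _in01(name):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

        for name in (
            "fvfm_min",
            "fit_r2_min",
            "expression_min_fraction",
            "top_twas_fraction",
            "top_fct_fraction",
            "fct_gwas_fraction",
            "outlier_alpha",
        ):
            _in01(name)
        if not 0 < self.top_gwas_fraction < 1:
            raise ValueError("top_gwas_fraction must lie in (0, 1)")
        if self.residual_structure not in ("ar1ar1", "independent", "aic"):
            raise ValueError("residual_structure must be ar1ar1|independent|aic")
        if self.mac_min < 0 or self.analyses_min < 1 or self.traits_min < 1:
            raise ValueError("counting thresholds must be positive")
        if not abs(self.spatial_rho_row) < 1 or not abs(self.spatial_rho_col) < 1:
            raise ValueError("spatial correlations must lie in (-1, 1)")
        self.years = tuple(str(y) for y in self.years)
        self.maf_range = tuple(self.maf_range)
        self.block_size_range = tuple(self.block_size_range)
        self.stages = tuple(self.stages)

    # --- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
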