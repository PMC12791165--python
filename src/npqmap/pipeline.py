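"""End-to-end pipeline orchestration.

Stages (in dependency order): simulate -> traces -> blups -> gwas -> twas
-> candidates.  Each stage reads its inputs from the run directory when not
already in memory and writes its outputs there, together with a manifest
entry (config hash, seed, row counts), so re-running a stage with the same
config and seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from npqmap import __version__
from npqmap import traits as T
from npqmap.config import PipelineConfig
from npqmap.ensemble import build_top_sets, call_candidates, overlap_counts
from npqmap.factors import hidden_factors
from npqmap.gwas import (
    filter_mac,
    genotype_pcs,
    gwas_lmm,
    gwas_mvlmm,
    kinship,
    ld_prune,
)
from npqmap.io import read_gff3_genes, read_traces, read_vcf
from npqmap.kinetics import extract_traits, qc_filter
from npqmap.ldblocks import ld_blocks
from npqmap.sim import (
    build_design,
    draw_causal_gene_latents,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotypes,
)
from npqmap.sim.annotation import simulate_annotation
from npqmap.sim.io import (
    read_expression_tsv,
    write_expression_tsv,
    write_gff3,
    write_truth_json,
    write_vcf,
)
from npqmap.sim.traces import simulate_trace_batch
from npqmap.sim.truth import DEFAULT_GENETIC_SD, TruthSpec
from npqmap.traits import KINETIC_PARAMS, MODEL_YEARS, TISSUES, TRAIT_COMBOS, TRAITS
from npqmap.trial import (
    MixedModelSpec,
    fit_trait,
    heritability,
    multi_trait_score,
    plot_means,
    trait_correlations,
)
from npqmap.twas import filter_expression, twas_glm, twas_multitrait

log = logging.getLogger("npqmap")

_CAUSAL_PARAM_CYCLE = ("a_npq_i", "k_ind", "k_rel", "b_npq", "k_rec")
_STREAM_NAMES = (
    "design",
    "genotypes",
    "latents",
    "phenotypes",
    "expr_GP",
    "expr_3L",
    "traces",
    "lines",
)


def _stream_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAM_NAMES))
    return {
        name: int(c.generate_state(1)[0] % 2**31)
        for name, c in zip(_STREAM_NAMES, children)
    }


@dataclass
class PipelineResult:
    config: PipelineConfig
    run_dir: Path
    frames: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.frames[key]


class PipelineRun:
    """Stateful runner; see :func:`run_pipeline` for the one-call interface."""

    def __init__(self, config: PipelineConfig, run_dir: str | Path):
        self.cfg = config
        self.run_dir = Path(run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}
        self.seeds = _stream_seeds(config.seed)
        self._manifest_path = self.run_dir / "manifest.json"
        config.to_yaml(self.run_dir / "config.yaml")

    # ------------------------------------------------------------- manifest
    def _record(self, stage: str, outputs: dict[str, int]) -> None:
        manifest = {}
        if self._manifest_path.exists():
            manifest = json.loads(self._manifest_path.read_text())
        manifest.setdefault("config_hash", self.cfg.config_hash())
        manifest.setdefault("seed", self.cfg.seed)
        manifest.setdefault("version", __version__)
        manifest.setdefault("stages", {})
        manifest["stages"][stage] = {
            "outputs": outputs,
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self._manifest_path.write_text(json.dumps(manifest, indent=2))

    def _write(self, name: str, df: pd.DataFrame, sep: str = ",") -> int:
        path = self.run_dir / name
        with open(path, "w") as fh:
            fh.write(f"# npqmap {__version__} config={self.cfg.config_hash()}\n")
            df.to_csv(fh, sep=sep, index=False)
        return len(df)

    def _read(self, name: str, sep: str = ",", **kw) -> pd.DataFrame:
        return pd.read_csv(self.run_dir / name, sep=sep, comment="#", **kw)

    # -------------------------------------------------------------- stages
    def simulate(self) -> None:
        cfg = self.cfg
        design = build_design(
            cfg.n_accessions,
            cfg.n_blocks,
            cfg.n_checks,
            cfg.rows,
            cfg.cols,
            seed=self.seeds["design"],
            years=cfg.years,
            blocks_per_set=cfg.blocks_per_set,
        )
        accessions = sorted(design["accession"].unique())
        G, variants = simulate_genotypes(
            len(accessions),
            cfg.n_snps,
            block_size_range=cfg.block_size_range,
            maf_range=cfg.maf_range,
            seed=self.seeds["genotypes"],
            n_chrom=cfg.n_chrom,
        )
        genes = simulate_annotation(
            variants, seed=self.seeds["genotypes"], n_extra=cfg.n_extra_genes
        )
        n_blocks_total = int(variants["block"].nunique())
        n_genes_total = n_blocks_total + cfg.n_extra_genes

        causal_blocks = sorted(
            set(np.linspace(0, n_blocks_total - 1, cfg.n_causal).astype(int))
        )
        causal_snps, causal_genes = [], []
        for i, b in enumerate(causal_blocks):
            param = _CAUSAL_PARAM_CYCLE[i % len(_CAUSAL_PARAM_CYCLE)]
            members = np.flatnonzero(variants["block"].to_numpy() == b)
            snp_idx = int(members[len(members) // 2])
            causal_snps.append(
                (snp_idx, {param: cfg.snp_effect_sd * DEFAULT_GENETIC_SD[param]})
            )
            causal_genes.append(
                (b, {param: cfg.expr_effect_sd * DEFAULT_GENETIC_SD[param]})
            )
        latents = draw_causal_gene_latents(
            accessions, [b for b, _ in causal_genes], self.seeds["latents"]
        )
        truth = TruthSpec(
            n_accessions=cfg.n_accessions,
            n_years=len(cfg.years),
            spatial_rho_row=cfg.spatial_rho_row,
            spatial_rho_col=cfg.spatial_rho_col,
            causal_snps=causal_snps,
            causal_genes=causal_genes,
            n_hidden_factors=cfg.n_hidden_factors_truth,
            seed=self.seeds["phenotypes"],
        )
        phen = simulate_phenotypes(
            design, G, accessions, truth, latents, discs_per_plot=cfg.discs_per_plot
        )
        rng_lines = np.random.default_rng(self.seeds["lines"])
        n_lines = max(20, int(round(cfg.expression_line_fraction * len(accessions))))
        lines = sorted(rng_lines.choice(accessions, size=n_lines, replace=False))
        expr = {}
        for tissue in TISSUES:
            E, _ = simulate_expression(
                lines,
                n_genes=n_genes_total,
                n_hidden_factors=cfg.n_hidden_factors_truth,
                causal_latents=latents,
                sparse_fraction=cfg.expression_sparse_fraction,
                seed=self.seeds[f"expr_{tissue}"],
                tissue=tissue,
            )
            expr[tissue] = E
        traces = simulate_trace_batch(
            phen.disc_params, noise_sd=cfg.trace_noise_sd, seed=self.seeds["traces"]
        )

        st = self.state
        st.update(
            design=design,
            G=G,
            variants=variants,
            genes=genes,
            accessions=accessions,
            lines=lines,
            expression=expr,
            traces_raw=traces,
            truth=truth,
            causal_gene_ids=[genes["gene_id"].iloc[b] for b, _ in causal_genes],
        )
        outputs = {
            "design.csv": self._write("design.csv", design),
            "traces.csv": self._write("traces.csv", traces),
        }
        write_vcf(G, variants, accessions, self.run_dir / "genotypes.vcf")
        write_gff3(genes, self.run_dir / "genes.gff3")
        for tissue, E in expr.items():
            write_expression_tsv(E, tissue, self.run_dir / f"expression_{tissue}.tsv")
        write_truth_json(
            {
                "causal_snps": [
                    {"snp_id": variants["snp_id"].iloc[i], "effects": dict(e)}
                    for i, e in truth.causal_snps
                ],
                "causal_genes": [
                    {"gene_id": genes["gene_id"].iloc[b], "effects": dict(e)}
                    for b, e in truth.causal_genes
                ],
                "lines": list(lines),
                "seed": cfg.seed,
            },
            self.run_dir / "truth.json",
        )
        outputs["genotypes.vcf"] = int(len(variants))
        self._record("simulate", outputs)

    # ..................................................................
    def traces(self) -> None:
        if "traces_raw" not in self.state:
            self.state["traces_raw"] = read_traces(self.run_dir / "traces.csv")
        records = extract_traits(self.state["traces_raw"])
        kept, excl = qc_filter(
            records, fvfm_min=self.cfg.fvfm_min, fit_r2_min=self.cfg.fit_r2_min
        )
        self.state["disc_traits"] = kept
        self.state["exclusions"] = excl
        self._record(
            "traces",
            {
                "disc_traits.csv": self._write("disc_traits.csv", kept),
                "exclusions.csv": self._write("exclusions.csv", excl),
            },
        )

    # ..................................................................
    def blups(self) -> None:
        cfg = self.cfg
        if "disc_traits" not in self.state:
            self.state["disc_traits"] = self._read(
                "disc_traits.csv", dtype={"year": str}
            )
        if "design" not in self.state:
            self.state["design"] = self._read("design.csv", dtype={"year": str})
        disc = self.state["disc_traits"]
        design = self.state["design"]
        data = plot_means(disc, design, list(TRAITS))

        rows_b, rows_h = [], []
        for trait in TRAITS:
            for my in MODEL_YEARS:
                if my == "joint":
                    if len(cfg.years) < 2:
                        continue
                    spec = MixedModelSpec(
                        response=trait,
                        env_col="year",
                        residual=cfg.residual_structure,
                    )
                    sub = data
                else:
                    if my not in cfg.years:
                        continue
                    spec = MixedModelSpec(
                        response=trait, residual=cfg.residual_structure
                    )
                    sub = data[data["year"] == my]
                fit = fit_trait(sub, spec, outlier_alpha=cfg.outlier_alpha)
                b = fit.blups.copy()
                b["trait"] = trait
                b["model_year"] = my
                rows_b.append(b)
                rows_h.append(
                    {
                        "trait": trait,
                        "model_year": my,
                        "H2": heritability(fit),
                        "sigma2_g": fit.vc.sigma2.get("g", np.nan),
                        "sigma2_resid": fit.vc.resid,
                        "rho_row": fit.vc.rho_row,
                        "rho_col": fit.vc.rho_col,
                        "structure": fit.vc.structure,
                        "loglik": fit.vc.loglik,
                        "aic": fit.vc.aic,
                        "n_outliers": len(fit.outliers),
                    }
                )
                log.info("blups: %s/%s done", trait, my)
        blups_long = pd.concat(rows_b, ignore_index=True)
        herit = pd.DataFrame(rows_h)
        self.state["blups"] = blups_long
        self.state["heritability"] = herit

        outputs = {
            "blups.csv": self._write("blups.csv", blups_long),
            "heritability.csv": self._write("heritability.csv", herit),
        }
        for my in [m for m in MODEL_YEARS if m == "joint" or m in cfg.years]:
            wide = self.adjusted_means(my)
            r, _, p_holm = trait_correlations(wide)
            outputs[f"correlations_{my}.csv"] = self._write(
                f"correlations_{my}.csv", r.reset_index(names="trait")
            )
            self._write(
                f"correlations_{my}_holm_p.csv", p_holm.reset_index(names="trait")
            )
        score = multi_trait_score(
            self.adjusted_means("joint" if len(cfg.years) > 1 else cfg.years[0])
        )
        outputs["multitrait_score.csv"] = self._write(
            "multitrait_score.csv", score.reset_index(names="accession")
        )
        self.state["multitrait_score"] = score
        self._record("blups", outputs)

    def adjusted_means(self, model_year: str) -> pd.DataFrame:
        blups = self.state["blups"]
        sub = blups[blups["model_year"] == model_year]
        return sub.pivot(index="accession", columns="trait", values="adjusted_mean")

    # ..................................................................
    def gwas(self) -> None:
        cfg = self.cfg
        st = self.state
        if "G" not in st:
            G, variants, samples = read_vcf(self.run_dir / "genotypes.vcf")
            st.update(G=G, variants=variants, accessions=samples)
        if "blups" not in st:
            st["blups"] = self._read("blups.csv", dtype={"model_year": str})
        G = st["G"].astype(float)
        variants = st["variants"]

        Gm, vm = filter_mac(G, variants, cfg.mac_min)
        blocks = ld_blocks(
            Gm.astype(int),
            vm,
            max_kb=cfg.block_max_kb,
            min_maf=cfg.block_min_maf,
            r2_prefilter=cfg.ld_r2_prefilter,
            ci_lower=cfg.dprime_ci_low,
            ci_upper=cfg.dprime_ci_high,
        )
        Gp, vp = ld_prune(
            Gm, vm, window=cfg.prune_window, step=cfg.prune_step, r2_max=cfg.prune_r2
        )
        K = kinship(Gp)
        PCs = genotype_pcs(Gp, cfg.n_pcs)
        accessions = list(st["accessions"])

        n_pcs_fixed = None if cfg.select_pcs_by_bic else cfg.n_pcs
        results = []
        gwas_by_key: dict[tuple[str, str], pd.DataFrame] = {}
        model_years = [m for m in MODEL_YEARS if m == "joint" or m in cfg.years]
        if len(cfg.years) < 2:
            model_years = [m for m in model_years if m != "joint"]
        for my in model_years:
            # Accessions can drop out of a model-year when QC removed every
            # disc of their plot; subset genotypes and kinship accordingly.
            wide = self.adjusted_means(my).reindex(accessions).dropna()
            idx = np.array([accessions.index(a) for a in wide.index])
            Gs, Ks, Ps = Gp[idx], K[np.ix_(idx, idx)], PCs[idx]
            d, U = np.linalg.eigh(Ks)
            eig = (np.maximum(d, 0.0), U)
            for trait in TRAITS:
                y = wide[trait].to_numpy(float)
                res = gwas_lmm(y, Gs, vp, Ks, PCs=Ps, n_pcs=n_pcs_fixed, eig=eig)
                res.insert(0, "analysis", "GWAS")
                res.insert(1, "trait", trait)
                res.insert(2, "model_year", my)
                results.append(res)
                gwas_by_key[(trait, my)] = res
            for combo, members in TRAIT_COMBOS.items():
                Y = wide[list(members)].to_numpy(float)
                res = gwas_mvlmm(Y, Gs, vp, Ks, PCs=Ps, n_pcs=n_pcs_fixed, eig=eig)
                res.insert(0, "analysis", "GWAS")
                res.insert(1, "trait", combo)
                res.insert(2, "model_year", my)
                results.append(res)
                gwas_by_key[(combo, my)] = res
            log.info("gwas: model-year %s done", my)
        gwas_all = pd.concat(results, ignore_index=True)
        st["gwas_results"] = gwas_all
        st["gwas_by_key"] = gwas_by_key
        st["ld_blocks"] = blocks
        st["kinship"] = pd.DataFrame(K, index=accessions, columns=accessions)
        st["pcs"] = pd.DataFrame(
            PCs, index=accessions,
            columns=[f"PC{i+1}" for i in range(PCs.shape[1])],
        )
        self._record(
            "gwas",
            {
                "gwas_results.tsv": self._write("gwas_results.tsv", gwas_all, sep="\t"),
                "ld_blocks.tsv": self._write("ld_blocks.tsv", blocks, sep="\t"),
                "kinship.tsv": self._write(
                    "kinship.tsv", st["kinship"].reset_index(names="accession"),
                    sep="\t",
                ),
                "pcs.tsv": self._write(
                    "pcs.tsv", st["pcs"].reset_index(names="accession"), sep="\t"
                ),
            },
        )

    # ..................................................................
    def twas(self) -> None:
        cfg = self.cfg
        st = self.state
        if "expression" not in st:
            st["expression"] = {}
            for tissue in TISSUES:
                E, _ = read_expression_tsv(self.run_dir / f"expression_{tissue}.tsv")
                st["expression"][tissue] = E
        if "blups" not in st:
            st["blups"] = self._read("blups.csv", dtype={"model_year": str})
        if "pcs" not in st:
            st["pcs"] = self._read("pcs.tsv", sep="\t").set_index("accession")

        model_years = [m for m in MODEL_YEARS if m == "joint" or m in cfg.years]
        if len(cfg.years) < 2:
            model_years = [m for m in model_years if m != "joint"]
        results = []
        twas_by_key: dict[tuple[str, str, str], pd.DataFrame] = {}
        for tissue, E in st["expression"].items():
            Ef, _ = filter_expression(E, min_fraction=cfg.expression_min_fraction)
            hf = hidden_factors(
                Ef, n_factors=cfg.n_hidden_factors, method=cfg.factor_method
            )
            pcs = st["pcs"].reindex(Ef.index)
            for my in model_years:
                wide = self.adjusted_means(my)
                for trait in TRAITS:
                    y = wide[trait]
                    res = twas_glm(y, Ef, hf.scores, pcs)
                    res.insert(0, "analysis", "TWAS")
                    res.insert(1, "trait", trait)
                    res.insert(2, "model_year", my)
                    res.insert(3, "tissue", tissue)
                    results.append(res)
                    twas_by_key[(trait, my, tissue)] = res
                for combo, members in TRAIT_COMBOS.items():
                    res = twas_multitrait(wide[list(members)], Ef, hf.scores, pcs)
                    res.insert(0, "analysis", "TWAS")
                    res.insert(1, "trait", combo)
                    res.insert(2, "model_year", my)
                    res.insert(3, "tissue", tissue)
                    results.append(res)
                    twas_by_key[(combo, my, tissue)] = res
            log.info("twas: tissue %s done", tissue)
        twas_all = pd.concat(results, ignore_index=True)
        st["twas_results"] = twas_all
        st["twas_by_key"] = twas_by_key
        self._record(
            "twas",
            {"twas_results.tsv": self._write("twas_results.tsv", twas_all, sep="\t")},
        )

    # ..................................................................
    def fct(self) -> None:
        """Write the per-gene Fisher's-combined-test tables explicitly."""
        from npqmap.ensemble import fct_table

        st = self.state
        if "genes" not in st:
            st["genes"] = read_gff3_genes(self.run_dir / "genes.gff3")
        self._load_assoc_results()
        rows = []
        for (trait, my, tissue), tw in st["twas_by_key"].items():
            gw = st["gwas_by_key"].get((trait, my))
            if gw is None:
                continue
            fct = fct_table(
                gw, tw.dropna(subset=["p"]), st["genes"],
                gwas_fraction=self.cfg.fct_gwas_fraction,
            )
            fct.insert(0, "trait", trait)
            fct.insert(1, "model_year", my)
            fct.insert(2, "tissue", tissue)
            rows.append(fct)
        fct_all = pd.concat(rows, ignore_index=True)
        st["fct_results"] = fct_all
        self._record(
            "fct",
            {"fct_results.tsv": self._write("fct_results.tsv", fct_all, sep="\t")},
        )

    def _load_assoc_results(self) -> None:
        st = self.state
        if "gwas_by_key" not in st:
            gw = self._read("gwas_results.tsv", sep="\t", dtype={"model_year": str})
            st["gwas_by_key"] = {
                (t, m): grp.reset_index(drop=True)
                for (t, m), grp in gw.groupby(["trait", "model_year"])
            }
        if "twas_by_key" not in st:
            tw = self._read("twas_results.tsv", sep="\t", dtype={"model_year": str})
            st["twas_by_key"] = {
                (t, m, ti): grp.reset_index(drop=True)
                for (t, m, ti), grp in tw.groupby(["trait", "model_year", "tissue"])
            }

    # ..................................................................
    def candidates(self) -> None:
        cfg = self.cfg
        st = self.state
        if "genes" not in st:
            st["genes"] = read_gff3_genes(self.run_dir / "genes.gff3")
        if "ld_blocks" not in st:
            st["ld_blocks"] = self._read("ld_blocks.tsv", sep="\t")
        self._load_assoc_results()

        top_sets = build_top_sets(
            st["gwas_by_key"],
            st["twas_by_key"],
            st["ld_blocks"],
            st["genes"],
            gwas_fraction=cfg.top_gwas_fraction,
            twas_fraction=cfg.top_twas_fraction,
            fct_fraction=cfg.top_fct_fraction,
            fct_gwas_fraction=cfg.fct_gwas_fraction,
        )
        ledger = overlap_counts(top_sets)
        candidates = call_candidates(
            ledger, analyses_min=cfg.analyses_min, traits_min=cfg.traits_min
        )
        st["top_sets"] = top_sets
        st["ledger"] = ledger
        st["candidates"] = candidates

        sets_df = pd.DataFrame(
            [
                {
                    "trait": k.trait,
                    "model_year": k.model_year,
                    "analysis": k.analysis,
                    "tissue": k.tissue,
                    "genes": ",".join(sorted(map(str, v))),
                    "n_genes": len(v),
                }
                for k, v in top_sets.items()
            ]
        )
        self._record(
            "candidates",
            {
                "top_sets.csv": self._write("top_sets.csv", sets_df),
                "overlap_ledger.csv": self._write("overlap_ledger.csv", ledger),
                "candidates.csv": self._write("candidates.csv", candidates),
            },
        )

    # ------------------------------------------------------------------
    _STAGE_FUNCS = {
        "simulate": simulate,
        "traces": traces,
        "blups": blups,
        "gwas": gwas,
        "twas": twas,
        "fct": fct,
        "candidates": candidates,
    }

    def run(self, stages: tuple[str, ...] | None = None) -> PipelineResult:
        stages = stages or self.cfg.stages
        for stage in stages:
            if stage not in self._STAGE_FUNCS:
                raise ValueError(f"unknown stage {stage!r}")
            log.info("stage %s: starting", stage)
            t0 = time.time()
            try:
                self._STAGE_FUNCS[stage](self)
            except Exception:
                log.error("stage %s failed; partial outputs kept", stage)
                raise
            log.info("stage %s: done in %.1f s", stage, time.time() - t0)
        return PipelineResult(self.cfg, self.run_dir, self.state)


def run_pipeline(
    config: PipelineConfig, run_dir: str | Path, stages=None
) -> PipelineResult:
    """Run the pipeline stages (default: all) and return the result state."""
    return PipelineRun(config, run_dir).run(stages)


def permuted_null_candidates(
    result: PipelineResult, run_dir: str | Path, seed: int
) -> int:
    """Chance-overlap candidate count under an expression permutation.

    Re-runs the TWAS and candidate stages after permuting the line labels of
    both tissues' expression matrices (one shared permutation), which breaks
    every gene-trait link while preserving gene-gene and trait-trait
    correlation.  Candidates called on the permuted data that are not
    planted causal genes estimate how many null genes the top-fraction
    overlap rules pick up by chance alone.
    """
    rng = np.random.default_rng(seed)
    run = PipelineRun(result.config, run_dir)
    run.state = dict(result.frames)
    expr = {}
    perm = None
    for tissue, E in result["expression"].items():
        if perm is None:
            perm = rng.permutation(len(E))
        E2 = E.copy()
        E2.index = E.index[perm]
        expr[tissue] = E2
    run.state["expression"] = expr
    for key in ("twas_by_key", "twas_results", "top_sets", "ledger", "candidates"):
        run.state.pop(key, None)
    run.run(("twas", "candidates"))
    called = set(run.state["candidates"]["gene_id"])
    return len(called - set(result["causal_gene_ids"]))


def evaluate_recovery(result: PipelineResult) -> dict:
    """Planted-truth scoring of a synthetic run (requires simulate stage).

    Returns the causal-gene recovery fraction, the false-candidate count,
    and the candidate list split into true/false.
    """
    causal = set(result["causal_gene_ids"])
    called = set(result["candidates"]["gene_id"]) if len(result["candidates"]) else set()
    true_hits = causal & called
    return {
        "n_causal": len(causal),
        "n_candidates": len(called),
        "n_true": len(true_hits),
        "recovery": len(true_hits) / len(causal) if causal else np.nan,
        "false_candidates": sorted(called - causal),
        "n_false": len(called - causal),
    }
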