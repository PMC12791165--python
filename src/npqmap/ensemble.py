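"""Ensemble candidate-gene calling from GWAS, TWAS and Fisher's combined test.

Per trait there are fifteen analysis cells: GWAS for the 2017, 2019 and
joint models, plus TWAS and FCT for each model-year in each of two tissues.
"Top genes" per cell are: all genes overlapping LD blocks that contain the
top 0.05% of GWAS SNPs (SNPs outside any block contribute their nearest
gene); the top 1% of TWAS genes; and the top 1% of FCT genes, where FCT
combines each gene's best (minimum) GWAS p among its assigned top-10% SNPs
with the tissue's TWAS p.  A gene is a candidate when it appears in >= 8
cells for some trait or in >= 10 distinct trait columns (combined-trait
sets count as their own columns).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ----------------------------------------------------------- gene geometry

def nearest_gene(snps: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Nearest gene id per SNP (same chromosome, boundary distance).

    A SNP inside a gene's span maps to that gene; ties in distance go to
    the gene with the lower start coordinate.  SNPs on chromosomes without
    genes map to NA (logged via warning).
    """
    out = pd.Series(pd.NA, index=snps.index, dtype=object)
    unassigned = 0
    for chrom, grp in snps.groupby("chrom"):
        g = genes[genes["chrom"] == chrom].sort_values("start")
        if g.empty:
            unassigned += len(grp)
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        ids = g["gene_id"].to_numpy()
        pos = grp["pos"].to_numpy()[:, None]
        dist = np.maximum(starts[None, :] - pos, 0) + np.maximum(
            pos - ends[None, :], 0
        )
        out.loc[grp.index] = ids[np.argmin(dist, axis=1)]
    if unassigned:
        warnings.warn(f"{unassigned} SNPs on chromosomes with no genes")
    return out


def genes_in_blocks(blocks: pd.DataFrame, genes: pd.DataFrame) -> dict[int, list]:
    """Map block row index -> gene ids overlapping the block span."""
    result: dict[int, list] = {}
    for i, b in blocks.iterrows():
        g = genes[
            (genes["chrom"] == b["chrom"])
            & (genes["end"] >= b["start"])
            & (genes["start"] <= b["end"])
        ]
        result[i] = list(g["gene_id"])
    return result


def assign_snps_to_blocks(snps: pd.DataFrame, blocks: pd.DataFrame) -> pd.Series:
    """Block row index per SNP (NA when the SNP lies in no block)."""
    out = pd.Series(pd.NA, index=snps.index, dtype=object)
    for i, b in blocks.iterrows():
        sel = (
            (snps["chrom"] == b["chrom"])
            & (snps["pos"] >= b["start"])
            & (snps["pos"] <= b["end"])
        )
        out[sel & out.isna()] = i
    return out


# ------------------------------------------------------------ Fisher's test

def fisher_combined(pvals: np.ndarray) -> np.ndarray:
    """Fisher's combined probability per row: X = -2 sum(ln p) ~ chi2(2k).

    ``pvals`` is (n, k); zeros are clamped to the smallest positive float
    with a warning.
    """
    p = np.atleast_2d(np.asarray(pvals, float))
    if (p <= 0).any():
        warnings.warn("p-values of 0 clamped to the smallest positive float")
        p = np.clip(p, np.finfo(float).tiny, None)
    if (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    X = -2.0 * np.log(p).sum(axis=1)
    return stats.chi2.sf(X, df=2 * p.shape[1])


# ------------------------------------------------------------ top-set logic

def top_fraction(df: pd.DataFrame, fraction: float, p_col: str = "p") -> pd.DataFrame:
    """Top ``ceil(fraction * n)`` rows by p; ties broken by (p, chrom, pos).

    Rows lacking chrom/pos (gene tables) are tie-broken by identifier.
    """
    n = len(df)
    if n == 0:
        return df
    k = math.ceil(fraction * n)
    by = [p_col] + [c for c in ("chrom", "pos", "gene_id", "snp_id") if c in df.columns]
    return df.sort_values(by, kind="mergesort").head(k)


@dataclass(frozen=True)
class CellKey:
    trait: str
    model_year: str
    analysis: str  # GWAS | TWAS | FCT
    tissue: str  # GP | 3L | none


def gwas_cell_genes(
    gwas_result: pd.DataFrame,
    blocks: pd.DataFrame,
    genes: pd.DataFrame,
    fraction: float = 0.0005,
    block_gene_map: dict[int, list] | None = None,
    snp_block: pd.Series | None = None,
) -> set:
    """Genes for one GWAS cell: LD-block genes of the top-fraction SNPs."""
    top = top_fraction(gwas_result, fraction)
    if block_gene_map is None:
        block_gene_map = genes_in_blocks(blocks, genes)
    if snp_block is None:
        snp_block = assign_snps_to_blocks(gwas_result, blocks)
    out: set = set()
    blockless = []
    for idx in top.index:
        b = snp_block.loc[idx]
        if pd.isna(b):
            blockless.append(idx)
        else:
            out.update(block_gene_map[b])
    if blockless:
        nearest = nearest_gene(gwas_result.loc[blockless], genes)
        out.update(x for x in nearest if pd.notna(x))
    return out


def fct_table(
    gwas_result: pd.DataFrame,
    twas_result: pd.DataFrame,
    genes: pd.DataFrame,
    gwas_fraction: float = 0.10,
) -> pd.DataFrame:
    """Per-gene Fisher's combined test of GWAS and TWAS evidence.

    The nearest gene is assigned to the top ``gwas_fraction`` of GWAS SNPs
    by p-value; each such gene's minimum SNP p is combined with its TWAS p.
    Genes without an assigned top SNP, or absent from the TWAS table, are
    excluded.
    """
    top = top_fraction(gwas_result, gwas_fraction).copy()
    top["gene_id"] = nearest_gene(top, genes).to_numpy()
    gene_p = top.dropna(subset=["gene_id"]).groupby("gene_id")["p"].min()
    merged = (
        twas_result.dropna(subset=["p"])
        .merge(gene_p.rename("p_gwas"), on="gene_id", how="inner")
        .reset_index(drop=True)
    )
    if merged.empty:
        return pd.DataFrame(columns=["gene_id", "p_gwas", "p_twas", "p"])
    combined = fisher_combined(merged[["p_gwas", "p"]].to_numpy())
    return pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "p_gwas": merged["p_gwas"],
            "p_twas": merged["p"],
            "p": combined,
        }
    )


def build_top_sets(
    gwas_results: dict[tuple[str, str], pd.DataFrame],
    twas_results: dict[tuple[str, str, str], pd.DataFrame],
    blocks: pd.DataFrame,
    genes: pd.DataFrame,
    gwas_fraction: float = 0.0005,
    twas_fraction: float = 0.01,
    fct_fraction: float = 0.01,
    fct_gwas_fraction: float = 0.10,
) -> dict[CellKey, set]:
    """All analysis cells: trait x model-year x {GWAS, TWAS+tissue, FCT+tissue}.

    ``gwas_results`` keys are (trait, model_year); ``twas_results`` keys are
    (trait, model_year, tissue).
    """
    top_sets: dict[CellKey, set] = {}
    block_gene_map = genes_in_blocks(blocks, genes)
    snp_block_cache: dict[int, pd.Series] = {}

    for (trait, my), res in gwas_results.items():
        key_id = id(res)
        if key_id not in snp_block_cache:
            snp_block_cache[key_id] = assign_snps_to_blocks(res, blocks)
        top_sets[CellKey(trait, my, "GWAS", "none")] = gwas_cell_genes(
            res, blocks, genes, gwas_fraction, block_gene_map,
            snp_block_cache[key_id],
        )
    for (trait, my, tissue), res in twas_results.items():
        clean = res.dropna(subset=["p"])
        top = top_fraction(clean, twas_fraction)
        top_sets[CellKey(trait, my, "TWAS", tissue)] = set(top["gene_id"])
        gw = gwas_results.get((trait, my))
        if gw is None:
            warnings.warn(f"no GWAS result for {trait}/{my}; FCT cell empty")
            top_sets[CellKey(trait, my, "FCT", tissue)] = set()
            continue
        fct = fct_table(gw, clean, genes, fct_gwas_fraction)
        top_sets[CellKey(trait, my, "FCT", tissue)] = set(
            top_fraction(fct, fct_fraction)["gene_id"]
        )
    return top_sets


# --------------------------------------------------------------- candidates

def overlap_counts(top_sets: dict[CellKey, set]) -> pd.DataFrame:
    """Per-gene ledger: cell count per trait and distinct-trait count."""
    traits = sorted({k.trait for k in top_sets})
    per_gene: dict[str, dict[str, int]] = {}
    for key, gene_set in top_sets.items():
        for g in gene_set:
            per_gene.setdefault(g, {t: 0 for t in traits})[key.trait] += 1
    rows = []
    for g, counts in per_gene.items():
        row = {"gene_id": g, **{f"n_{t}": c for t, c in counts.items()}}
        row["max_analyses"] = max(counts.values())
        row["n_traits"] = sum(1 for c in counts.values() if c > 0)
        rows.append(row)
    ledger = pd.DataFrame(rows)
    if not ledger.empty:
        ledger = ledger.sort_values(
            ["max_analyses", "n_traits", "gene_id"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return ledger


def call_candidates(
    ledger: pd.DataFrame,
    analyses_min: int = 8,
    traits_min: int = 10,
    manual_genes: list | None = None,
) -> pd.DataFrame:
    """Candidate table with the rule(s) that fired per gene.

    Rule 1: >= ``analyses_min`` cells for a single trait; rule 2: top gene
    in >= ``traits_min`` distinct trait columns.  ``manual_genes`` (an
    externally curated list) are merged with a distinct tag.
    """
    if ledger.empty:
        ledger = pd.DataFrame(columns=["gene_id", "max_analyses", "n_traits"])
    df = ledger.copy()
    rule1 = df["max_analyses"] >= analyses_min if len(df) else pd.Series(dtype=bool)
    rule2 = df["n_traits"] >= traits_min if len(df) else pd.Series(dtype=bool)
    df["candidate"] = rule1 | rule2
    df["rule"] = np.select(
        [rule1 & rule2, rule1, rule2],
        ["analyses+traits", "analyses", "traits"],
        default="",
    ) if len(df) else ""
    out = df[df["candidate"]].copy()
    if manual_genes:
        extra = [g for g in manual_genes if g not in set(out["gene_id"])]
        manual = pd.DataFrame(
            {"gene_id": extra, "candidate": True, "rule": "manual-annotation"}
        )
        out = pd.concat([out, manual], ignore_index=True)
    return out.reset_index(drop=True)
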