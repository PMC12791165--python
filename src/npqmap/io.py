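"""Readers for the pipeline's standard input formats."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd


def read_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Load a biallelic-SNP VCF into ``(G, variants, samples)``.

    Dosages are alt-allele counts in {0, 1, 2}; missing genotypes are
    mean-imputed (rounded) with a warning.  Multi-allelic records are
    rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    dosages, rows = [], []
    n_missing = 0
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS}")
        gt = var.gt_types.astype(float)  # 0,1,2; 3 == missing under gts012
        miss = gt == 3
        if miss.any():
            n_missing += int(miss.sum())
            gt[miss] = gt[~miss].mean() if (~miss).any() else 0.0
        dosages.append(gt)
        rows.append(
            {
                "snp_id": var.ID or f"snp{var.CHROM}_{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    if n_missing:
        warnings.warn(f"mean-imputed {n_missing} missing genotype calls")
    G = np.column_stack(dosages) if dosages else np.empty((len(samples), 0))
    variants = pd.DataFrame(rows)
    variants["chrom"] = _numeric_if_possible(variants["chrom"])
    return G, variants, samples


def _numeric_if_possible(s: pd.Series) -> pd.Series:
    try:
        return s.astype(int)
    except (ValueError, TypeError):
        return s


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Load gene features from a GFF3 into (gene_id, chrom, start, end, strand)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for gene in db.features_of_type("gene"):
        rows.append(
            {
                "gene_id": gene.attributes.get("ID", [gene.id])[0],
                "chrom": gene.seqid,
                "start": gene.start,
                "end": gene.end,
                "strand": gene.strand,
            }
        )
    genes = pd.DataFrame(rows)
    genes["chrom"] = _numeric_if_possible(genes["chrom"])
    return genes.sort_values(["chrom", "start"], ignore_index=True)


def read_traces(path: str | Path) -> pd.DataFrame:
    """Read the per-disc fluorescence trace table (CSV)."""
    df = pd.read_csv(path, dtype={"year": str}, comment="#")
    required = {"disc_id", "time_min", "phase", "F", "Fm_prime", "Fo", "Fm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    return df
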