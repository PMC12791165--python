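"""Writers for the synthetic inputs (all plain-text formats)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(
    G: np.ndarray,
    variants: pd.DataFrame,
    accessions: list[str],
    path: str | Path,
) -> Path:
    """Write biallelic dosages as an uncompressed VCF (GT field only)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(variants["chrom"].unique()):
            end = int(variants.loc[variants["chrom"] == c, "pos"].max()) + 1000
            fh.write(f"##contig=<ID={c},length={end}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(accessions)
            + "\n"
        )
        for j, row in enumerate(variants.itertuples(index=False)):
            gts = "\t".join(_GT[int(d)] for d in G[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return path


def write_gff3(genes: pd.DataFrame, path: str | Path) -> Path:
    """Write gene features (only) as GFF3."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tnpqmap_sim\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )
    return path


def write_expression_tsv(E: pd.DataFrame, tissue: str, path: str | Path) -> Path:
    """Write a lines x genes abundance matrix as TSV with a tissue tag."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tissue: {tissue}\n")
        E.to_csv(fh, sep="\t")
    return path


def read_expression_tsv(path: str | Path) -> tuple[pd.DataFrame, str]:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    tissue = first.split(":", 1)[1].strip() if first.startswith("#") else ""
    E = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return E, tissue


def write_truth_json(truth_summary: dict, path: str | Path) -> Path:
    """Machine-readable planted-truth sidecar."""
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    path.write_text(json.dumps(truth_summary, indent=2, default=_default))
    return path
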