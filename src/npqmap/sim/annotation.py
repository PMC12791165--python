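"""Gene annotation paired with the simulated haplotype blocks.

One gene is placed over the span of each simulated LD block (gene index ==
block index), so a causal SNP planted in block *i* lies inside gene *i* and
the expression matrix columns line up with the annotation one-to-one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def simulate_annotation(
    variants: pd.DataFrame,
    pad: int = 500,
    seed: int = 0,
    n_extra: int = 0,
) -> pd.DataFrame:
    """Build a gene table (gene_id, chrom, start, end, strand) from blocks.

    ``variants`` must carry the ``block`` column produced by
    :func:`npqmap.sim.genotypes.simulate_genotypes`.  ``n_extra`` additional
    genes are scattered into the SNP-free gaps between blocks (mimicking
    genes without genotyped markers), with ids continuing after the block
    genes so annotation rows line up with expression matrix columns.
    """
    rng = np.random.default_rng(seed)
    rows = []
    spans = []  # (chrom, block_end, next_block_start) candidate gaps
    prev = None
    for b, grp in variants.groupby("block", sort=True):
        start = max(1, int(grp["pos"].min()) - pad)
        end = int(grp["pos"].max()) + pad
        chrom = int(grp["chrom"].iloc[0])
        rows.append(
            {
                "gene_id": f"gene{int(b):05d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": "+" if rng.uniform() < 0.5 else "-",
            }
        )
        if prev is not None and prev[0] == chrom and start - prev[1] > 4000:
            spans.append((chrom, prev[1] + 1000, start - 1000))
        prev = (chrom, end)
    n_block_genes = len(rows)
    for i in range(n_extra):
        chrom, lo, hi = spans[int(rng.integers(len(spans)))]
        length = int(rng.integers(500, 2000))
        start = int(rng.integers(lo, max(hi - length, lo + 1)))
        rows.append(
            {
                "gene_id": f"gene{n_block_genes + i:05d}",
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "strand": "+" if rng.uniform() < 0.5 else "-",
            }
        )
    genes = pd.DataFrame(rows)
    if (genes["start"] > genes["end"]).any():
        raise AssertionError("gene with start > end")
    return genes
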