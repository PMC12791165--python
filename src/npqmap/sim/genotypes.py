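"""Genotypes with haplotype-block LD structure.

SNPs are organized into blocks; within a block, haplotypes are *nested*: one
uniform draw per haplotype determines carrier status against per-SNP allele
frequencies sorted in decreasing order, so derived-allele carrier sets are
nested subsets.  Nesting forbids recombinant gametes, hence |D'| = 1 for
every within-block pair (while r2 varies with the frequencies), which gives
direct control over Gabriel-style block detection.  Blocks are mutually
independent, so between-block r2 is ~0.  Diploid dosages are the sum of two
independent haplotypes (Hardy-Weinberg).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def simulate_genotypes(
    n_accessions: int,
    n_snps: int,
    block_size_range: tuple[int, int] = (4, 12),
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    n_chrom: int = 2,
    intra_snp_spacing: tuple[int, int] = (200, 2000),
    inter_block_gap: tuple[int, int] = (20_000, 120_000),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate a dosage matrix with LD-block structure.

    Returns ``(G, variants)`` where ``G`` is an (accessions x SNPs) dosage
    matrix in {0, 1, 2} and ``variants`` has columns snp_id, chrom, pos
    (1-based, strictly increasing per chromosome), ref, alt, block
    (block index, shared by SNPs generated from the same haplotype system).
    """
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)

    # Partition SNPs into blocks.
    sizes: list[int] = []
    remaining = n_snps
    while remaining > 0:
        s = int(rng.integers(block_size_range[0], block_size_range[1] + 1))
        sizes.append(min(s, remaining))
        remaining -= sizes[-1]
    n_blocks = len(sizes)

    G = np.empty((n_accessions, n_snps), dtype=np.int8)
    block_of = np.empty(n_snps, dtype=int)
    j = 0
    for b, size in enumerate(sizes):
        freqs = np.sort(rng.uniform(lo, hi, size))[::-1]
        u1 = rng.uniform(size=n_accessions)
        u2 = rng.uniform(size=n_accessions)
        hap1 = (u1[:, None] < freqs[None, :]).astype(np.int8)
        hap2 = (u2[:, None] < freqs[None, :]).astype(np.int8)
        G[:, j : j + size] = hap1 + hap2
        block_of[j : j + size] = b
        j += size

    # Positions: blocks laid sequentially, spread over chromosomes.
    chrom = np.empty(n_snps, dtype=int)
    pos = np.empty(n_snps, dtype=int)
    blocks_per_chrom = int(np.ceil(n_blocks / n_chrom))
    j = 0
    for b, size in enumerate(sizes):
        c = b // blocks_per_chrom + 1
        if b % blocks_per_chrom == 0:
            cursor = 1
        else:
            cursor += int(rng.integers(*inter_block_gap))
        for _ in range(size):
            chrom[j] = c
            pos[j] = cursor
            cursor += int(rng.integers(*intra_snp_spacing))
            j += 1

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n_snps)]
    alt_offset = rng.integers(1, 4, n_snps)
    alt = bases[(np.searchsorted(bases, ref) + alt_offset) % 4]
    variants = pd.DataFrame(
        {
            "snp_id": [f"snp{c}_{p}" for c, p in zip(chrom, pos)],
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "block": block_of,
        }
    )
    return G, variants
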