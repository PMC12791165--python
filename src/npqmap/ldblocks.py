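"""Gabriel-style LD blocks from D' confidence intervals.

For every same-chromosome SNP pair within a 500 kb window (and with
pairwise r^2 above 0.2), two-locus haplotype frequencies are estimated from
unphased genotypes by EM; a 90% confidence interval on |D'| is obtained by
profiling the composite (HWE random-union) likelihood over a |D'| grid with
the EM allele frequencies held fixed.  A pair is in *strong LD* when the
lower CI bound exceeds 0.70 and the upper bound reaches at least 0.98;
*strong recombination* when the upper bound falls below 0.90.  A candidate
block is a pair of strong-LD SNPs spanning at most 500 kb whose enclosed
informative pairs are at least 95% strong LD; candidates are accepted
longest-first without sharing SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CI_GRID = np.arange(0.0, 1.0 + 1e-9, 0.001)


@dataclass
class LDBlock:
    chrom: object
    start: int
    end: int
    snp_ids: list

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def _pair_counts(G: np.ndarray, I: np.ndarray, J: np.ndarray) -> np.ndarray:
    """9-cell genotype count tables for the pair list, shape (P, 9)."""
    code = 3 * G[:, I] + G[:, J]  # (n, P)
    counts = np.empty((I.size, 9), dtype=float)
    for c in range(9):
        counts[:, c] = (code == c).sum(axis=0)
    return counts


def _em_haplotypes(counts: np.ndarray, n_iter: int = 64) -> np.ndarray:
    """EM haplotype frequencies (h11, h10, h01, h00) per pair.

    Cell order in ``counts`` is (a, b) with a = 3-quotient: index 3a + b,
    alleles counted as alt dosage.
    """
    n = counts.sum(axis=1, keepdims=True)
    # fixed haplotype contributions (independent of phase)
    c22, c21, c20 = counts[:, 8], counts[:, 7], counts[:, 6]
    c12, c11, c10 = counts[:, 5], counts[:, 4], counts[:, 3]
    c02, c01, c00 = counts[:, 2], counts[:, 1], counts[:, 0]
    base11 = 2 * c22 + c21 + c12
    base10 = 2 * c20 + c21 + c10
    base01 = 2 * c02 + c12 + c01
    base00 = 2 * c00 + c01 + c10
    total = 2.0 * n[:, 0]
    pA = (base11 + base10 + c11) / total
    pB = (base11 + base01 + c11) / total
    h = np.column_stack(
        [pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)]
    )
    h = np.clip(h, 1e-10, None)
    for _ in range(n_iter):
        w = h[:, 0] * h[:, 3] / (h[:, 0] * h[:, 3] + h[:, 1] * h[:, 2] + 1e-300)
        h11 = base11 + w * c11
        h10 = base10 + (1 - w) * c11
        h01 = base01 + (1 - w) * c11
        h00 = base00 + w * c11
        h = np.column_stack([h11, h10, h01, h00]) / total[:, None]
        h = np.clip(h, 1e-12, None)
    return h


def _dprime(h: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(|D'|, pA, pB, signed D) from haplotype frequencies."""
    pA = h[:, 0] + h[:, 1]
    pB = h[:, 0] + h[:, 2]
    D = h[:, 0] - pA * pB
    dmax = np.where(
        D >= 0,
        np.minimum(pA * (1 - pB), (1 - pA) * pB),
        np.minimum(pA * pB, (1 - pA) * (1 - pB)),
    )
    dmax = np.maximum(dmax, 1e-12)
    return np.abs(D) / dmax, pA, pB, D


def dprime_ci(
    counts: np.ndarray, ci_mass: float = 0.90, chunk: int = 256
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(|D'| point estimate, CI low, CI high) per pair from genotype counts.

    The interval covers the central ``ci_mass`` of the normalized composite
    likelihood over the |D'| grid (step 0.001).
    """
    h = _em_haplotypes(counts)
    dp, pA, pB, D = _dprime(h)
    lo_q = (1.0 - ci_mass) / 2.0
    hi_q = 1.0 - lo_q
    low = np.empty(dp.size)
    high = np.empty(dp.size)
    sign = np.where(D >= 0, 1.0, -1.0)
    dmax = np.where(
        D >= 0,
        np.minimum(pA * (1 - pB), (1 - pA) * pB),
        np.minimum(pA * pB, (1 - pA) * (1 - pB)),
    )
    dmax = np.maximum(dmax, 1e-12)
    for s in range(0, dp.size, chunk):
        e = min(s + chunk, dp.size)
        Dg = (sign[s:e, None] * dmax[s:e, None]) * CI_GRID[None, :]  # (p, g)
        a = pA[s:e, None]
        b = pB[s:e, None]
        h11 = np.clip(a * b + Dg, 1e-12, None)
        h10 = np.clip(a * (1 - b) - Dg, 1e-12, None)
        h01 = np.clip((1 - a) * b - Dg, 1e-12, None)
        h00 = np.clip((1 - a) * (1 - b) + Dg, 1e-12, None)
        cell = np.stack(
            [
                h00**2,
                2 * h01 * h00,
                h01**2,
                2 * h10 * h00,
                2 * (h11 * h00 + h10 * h01),
                2 * h11 * h01,
                h10**2,
                2 * h11 * h10,
                h11**2,
            ],
            axis=-1,
        )  # (p, g, 9), index 3a + b
        ll = np.einsum("pc,pgc->pg", counts[s:e], np.log(cell))
        ll -= ll.max(axis=1, keepdims=True)
        post = np.exp(ll)
        cum = np.cumsum(post, axis=1) / post.sum(axis=1, keepdims=True)
        low[s:e] = CI_GRID[np.argmax(cum >= lo_q, axis=1)]
        high[s:e] = CI_GRID[np.argmax(cum >= hi_q, axis=1)]
    return dp, low, high


def ld_blocks(
    G: np.ndarray,
    variants: pd.DataFrame,
    max_kb: float = 500.0,
    min_maf: float = 0.001,
    r2_prefilter: float = 0.2,
    ci_lower: float = 0.70,
    ci_upper: float = 0.98,
    recomb_upper: float = 0.90,
    strong_fraction: float = 0.95,
) -> pd.DataFrame:
    """Detect LD blocks; returns (chrom, start, end, n_snps, snp_ids)."""
    alt = G.sum(axis=0)
    maf = np.minimum(alt, 2 * G.shape[0] - alt) / (2 * G.shape[0])
    keep = maf >= min_maf
    G = G[:, keep]
    variants = variants.loc[keep].reset_index(drop=True)

    blocks: list[LDBlock] = []
    for chrom, idx in variants.groupby("chrom", sort=True).groups.items():
        idx = np.asarray(idx)
        if idx.size < 2:
            continue
        pos = variants.loc[idx, "pos"].to_numpy()
        ids = variants.loc[idx, "snp_id"].to_numpy()
        Gc = G[:, idx].astype(float)
        m = idx.size

        # Candidate pairs within the window.
        I, J = np.triu_indices(m, k=1)
        span_ok = (pos[J] - pos[I]) <= max_kb * 1000.0
        I, J = I[span_ok], J[span_ok]
        if I.size == 0:
            continue
        # r^2 prefilter.
        Gz = Gc - Gc.mean(axis=0)
        sd = Gz.std(axis=0)
        sd[sd == 0] = np.inf
        Gz = Gz / sd
        r2 = np.einsum("ni,ni->i", Gz[:, I], Gz[:, J]) ** 2 / G.shape[0] ** 2
        informative_mask = r2 > r2_prefilter
        I, J = I[informative_mask], J[informative_mask]
        if I.size == 0:
            continue
        counts = _pair_counts(Gc.astype(int), I, J)
        _, low, high = dprime_ci(counts)
        strong = (low > ci_lower) & (high >= ci_upper)
        recomb = high < recomb_upper
        informative = strong | recomb

        strong_mat = np.zeros((m, m), dtype=bool)
        info_mat = np.zeros((m, m), dtype=bool)
        strong_mat[I[strong], J[strong]] = True
        info_mat[I[informative], J[informative]] = True

        order = np.argsort(
            -(pos[J[strong]] - pos[I[strong]]), kind="stable"
        )
        cand_i, cand_j = I[strong][order], J[strong][order]
        used = np.zeros(m, dtype=bool)
        for a, b in zip(cand_i, cand_j):
            if used[a : b + 1].any():
                continue
            sub_info = info_mat[a : b + 1, a : b + 1]
            sub_strong = strong_mat[a : b + 1, a : b + 1]
            n_info = int(sub_info.sum())
            if n_info == 0:
                continue
            if sub_strong.sum() / n_info < strong_fraction:
                continue
            used[a : b + 1] = True
            blocks.append(
                LDBlock(
                    chrom=chrom,
                    start=int(pos[a]),
                    end=int(pos[b]),
                    snp_ids=list(ids[a : b + 1]),
                )
            )
    rows = [
        {
            "chrom": b.chrom,
            "start": b.start,
            "end": b.end,
            "n_snps": b.n_snps,
            "snp_ids": ",".join(map(str, b.snp_ids)),
        }
        for b in sorted(blocks, key=lambda b: (str(b.chrom), b.start))
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "snp_ids"])
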