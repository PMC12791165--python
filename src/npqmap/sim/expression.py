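"""Expression matrices with hidden confounding factors and planted signals.

Abundance is generated as ``exp(0.5 * (F L' + eps))`` -- a log-normal-like
positive scale -- where ``F`` holds hidden factor scores and ``L`` loadings.
Designated causal genes instead track a per-accession latent (shared with
the phenotype simulator) so a trait-transcript link is planted.  A
configurable fraction of genes is set to zero ("non-expressed") in a random
subset of lines to exercise the expressed-in-at-least-half filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def gene_ids(n_genes: int) -> list[str]:
    return [f"gene{i:05d}" for i in range(n_genes)]


def simulate_expression(
    lines: list[str],
    n_genes: int,
    n_hidden_factors: int,
    causal_latents: pd.DataFrame | None = None,
    causal_expr_scale: float = 1.0,
    sparse_fraction: float = 0.1,
    seed: int = 0,
    tissue: str = "GP",
) -> tuple[pd.DataFrame, dict]:
    """Simulate an abundance matrix (lines x genes) for one tissue.

    ``causal_latents`` columns are causal gene *indices*; the matching gene
    column becomes ``causal_expr_scale * latent + noise`` before the
    positive-scale transform.  Returns ``(E, truth)`` with truth holding the
    factor scores/loadings and the sparsified gene list.
    """
    if n_hidden_factors < 0:
        raise ValueError("n_hidden_factors must be >= 0")
    n_lines = len(lines)
    rng = np.random.default_rng(seed)
    if n_hidden_factors > 0:
        F = rng.standard_normal((n_lines, n_hidden_factors))
        L = rng.standard_normal((n_genes, n_hidden_factors))
        raw = F @ L.T
    else:
        F = np.zeros((n_lines, 0))
        L = np.zeros((n_genes, 0))
        raw = np.zeros((n_lines, n_genes))
    raw = raw + rng.standard_normal((n_lines, n_genes))

    causal_idx: list[int] = []
    if causal_latents is not None:
        for gene_idx in causal_latents.columns:
            gi = int(gene_idx)
            if not 0 <= gi < n_genes:
                raise IndexError(f"causal gene index {gi} out of range")
            z = causal_latents[gene_idx].reindex(lines).to_numpy()
            if np.isnan(z).any():
                raise ValueError("causal latents missing for some lines")
            raw[:, gi] = causal_expr_scale * z + 0.4 * rng.standard_normal(n_lines)
            causal_idx.append(gi)

    E = np.exp(0.5 * raw)

    # Sparsify a random subset of non-causal genes.
    n_sparse = int(round(sparse_fraction * n_genes))
    candidates = np.setdiff1d(np.arange(n_genes), np.array(causal_idx, dtype=int))
    sparse_genes = rng.choice(candidates, size=min(n_sparse, candidates.size),
                              replace=False)
    expressed_frac = {}
    for gi in sparse_genes:
        frac = rng.uniform(0.1, 0.9)
        mask = rng.uniform(size=n_lines) > frac
        E[mask, gi] = 0.0
        expressed_frac[int(gi)] = 1.0 - mask.mean()

    edf = pd.DataFrame(E, index=pd.Index(lines, name="line"), columns=gene_ids(n_genes))
    truth = {
        "tissue": tissue,
        "factors": F,
        "loadings": L,
        "sparse_genes": sorted(int(g) for g in sparse_genes),
        "expressed_frac": expressed_frac,
        "causal_genes": causal_idx,
    }
    return edf, truth
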