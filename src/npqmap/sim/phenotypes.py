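"""Plot- and disc-level kinetic phenotypes with planted genetic truth.

For every kinetic parameter the accession effect is
``g = sum(causal SNP dosage x effect) + sum(causal transcript latent x
effect) + polygenic draw``; the plot value adds a genotype-by-year draw,
set and block-within-set effects, and an AR1xAR1 spatially correlated
residual sampled on the full row-by-column grid via a Kronecker-structured
Cholesky factorization.  Per-disc parameters jitter around the plot value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from npqmap.sim.truth import TruthSpec
from npqmap.traits import KINETIC_PARAMS

#: Hard physical bounds applied to per-disc kinetic parameters.
_PARAM_BOUNDS = {
    "a_npq_i": (0.05, None),
    "k_ind": (0.02, 20.0),
    "a_npq_r": (0.01, None),
    "k_rel": (0.05, 40.0),
    "b_npq": (0.0, None),
    "a_phi": (0.01, 0.95),
    "k_rec": (0.05, 40.0),
    "b_phi": (0.01, 0.9),
    "fvfm": (0.2, 0.92),
}


@dataclass
class SimPhenotypes:
    """Simulation output: per-disc parameters plus the planted components."""

    disc_params: pd.DataFrame
    plot_values: pd.DataFrame
    accession_effects: pd.DataFrame  # genetic value (deviation from mean)


def draw_causal_gene_latents(
    accessions: list[str],
    causal_gene_indices: list[int],
    seed: int,
) -> pd.DataFrame:
    """Standard-normal per-accession latents, one column per causal gene.

    The same latent drives the gene's expression (plus noise) in
    :func:`npqmap.sim.expression.simulate_expression` and its trait effect
    here, planting a trait-transcript link.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(accessions), len(causal_gene_indices)))
    return pd.DataFrame(z, index=pd.Index(accessions, name="accession"),
                        columns=list(causal_gene_indices))


def _ar1_chol(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr + 1e-10 * np.eye(n))


def simulate_phenotypes(
    design: pd.DataFrame,
    G: np.ndarray,
    geno_accessions: list[str],
    truth: TruthSpec,
    expression_truth: pd.DataFrame | None = None,
    discs_per_plot: int = 4,
) -> SimPhenotypes:
    """Simulate kinetic parameters for every plot and disc in ``design``.

    ``geno_accessions`` gives the row order of the dosage matrix ``G``.
    ``expression_truth`` (accession x causal-gene latents) must be supplied
    when ``truth.causal_genes`` is non-empty.
    """
    acc_index = {a: i for i, a in enumerate(geno_accessions)}
    unknown = set(design["accession"]) - set(acc_index)
    if unknown:
        raise ValueError(f"design contains unknown accessions: {sorted(unknown)[:5]}")
    if truth.causal_genes and expression_truth is None:
        raise ValueError("causal genes planted but no expression_truth given")

    ss = np.random.SeedSequence(truth.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["genetic", "gxe", "set", "block", "resid", "disc"], ss.spawn(6)
        )
    }

    accs = list(geno_accessions)
    n_acc = len(accs)
    years = sorted(design["year"].unique())
    n_rows = int(design["row"].max()) + 1
    n_cols = int(design["col"].max()) + 1
    L_r = _ar1_chol(n_rows, truth.spatial_rho_row)
    L_c = _ar1_chol(n_cols, truth.spatial_rho_col)

    # Accession-level genetic values (deviation from the panel mean).
    g_effects = pd.DataFrame(0.0, index=pd.Index(accs, name="accession"),
                             columns=list(KINETIC_PARAMS))
    for param in KINETIC_PARAMS:
        g = streams["genetic"].normal(0.0, truth.genetic_sd[param], n_acc)
        for snp_idx, effects in truth.causal_snps:
            beta = effects.get(param, 0.0)
            if beta:
                g = g + beta * G[:, snp_idx].astype(float)
        for gene_idx, effects in truth.causal_genes:
            beta = effects.get(param, 0.0)
            if beta:
                z = expression_truth[gene_idx].reindex(accs).to_numpy()
                g = g + beta * z
        g_effects[param] = g

    # Year-, set-, block- and spatially-structured components.
    plot_vals = design.copy()
    set_keys = plot_vals[["year", "set"]].apply(tuple, axis=1)
    block_keys = plot_vals[["year", "set", "block"]].apply(tuple, axis=1)
    uniq_sets = sorted(set_keys.unique())
    uniq_blocks = sorted(block_keys.unique())
    acc_rows = plot_vals["accession"].map(acc_index).to_numpy()

    for param in KINETIC_PARAMS:
        mean = truth.kinetic_means[param]
        gxe = {
            (a, y): streams["gxe"].normal(0.0, truth.gxe_sd[param])
            for y in years
            for a in accs
        }
        set_eff = {
            k: streams["set"].normal(0.0, truth.set_sd[param]) for k in uniq_sets
        }
        block_eff = {
            k: streams["block"].normal(0.0, truth.block_sd[param])
            for k in uniq_blocks
        }
        resid_fields = {
            y: truth.resid_sd[param]
            * (L_r @ streams["resid"].standard_normal((n_rows, n_cols)) @ L_c.T)
            for y in years
        }
        vals = (
            mean
            + g_effects[param].to_numpy()[acc_rows]
            + np.array(
                [gxe[(a, y)] for a, y in zip(plot_vals["accession"], plot_vals["year"])]
            )
            + set_keys.map(set_eff).to_numpy()
            + block_keys.map(block_eff).to_numpy()
            + np.array(
                [
                    resid_fields[y][r, c]
                    for y, r, c in zip(
                        plot_vals["year"], plot_vals["row"], plot_vals["col"]
                    )
                ]
            )
        )
        plot_vals[param] = vals

    # Per-disc jitter around the plot value.
    reps = np.tile(np.arange(1, discs_per_plot + 1), len(plot_vals))
    disc = plot_vals.loc[plot_vals.index.repeat(discs_per_plot)].reset_index(drop=True)
    disc["replicate"] = reps
    disc["disc_id"] = disc["plot"] + "_d" + disc["replicate"].astype(str)
    for param in KINETIC_PARAMS:
        jit = streams["disc"].normal(0.0, truth.disc_sd[param], len(disc))
        lo, hi = _PARAM_BOUNDS[param]
        disc[param] = np.clip(disc[param] + jit, lo, hi)

    meta = ["disc_id", "accession", "plot", "replicate", "year"]
    disc_params = disc[meta + list(KINETIC_PARAMS)]
    return SimPhenotypes(
        disc_params=disc_params,
        plot_values=plot_vals,
        accession_effects=g_effects,
    )
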