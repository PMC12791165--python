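"""Augmented block field design with replicated check accessions.

Each non-check accession is planted once per year; a small number of check
accessions is repeated in every incomplete block, connecting the blocks so
that block and set effects are estimable.  Plots are laid out on a
row-by-column grid (the real trial used 960 four-row plots on a 40 x 24
grid in 16 blocks), which carries the AR1xAR1 spatial residual structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DESIGN_COLUMNS = [
    "plot",
    "row",
    "col",
    "block",
    "set",
    "accession",
    "year",
    "is_check",
]


def accession_ids(n_accessions: int, n_checks: int) -> tuple[list[str], list[str]]:
    """Accession labels: checks first, then unique entries."""
    checks = [f"CHK{i:02d}" for i in range(n_checks)]
    uniques = [f"ACC{i:04d}" for i in range(n_accessions - n_checks)]
    return checks, uniques


def build_design(
    n_accessions: int,
    n_blocks: int,
    n_checks: int,
    rows: int,
    cols: int,
    seed: int,
    years: tuple[str, ...] = ("2017", "2019"),
    blocks_per_set: int = 4,
) -> pd.DataFrame:
    """Randomized augmented block design over a ``rows x cols`` plot grid.

    ``n_accessions`` counts all accessions including the ``n_checks`` checks.
    Every check appears once in each block; each of the remaining accessions
    appears in exactly one block per year.  Blocks are contiguous runs of
    plots in field order and are grouped into sets of ``blocks_per_set``.

    Returns a long table with one row per plot and year
    (columns: plot, row, col, block, set, accession, year, is_check).
    """
    if n_checks < 1:
        raise ValueError(
            "at least one check accession is required to connect blocks"
        )
    if n_blocks < 1 or n_accessions <= n_checks:
        raise ValueError("need at least one block and one non-check accession")
    n_unique = n_accessions - n_checks
    n_plots = n_unique + n_blocks * n_checks
    if n_plots > rows * cols:
        raise ValueError(
            f"design needs {n_plots} plots but the grid has only {rows * cols}"
        )

    checks, uniques = accession_ids(n_accessions, n_checks)
    # Split unique accessions across blocks as evenly as possible.
    base, extra = divmod(n_unique, n_blocks)
    block_sizes = [base + (1 if b < extra else 0) + n_checks for b in range(n_blocks)]

    # Field order: fill the grid column-major (plots run down each column).
    grid_rows, grid_cols = np.unravel_index(np.arange(n_plots), (rows, cols), order="F")

    rng_root = np.random.default_rng(seed)
    frames = []
    for year in years:
        rng = np.random.default_rng(rng_root.integers(2**31))
        entries = list(uniques)
        rng.shuffle(entries)
        plot_accessions: list[str] = []
        plot_blocks: list[int] = []
        start = 0
        for b, size in enumerate(block_sizes):
            members = checks + entries[start : start + size - n_checks]
            start += size - n_checks
            members = list(members)
            rng.shuffle(members)
            plot_accessions.extend(members)
            plot_blocks.extend([b] * size)
        frames.append(
            pd.DataFrame(
                {
                    "plot": [f"{year}_P{i:04d}" for i in range(n_plots)],
                    "row": grid_rows.astype(int),
                    "col": grid_cols.astype(int),
                    "block": [f"B{b:02d}" for b in plot_blocks],
                    "set": [f"S{b // blocks_per_set:02d}" for b in plot_blocks],
                    "accession": plot_accessions,
                    "year": year,
                    "is_check": [a in set(checks) for a in plot_accessions],
                }
            )
        )
    design = pd.concat(frames, ignore_index=True)[DESIGN_COLUMNS]
    return design
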