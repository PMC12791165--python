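"""Published descriptive statistics of the 861-accession sorghum NPQ panel.

Joint-model adjusted genotype means (BLUP-adjusted) for the nine headline
photoprotection traits of the two-year field screen, kept here as reference
values for sanity checks and for computing the percentage spread between the
lowest- and highest-ranked accessions.
"""

from __future__ import annotations

import pandas as pd

# trait -> (mean, min, max, H2) of joint-model adjusted genotype means
_JOINT_STATS = {
    "max_npq": (2.80, 2.50, 3.10, 0.52),
    "ind_slope": (1.29, 0.92, 1.72, 0.58),
    "rel_slope": (-2.68, -3.20, -2.19, 0.67),
    "ind_k": (0.58, 0.39, 0.84, 0.67),
    "rel_k": (5.09, 3.68, 6.87, 0.44),
    "npqf": (0.89, 0.69, 1.12, 0.47),
    "rec_k": (5.08, 3.97, 6.48, 0.43),
    "pi": (0.82, 0.76, 0.85, 0.36),
    "fvfm": (0.75, 0.73, 0.77, 0.30),
}


def joint_trait_stats() -> pd.DataFrame:
    """Reference joint-model trait statistics (mean, min, max, H2)."""
    df = pd.DataFrame.from_dict(
        _JOINT_STATS, orient="index", columns=["mean", "min", "max", "H2"]
    )
    df.index.name = "trait"
    return df


def range_spread_percent(lo: float, hi: float) -> float:
    """Percentage difference between the lowest and highest accession.

    Defined as ``(max - min) / min * 100`` on adjusted genotype means; for
    negative-valued traits the magnitudes are used.
    """
    lo, hi = abs(lo), abs(hi)
    lo, hi = min(lo, hi), max(lo, hi)
    if lo == 0:
        raise ValueError("range spread undefined for a zero minimum")
    return (hi - lo) / lo * 100.0


def joint_range_spreads() -> pd.Series:
    """Range spread (percent) per trait from the reference statistics."""
    stats = joint_trait_stats()
    return pd.Series(
        {
            t: range_spread_percent(row["min"], row["max"])
            for t, row in stats.iterrows()
        },
        name="range_spread_percent",
    )
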