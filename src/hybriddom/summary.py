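"""Headline summary statistics of a three-contrast analysis.

Per-contrast DE counts with up/down directions, the divergence-ratio
statistic (how much farther the hybrid transcriptome sits from each
parent than the parents sit from each other, measured in DE-gene
counts), and the up/down asymmetry chi-squared between the two
hybrid-vs-parent contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency


def de_summary(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """One row per contrast: tested/significant/up/down counts and the
    percentage of tested genes called DE."""
    rows = []
    for name, df in results.items():
        tested = int(df["tested"].sum())
        de = df["de"].astype(bool)
        n_sig = int(de.sum())
        n_up = int((df.loc[de, "direction"] > 0).sum())
        n_down = int((df.loc[de, "direction"] < 0).sum())
        pct = 100.0 * n_sig / tested if tested else np.nan
        rows.append((name, tested, n_sig, n_up, n_down, pct))
    return pd.DataFrame(
        rows,
        columns=["contrast", "n_tested", "n_significant", "n_up", "n_down", "pct_of_tested"],
    )


def divergence_ratio(n_h_vs_p1: int, n_h_vs_p2: int, n_p1_vs_p2: int) -> float:
    """Mean hybrid-vs-parent DE count over the parent-vs-parent DE count.

    Returns NaN when the parent-vs-parent count is zero (undefined).
    """
    if min(n_h_vs_p1, n_h_vs_p2, n_p1_vs_p2) < 0:
        raise ValueError("DE counts must be non-negative")
    if n_p1_vs_p2 == 0:
        return float("nan")
    return 0.5 * (n_h_vs_p1 + n_h_vs_p2) / n_p1_vs_p2


def divergence_report(n_h_vs_p1: int, n_h_vs_p2: int, n_p1_vs_p2: int) -> dict:
    """Raw and rounded divergence ratios, plus each single-contrast ratio."""
    r = divergence_ratio(n_h_vs_p1, n_h_vs_p2, n_p1_vs_p2)
    denom = n_p1_vs_p2 if n_p1_vs_p2 else np.nan
    return {
        "ratio": r,
        "ratio_rounded": int(round(r)) if np.isfinite(r) else None,
        "ratio_h_vs_p1": n_h_vs_p1 / denom,
        "ratio_h_vs_p2": n_h_vs_p2 / denom,
    }


def updown_chisq(
    up_a: int, down_a: int, up_b: int, down_b: int, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared (df=1) on the 2x2 up/down-by-contrast table.

    No continuity correction by default; set ``correction=True`` for
    Yates. Raises on a zero row or column margin (expected counts
    undefined).
    """
    table = np.array([[up_a, down_a], [up_b, down_b]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-squared undefined: zero row or column margin")
    res = chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)
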