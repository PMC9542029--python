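"""Inheritance-mode classification of hybrid gene expression.

Each gene is classified from its two hybrid-vs-parent contrasts
(shrunken LFCs oriented hybrid over parent).  A gene deviates from a
parent (D) when padj < alpha and |LFC| > threshold.  Neither deviation:
conserved.  Both, same sign: over-dominant (up) or under-dominant
(down) — together transgressive.  Both, opposite signs: additive.
Deviation from exactly one parent: dominant for the other (matched)
parent.  Remaining patterns fall into an explicit ``ambiguous`` bin
rather than being misfiled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORIES = (
    "conserved",
    "additive",
    "dominant_p1",
    "dominant_p2",
    "over_dominant",
    "under_dominant",
    "ambiguous",
)


def classify_gene(
    r_h_p1,
    r_h_p2,
    lfc_threshold: float = 0.32,
    alpha: float = 0.05,
) -> str:
    """Classify one gene from its two hybrid-vs-parent records.

    Each record is a mapping with keys ``padj`` and ``lfc_shrunk``
    (LFC oriented hybrid over parent).
    """
    p1, l1 = r_h_p1["padj"], r_h_p1["lfc_shrunk"]
    p2, l2 = r_h_p2["padj"], r_h_p2["lfc_shrunk"]
    for name, p in (("hybrid-vs-parent1", p1), ("hybrid-vs-parent2", p2)):
        if p is None or (isinstance(p, float) and np.isnan(p)):
            raise ValueError(f"missing padj in {name} record for a tested gene")
    d1 = p1 < alpha and abs(l1) > lfc_threshold
    d2 = p2 < alpha and abs(l2) > lfc_threshold
    if not d1 and not d2:
        return "conserved"
    if d1 and d2:
        if l1 > lfc_threshold and l2 > lfc_threshold:
            return "over_dominant"
        if l1 < -lfc_threshold and l2 < -lfc_threshold:
            return "under_dominant"
        if l1 * l2 < 0:
            return "additive"
        return "ambiguous"
    # deviates from exactly one parent: dominant for the similar parent
    return "dominant_p1" if (d2 and not d1) else "dominant_p2"


def classify_all(
    res_h_p1: pd.DataFrame,
    res_h_p2: pd.DataFrame,
    lfc_threshold: float = 0.32,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify every gene tested in both hybrid-vs-parent contrasts.

    The background (``in_background=True``) is the intersection of
    genes tested in both contrasts; genes outside it receive no call.
    Returns one row per gene of the union, with columns gene_id,
    category, lfc_h_vs_p1, lfc_h_vs_p2, sig_h_vs_p1, sig_h_vs_p2,
    in_background.
    """
    for name, df in (("hybrid-vs-parent1", res_h_p1), ("hybrid-vs-parent2", res_h_p2)):
        if df["gene_id"].duplicated().any():
            dups = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"])
            raise ValueError(f"duplicated gene_id in {name} table: {dups[:10]}")
    a = res_h_p1.set_index("gene_id")
    b = res_h_p2.set_index("gene_id")
    genes = a.index.union(b.index, sort=False)
    a = a.reindex(genes)
    b = b.reindex(genes)

    tested1 = a["tested"].fillna(False).to_numpy(dtype=bool)
    tested2 = b["tested"].fillna(False).to_numpy(dtype=bool)
    background = tested1 & tested2

    p1 = a["padj"].to_numpy(dtype=float)
    p2 = b["padj"].to_numpy(dtype=float)
    l1 = a["lfc_shrunk"].to_numpy(dtype=float)
    l2 = b["lfc_shrunk"].to_numpy(dtype=float)
    if (background & (np.isnan(p1) | np.isnan(p2))).any():
        raise ValueError("missing padj for genes tested in both contrasts")

    d1 = background & (p1 < alpha) & (np.abs(l1) > lfc_threshold)
    d2 = background & (p2 < alpha) & (np.abs(l2) > lfc_threshold)
    both = d1 & d2
    category = np.select(
        [
            ~d1 & ~d2,
            both & (l1 > lfc_threshold) & (l2 > lfc_threshold),
            both & (l1 < -lfc_threshold) & (l2 < -lfc_threshold),
            both & (l1 * l2 < 0),
            both,
            d2 & ~d1,
            d1 & ~d2,
        ],
        [
            "conserved",
            "over_dominant",
            "under_dominant",
            "additive",
            "ambiguous",
            "dominant_p1",
            "dominant_p2",
        ],
        default="conserved",
    ).astype(object)
    category[~background] = None

    return pd.DataFrame(
        {
            "gene_id": genes,
            "category": category,
            "lfc_h_vs_p1": l1,
            "lfc_h_vs_p2": l2,
            "sig_h_vs_p1": d1,
            "sig_h_vs_p2": d2,
            "in_background": background,
        }
    ).reset_index(drop=True)


def inheritance_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Tally of calls per category with percentages of the background.

    Returns one row per category plus derived ``transgressive``
    (over + under dominant) and ``nonconserved`` (background minus
    conserved) rows; percentages are relative to the background size
    and rounded to two decimals.  Raw counts and an exact ``fraction``
    column are included alongside.
    """
    in_bg = calls[calls["in_background"].astype(bool)] if "in_background" in calls else calls
    n_bg = len(in_bg)
    counts = in_bg["category"].value_counts()
    rows = []
    for cat in CATEGORIES:
        c = int(counts.get(cat, 0))
        rows.append((cat, c))
    tally = dict(rows)
    transgressive = tally["over_dominant"] + tally["under_dominant"]
    nonconserved = n_bg - tally["conserved"]
    rows.append(("transgressive", transgressive))
    rows.append(("nonconserved", nonconserved))
    rows.append(("background", n_bg))
    out = pd.DataFrame(rows, columns=["category", "count"])
    frac = out["count"] / n_bg if n_bg else np.nan
    out["fraction"] = frac
    out["percent"] = np.round(100.0 * out["fraction"], 2)
    return out
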