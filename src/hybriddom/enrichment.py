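"""Hypergeometric over-representation tests.

Covers (i) enrichment of a chromosome category (typically the avian Z)
among differentially expressed genes, with unanchored scaffolds
excluded from the urn, and (ii) generic GO-term over-representation of
a DE gene set against a tested-gene background with Benjamini-Hochberg
correction across terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust

RESULT_COLUMNS = ["term_id", "term_name", "k", "K", "n", "N", "pvalue", "padj", "enriched"]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    N is the urn size, K the number of marked items, n the draw size
    and k the observed number of marked draws.
    """
    if not 0 <= K <= N:
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"require 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    return float(hypergeom.sf(k - 1, N, K, n))


def chromosome_enrichment(
    de_flags: pd.Series,
    annotation: pd.DataFrame,
    category: str = "Z",
) -> pd.Series:
    """Over-representation of one chromosome category among DE genes.

    ``de_flags`` is a boolean Series indexed by gene_id over the tested
    background; ``annotation`` carries gene_id and chrom_category.  The
    urn is restricted to genes categorised as ``category`` or autosome
    (unanchored scaffolds are excluded).
    """
    ann = annotation.set_index("gene_id")["chrom_category"]
    cat = ann.reindex(de_flags.index)
    keep = cat.isin([category, "autosome"])
    if not keep.any():
        raise ValueError("empty background after excluding unanchored genes")
    de = de_flags[keep].astype(bool)
    is_cat = (cat[keep] == category).to_numpy()
    N = int(keep.sum())
    K = int(is_cat.sum())
    n = int(de.sum())
    k = int((de.to_numpy() & is_cat).sum())
    p = hypergeom_upper(k, K, n, N)
    return pd.Series(
        {
            "term_id": category,
            "term_name": f"{category} chromosome",
            "k": k,
            "K": K,
            "n": n,
            "N": N,
            "pvalue": p,
            "padj": p,
            "enriched": p < 0.05,
        }
    )


def go_ora(
    de_genes,
    background,
    annotations: pd.DataFrame,
    alpha: float = 0.05,
    min_term_size: int = 5,
) -> pd.DataFrame:
    """Flat GO over-representation of ``de_genes`` against ``background``.

    One upper-tail hypergeometric test per term with at least
    ``min_term_size`` background genes; BH correction across the tested
    terms; ``enriched`` iff padj < alpha.  Rows are sorted by p-value.
    """
    de = set(de_genes)
    bg = set(background)
    offenders = sorted(de - bg)
    if offenders:
        raise ValueError(f"DE genes absent from background: {offenders[:20]}")
    ann = annotations[annotations["gene_id"].isin(bg)]
    N, n = len(bg), len(de)
    rows = []
    for (term_id, term_name), sub in ann.groupby(["term_id", "term_name"], sort=True):
        members = set(sub["gene_id"])
        K = len(members)
        if K < min_term_size:
            continue
        k = len(members & de)
        rows.append((term_id, term_name, k, K, n, N, hypergeom_upper(k, K, n, N)))
    if not rows or n == 0:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "pvalue"])
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out["enriched"] = out["padj"] < alpha
    return out.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
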