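"""Median-of-ratios library-size normalization.

Each sample's size factor is the median, over reference genes, of the
ratio of that sample's count to the gene's geometric mean across all
samples.  Reference genes are those with no zero count (their geometric
mean is positive); geometric means are computed in log space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import CountMatrix


def size_factors_median_of_ratios(cm: CountMatrix) -> pd.Series:
    """Per-sample size factors by the median-of-ratios method.

    Raises if no gene has strictly positive counts in every sample
    (no reference set exists).
    """
    counts = cm.counts.astype(float)
    ref = (counts > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has positive counts in every sample; the median-of-"
            "ratios reference set is empty (sequence deeper or use a "
            "pseudo-reference)"
        )
    logc = np.log(counts[ref])
    log_geo = logc.mean(axis=1)
    ratios = np.exp(logc - log_geo[:, None])
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=list(cm.sample_ids), name="s")


def normalize(cm: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Counts divided by their sample's size factor."""
    missing = [s for s in cm.sample_ids if s not in factors.index]
    if missing:
        raise KeyError(f"size factor missing for samples: {missing}")
    s = factors.reindex(list(cm.sample_ids)).to_numpy(dtype=float)
    if (s <= 0).any() or not np.isfinite(s).all():
        raise ValueError("size factors must be finite and positive")
    return pd.DataFrame(
        cm.counts / s[None, :],
        index=pd.Index(cm.gene_ids, name="gene_id"),
        columns=list(cm.sample_ids),
    )
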