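"""Negative-binomial Wald differential expression for two-group contrasts.

The model is the standard NB GLM with log link, design
``intercept + group`` and offsets ``log(size factor)``; with a
group-saturated design the group log-means are exact 1-D MLEs obtained
by Newton root-finding on the score equation, vectorized across genes.
Gene-wise dispersions (var = mu + alpha*mu^2) are maximum-likelihood
estimates shrunk in log space toward a fitted mean-dispersion trend
alpha(mu) = a0/mu + a1.  Log2 fold changes are additionally shrunk with
a zero-centred normal prior; multiple testing uses Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, polygamma
from scipy.stats import norm

from .io_formats import CountMatrix
from .normalization import normalize

LN2 = math.log(2.0)

ALPHA_FLOOR = 1e-8
ALPHA_CEILING = 10.0


@dataclass(frozen=True)
class ContrastSpec:
    """A pairwise comparison; LFC is oriented log2(mean_a / mean_b)."""

    name: str
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")

    def flipped(self) -> "ContrastSpec":
        return ContrastSpec(self.name + "_flipped", self.group_b, self.group_a)


def prefilter(
    cm: CountMatrix,
    sample_ids,
    min_count: int = 10,
    min_fraction: float = 0.5,
) -> pd.Series:
    """Tested-gene mask: raw count >= ``min_count`` in at least
    ``ceil(min_fraction * n_samples)`` of the contrast's samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    sub = cm.select_samples(list(sample_ids))
    need = math.ceil(min_fraction * sub.n_samples)
    ok = (sub.counts >= min_count).sum(axis=1) >= need
    return pd.Series(ok, index=list(cm.gene_ids), name="tested")


# ---------------------------------------------------------------------------
# dispersion estimation


def _nb_loglik(counts, mu, log_alpha, group_cols=None):
    """NB log-likelihood summed over samples; vectorized over genes.

    counts, mu: (genes, samples); log_alpha: (genes,).  When
    ``group_cols`` (list of per-group column index arrays) is given,
    the Cox-Reid adjustment -0.5*log det(X'WX) for the group-saturated
    design is included, removing the downward bias of the dispersion
    MLE caused by estimating the group means from the same data.
    """
    r = np.exp(-log_alpha)[:, None]
    mu = np.maximum(mu, 1e-10)
    ll = (
        gammaln(counts + r)
        - gammaln(r)
        - gammaln(counts + 1.0)
        + r * np.log(r / (r + mu))
        + counts * np.log(mu / (r + mu))
    ).sum(axis=1)
    if group_cols is not None:
        alpha = np.exp(log_alpha)[:, None]
        w = mu / (1.0 + alpha * mu)
        for cols in group_cols:
            ll = ll - 0.5 * np.log(w[:, cols].sum(axis=1))
    return ll


def _golden_max(f, lo: float, hi: float, n_genes: int, iters: int = 60):
    """Vectorized golden-section maximisation of per-gene unimodal f."""
    inv_phi = (math.sqrt(5.0) - 1.0) / 2.0
    a = np.full(n_genes, lo)
    b = np.full(n_genes, hi)
    c = b - inv_phi * (b - a)
    d = a + inv_phi * (b - a)
    fc = f(c)
    fd = f(d)
    for _ in range(iters):
        left = fc >= fd
        b[left] = d[left]
        d[left] = c[left]
        fd[left] = fc[left]
        c[left] = b[left] - inv_phi * (b[left] - a[left])
        right = ~left
        a[right] = c[right]
        c[right] = d[right]
        fc[right] = fd[right]
        d[right] = a[right] + inv_phi * (b[right] - a[right])
        new = np.where(left, c, d)
        fnew = f(new)
        fc = np.where(left, fnew, fc)
        fd = np.where(right, fnew, fd)
    return (a + b) / 2.0


def estimate_dispersions(
    cm: CountMatrix,
    factors: pd.Series,
    groups: pd.Series,
    prior_var: float = 0.25,
    floor: float = ALPHA_FLOOR,
    ceiling: float = ALPHA_CEILING,
) -> pd.DataFrame:
    """Gene-wise, trend and shrunk dispersion estimates.

    ``groups`` maps sample_id -> group label; group means of normalized
    counts are held fixed while the per-gene dispersion is profiled by
    maximum likelihood.  The trend alpha(mu) = a0/mu + a1 is fitted by
    non-negative least squares with iterative outlier exclusion, and the
    final estimate is the log-space posterior combining the gene-wise
    likelihood (variance approximated by trigamma((m - p)/2)) with a
    normal prior of variance ``prior_var`` centred on the trend.
    """
    sample_ids = list(cm.sample_ids)
    grp = groups.reindex(sample_ids)
    if grp.isna().any():
        raise KeyError(f"group labels missing for {list(grp.index[grp.isna()])}")
    q = normalize(cm, factors).to_numpy()
    s = factors.reindex(sample_ids).to_numpy(dtype=float)
    counts = cm.counts.astype(float)

    labels = grp.to_numpy()
    uniq = pd.unique(labels)
    qbar = np.empty_like(q)
    for g in uniq:
        m = labels == g
        qbar[:, m] = q[:, m].mean(axis=1, keepdims=True)
    mu = s[None, :] * qbar

    n_genes = cm.n_genes
    lo, hi = math.log(floor), math.log(ceiling)
    group_cols = [np.flatnonzero(labels == g) for g in uniq]
    log_alpha = _golden_max(
        lambda la: _nb_loglik(counts, mu, la, group_cols), lo, hi, n_genes
    )
    # pull estimates indistinguishable from the boundary onto it
    at_floor = log_alpha < lo + 2.0
    log_alpha[at_floor] = lo
    alpha_gene = np.exp(log_alpha)

    mean_norm = q.mean(axis=1)
    a0, a1 = _fit_trend(mean_norm, alpha_gene, at_floor, floor)
    alpha_trend = np.clip(a0 / np.maximum(mean_norm, 1e-10) + a1, floor, ceiling)

    m_samples, p_params = len(sample_ids), len(uniq)
    s2 = float(polygamma(1, max(m_samples - p_params, 1) / 2.0))
    w = (1.0 / s2) / (1.0 / s2 + 1.0 / prior_var)
    log_final = w * np.log(alpha_gene) + (1.0 - w) * np.log(alpha_trend)
    # genes at the likelihood floor carry no dispersion signal: use the trend
    log_final[at_floor] = np.log(alpha_trend[at_floor])
    alpha_final = np.clip(np.exp(log_final), floor, ceiling)

    out = pd.DataFrame(
        {
            "gene_id": list(cm.gene_ids),
            "mean_norm": mean_norm,
            "alpha_gene": alpha_gene,
            "alpha_trend": alpha_trend,
            "alpha_final": alpha_final,
            "at_floor": at_floor,
        }
    )
    out.attrs["trend_coefficients"] = {"a0": float(a0), "a1": float(a1)}
    return out


def _fit_trend(mean_norm, alpha_gene, at_floor, floor, max_iter: int = 10):
    """Fit alpha ~ a0/mu + a1 by NNLS with iterative outlier exclusion."""
    from scipy.optimize import nnls

    use = (~at_floor) & (mean_norm > 0)
    if use.sum() < 2:
        return 0.0, max(float(np.median(alpha_gene)), floor)
    x = 1.0 / mean_norm
    a0, a1 = 0.0, float(np.median(alpha_gene[use]))
    for _ in range(max_iter):
        A = np.column_stack([x[use], np.ones(use.sum())])
        coef, _ = nnls(A, alpha_gene[use])
        a0_new, a1_new = float(coef[0]), float(coef[1])
        pred = a0_new * x + a1_new
        ratio = alpha_gene / np.maximum(pred, 1e-12)
        keep = (~at_floor) & (mean_norm > 0) & (ratio > 1e-4) & (ratio < 15.0)
        converged = abs(a0_new - a0) <= 1e-8 * (1 + abs(a0)) and abs(
            a1_new - a1
        ) <= 1e-8 * (1 + abs(a1))
        a0, a1 = a0_new, a1_new
        if converged or keep.sum() < 2 or keep.sum() == use.sum():
            break
        use = keep
    return a0, max(a1, 0.0)


# ---------------------------------------------------------------------------
# Wald test


def _fit_group_logmean(counts, s, alpha, tol: float = 1e-12, max_iter: int = 100):
    """Exact NB GLM MLE of the per-gene group log-mean with offsets log(s).

    Solves the score equation sum_j (c_j - mu_j) / (1 + alpha*mu_j) = 0
    with mu_j = s_j * exp(beta) by Newton iteration (the score is
    strictly decreasing in beta, so iteration is globally stable).
    Returns (beta, fisher_information).
    """
    counts = np.asarray(counts, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    tot = counts.sum(axis=1)
    beta = np.log(np.maximum(tot, 0.5) / s.sum())
    for _ in range(max_iter):
        mu = s[None, :] * np.exp(beta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((counts - mu) / denom).sum(axis=1)
        dscore = -(mu * (1.0 + alpha[:, None] * counts) / denom**2).sum(axis=1)
        step = score / dscore
        beta = beta - step
        if np.max(np.abs(step)) < tol:
            break
    mu = s[None, :] * np.exp(beta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return beta, info


def wald_test(
    cm: CountMatrix,
    factors: pd.Series,
    contrast: ContrastSpec,
    samples: pd.DataFrame,
    disp: pd.DataFrame,
    tested: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test for one contrast.

    Returns a table with one row per gene of the matrix: base_mean (mean
    normalized count over the contrast's samples), lfc_mle and se in
    log2 units, the Wald statistic, two-sided normal p-value, and a
    ``tested`` flag; p-values of untested genes are NaN.  Genes with an
    all-zero group are fitted after adding a 0.5 pseudo-count and
    flagged in ``pseudo_fallback``.  Benjamini-Hochberg adjustment over
    tested genes fills ``padj``; ``lfc_shrunk`` is initialised to the
    MLE and updated by :func:`shrink_lfc`.
    """
    by_group = samples.groupby("group")["sample_id"].apply(list).to_dict()
    for g in (contrast.group_a, contrast.group_b):
        if g not in by_group:
            raise KeyError(f"group {g!r} absent from sample table")
        if len(by_group[g]) < 2:
            raise ValueError(f"group {g!r} has <2 replicates")
    ids_a, ids_b = by_group[contrast.group_a], by_group[contrast.group_b]
    contrast_ids = ids_a + ids_b

    if tested is None:
        tested = prefilter(cm, contrast_ids)
    tested = tested.reindex(list(cm.gene_ids)).fillna(False).astype(bool)

    alpha = (
        disp.set_index("gene_id")["alpha_final"]
        .reindex(list(cm.gene_ids))
        .to_numpy(dtype=float)
    )
    if np.isnan(alpha[tested.to_numpy()]).any():
        raise ValueError("dispersion estimates missing for tested genes")
    alpha = np.where(np.isnan(alpha), ALPHA_FLOOR, alpha)

    sub = cm.select_samples(contrast_ids)
    q = normalize(sub, factors)
    base_mean = q.to_numpy().mean(axis=1)

    mask = tested.to_numpy()
    idx = np.flatnonzero(mask)
    ca = cm.select_samples(ids_a).counts[idx].astype(float)
    cb = cm.select_samples(ids_b).counts[idx].astype(float)
    sa = factors.reindex(ids_a).to_numpy(dtype=float)
    sb = factors.reindex(ids_b).to_numpy(dtype=float)
    al = alpha[idx]

    pseudo = (ca.sum(axis=1) == 0) | (cb.sum(axis=1) == 0)
    if pseudo.any():
        ca = ca.copy()
        cb = cb.copy()
        ca[pseudo] += 0.5
        cb[pseudo] += 0.5
    beta_a, info_a = _fit_group_logmean(ca, sa, al)
    beta_b, info_b = _fit_group_logmean(cb, sb, al)

    lfc = (beta_a - beta_b) / LN2
    se = np.sqrt(1.0 / info_a + 1.0 / info_b) / LN2
    stat = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    pval = 2.0 * norm.sf(np.abs(stat))

    n = cm.n_genes
    full = lambda v, fill=np.nan: _scatter(v, idx, n, fill)
    res = pd.DataFrame(
        {
            "gene_id": list(cm.gene_ids),
            "base_mean": base_mean,
            "lfc_mle": full(lfc),
            "lfc_shrunk": full(lfc),
            "se": full(se),
            "wald_stat": full(stat),
            "pvalue": full(pval),
            "padj": np.nan,
            "tested": mask,
            "pseudo_fallback": _scatter(pseudo.astype(float), idx, n, 0.0) > 0,
        }
    )
    res.loc[mask, "padj"] = bh_adjust(res.loc[mask, "pvalue"].to_numpy())
    res.attrs["contrast"] = {
        "name": contrast.name,
        "group_a": contrast.group_a,
        "group_b": contrast.group_b,
    }
    return res


def _scatter(values, idx, n, fill):
    out = np.full(n, fill, dtype=float)
    out[idx] = values
    return out


def shrink_lfc(result: pd.DataFrame, prior_scale="auto") -> pd.DataFrame:
    """Shrink log2 fold changes with a zero-centred normal prior.

    The posterior mean is ``lfc * tau^2 / (tau^2 + se^2)``; with
    ``prior_scale="auto"`` the prior variance tau^2 is a method-of-
    moments estimate ``max(var(lfc_mle) - mean(se^2), 1e-6)`` over
    tested genes.  Sign is preserved and magnitude never increased.
    """
    res = result.copy()
    mask = res["tested"].to_numpy(dtype=bool)
    lfc = res["lfc_mle"].to_numpy(dtype=float)
    se = res["se"].to_numpy(dtype=float)
    if prior_scale == "auto":
        if mask.sum() == 0:
            return res
        tau2 = max(float(np.var(lfc[mask]) - np.mean(se[mask] ** 2)), 1e-6)
    else:
        if prior_scale <= 0:
            raise ValueError("prior_scale must be positive")
        tau2 = float(prior_scale) ** 2
    shrunk = lfc * tau2 / (tau2 + se**2)
    res["lfc_shrunk"] = np.where(mask, shrunk, np.nan)
    res.attrs.update(result.attrs)
    res.attrs["lfc_prior_var"] = tau2
    return res


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_de(
    result: pd.DataFrame, alpha: float = 0.05, lfc_threshold: float = 0.32
) -> pd.DataFrame:
    """Flag differential expression: padj < alpha and |shrunken LFC| > threshold."""
    res = result.copy()
    padj = res["padj"].to_numpy(dtype=float)
    lfc = res["lfc_shrunk"].to_numpy(dtype=float)
    de = (padj < alpha) & (np.abs(lfc) > lfc_threshold)
    de = np.where(np.isnan(padj) | np.isnan(lfc), False, de)
    res["de"] = de.astype(bool)
    sign = np.sign(np.nan_to_num(lfc)).astype(int)
    res["direction"] = np.where(res["de"], sign, 0)
    res.attrs.update(result.attrs)
    return res


def run_contrast(
    cm: CountMatrix,
    samples: pd.DataFrame,
    factors: pd.Series,
    contrast: ContrastSpec,
    alpha: float = 0.05,
    lfc_threshold: float = 0.32,
    min_count: int = 10,
    min_fraction: float = 0.5,
    lfc_prior_scale="auto",
    dispersion_prior_var: float = 0.25,
) -> pd.DataFrame:
    """Full single-contrast analysis: prefilter, dispersions, Wald test,
    LFC shrinkage, BH adjustment and DE calls."""
    by_group = samples.groupby("group")["sample_id"].apply(list).to_dict()
    ids = by_group[contrast.group_a] + by_group[contrast.group_b]
    tested = prefilter(cm, ids, min_count=min_count, min_fraction=min_fraction)
    sub = cm.select_samples(ids).select_genes(tested.to_numpy(dtype=bool))
    grp = samples.set_index("sample_id")["group"]
    disp = estimate_dispersions(sub, factors, grp, prior_var=dispersion_prior_var)
    res = wald_test(cm, factors, contrast, samples, disp, tested=tested)
    res = shrink_lfc(res, prior_scale=lfc_prior_scale)
    return call_de(res, alpha=alpha, lfc_threshold=lfc_threshold)
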