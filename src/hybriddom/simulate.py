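"""Synthetic three-group RNA-seq experiments with known inheritance truth.

Generates parent1 / parent2 / hybrid count matrices whose per-gene
expression geometry follows one of six inheritance modes (conserved,
additive, parent-dominant either way, over-dominant, under-dominant),
with negative-binomial noise (var = mu + alpha*mu^2), a decreasing
mean-dispersion trend alpha(mu) = a0/mu + a1, and per-sample library
size factors.  The returned truth table makes every downstream stage
testable against known labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, GROUPS

MODES = (
    "conserved",
    "additive",
    "dominant_p1",
    "dominant_p2",
    "over_dominant",
    "under_dominant",
)

#: mode mixture loosely echoing a testis-like run: mostly conserved,
#: a fifth of genes transgressive, few additive/dominant genes
DEFAULT_MODE_PROPORTIONS = {
    "conserved": 0.78,
    "additive": 0.01,
    "dominant_p1": 0.005,
    "dominant_p2": 0.005,
    "over_dominant": 0.10,
    "under_dominant": 0.10,
}


@dataclass
class SimConfig:
    """Parameters of one simulated three-group experiment.

    ``effect_lfc`` is the log2 magnitude by which a hybrid deviates from
    a parent under a non-conserved mode; parents of additive and
    dominant genes are separated by 2*effect_lfc so the additive
    midpoint and the unmatched parent are both distinguishable at the
    classification threshold.  Baseline means are log-normal
    (natural-log mean ``mean_log_mu``, sd ``sd_log_mu``); dispersions
    follow alpha(mu) = a0/mu + a1; per-sample size factors are drawn
    log-uniform from ``size_factor_range``.
    """

    n_genes: int = 12000
    replicates: dict = field(
        default_factory=lambda: {"parent1": 5, "parent2": 5, "hybrid": 5}
    )
    mode_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_MODE_PROPORTIONS)
    )
    effect_lfc: float = 1.0
    mean_log_mu: float = 5.5
    sd_log_mu: float = 1.5
    dispersion_a0: float = 3.0
    dispersion_a1: float = 0.05
    size_factor_range: tuple = (0.7, 1.4)
    frac_z: float = 0.05
    frac_unanchored: float = 0.07
    z_de_odds: float = 1.0  # >1 plants non-conserved genes on Z preferentially
    tissue: str = "testis"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for g in GROUPS:
            if g not in self.replicates:
                raise ValueError(f"replicates missing group {g!r}")
            if self.replicates[g] < 2:
                raise ValueError(f"need >=2 replicates per group, got {self.replicates[g]} for {g!r}")
        unknown = set(self.mode_proportions) - set(MODES)
        if unknown:
            raise ValueError(f"unknown inheritance modes: {sorted(unknown)}")
        total = sum(self.mode_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mode_proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.mode_proportions.values()):
            raise ValueError("mode_proportions must be non-negative")
        for name in ("effect_lfc", "sd_log_mu", "dispersion_a0", "dispersion_a1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("size_factor_range must be positive with lo <= hi")
        if not (0 <= self.frac_z < 1 and 0 <= self.frac_unanchored < 1):
            raise ValueError("chromosome fractions must lie in [0, 1)")
        if self.z_de_odds <= 0:
            raise ValueError("z_de_odds must be positive")


def ovary_like(**overrides) -> SimConfig:
    """Preset with the unbalanced 5/3/5 replicate design of an ovary run."""
    cfg = dict(replicates={"parent1": 5, "parent2": 3, "hybrid": 5}, tissue="ovary")
    cfg.update(overrides)
    return SimConfig(**cfg)


def hybrid_mean_for_mode(
    mode: str,
    mu_p1: float,
    mu_p2: float,
    effect_lfc: float,
    rng: np.random.Generator | None = None,
) -> float:
    """True hybrid mean implied by an inheritance mode and parent means.

    conserved: parents equal, hybrid equal.  additive: geometric midpoint
    of unequal parents.  dominant_p1/p2: hybrid matches that parent.
    over/under_dominant: hybrid exceeds the larger (falls below the
    smaller) parent by ``effect_lfc`` in log2.
    """
    if mu_p1 <= 0 or mu_p2 <= 0:
        raise ValueError("parent means must be positive")
    if mode == "conserved":
        if not math.isclose(mu_p1, mu_p2, rel_tol=1e-9):
            raise ValueError("conserved mode requires equal parent means")
        return mu_p1
    if mode == "additive":
        if math.isclose(mu_p1, mu_p2, rel_tol=1e-12):
            raise ValueError("additive mode requires unequal parent means")
        return math.sqrt(mu_p1 * mu_p2)
    if mode == "dominant_p1":
        return mu_p1
    if mode == "dominant_p2":
        return mu_p2
    if mode == "over_dominant":
        return max(mu_p1, mu_p2) * 2.0**effect_lfc
    if mode == "under_dominant":
        return min(mu_p1, mu_p2) * 2.0**-effect_lfc
    raise ValueError(f"unknown inheritance mode {mode!r}")


def _parent_means(modes: np.ndarray, base: np.ndarray, sign: np.ndarray,
                  effect_lfc: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene parent means implied by mode and a random orientation sign.

    Parents of additive and dominant genes are separated by
    2*effect_lfc in log2 (sign picks which parent is up); all other
    modes have equal parents.
    """
    mu_p1 = base.copy()
    mu_p2 = base.copy()
    step = 2.0 ** (sign * effect_lfc)
    add = modes == "additive"
    mu_p1[add] = base[add] * step[add]
    mu_p2[add] = base[add] / step[add]
    for dom in ("dominant_p1", "dominant_p2"):
        m = modes == dom
        other = mu_p2 if dom == "dominant_p1" else mu_p1
        other[m] = base[m] * step[m] ** 2  # 2*effect_lfc offset from the matched parent
    return mu_p1, mu_p2


def simulate_experiment(config: SimConfig):
    """Simulate counts, sample metadata and ground truth.

    Returns ``(CountMatrix, samples, truth)`` where ``samples`` has
    columns sample_id/group/tissue and ``truth`` has columns
    gene_id/true_mode/mu_p1/mu_p2/mu_h/dispersion/chromosome.  The same
    seed yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    props = np.array([config.mode_proportions.get(m, 0.0) for m in MODES])
    modes = rng.choice(np.array(MODES, dtype=object), size=n, p=props / props.sum())
    sign = rng.choice(np.array([-1.0, 1.0]), size=n)
    base = np.exp(rng.normal(config.mean_log_mu, config.sd_log_mu, size=n))

    mu_p1, mu_p2 = _parent_means(modes, base, sign, config.effect_lfc)
    mu_h = np.array(
        [
            hybrid_mean_for_mode(m, p1, p2, config.effect_lfc)
            for m, p1, p2 in zip(modes, mu_p1, mu_p2)
        ]
    )

    mean_mu = (mu_p1 + mu_p2 + mu_h) / 3.0
    alpha = config.dispersion_a0 / mean_mu + config.dispersion_a1

    # chromosome labels; optionally enrich non-conserved genes on Z
    nonconserved = modes != "conserved"
    p_z = np.full(n, config.frac_z)
    if config.z_de_odds != 1.0:
        odds = config.frac_z / (1 - config.frac_z) * config.z_de_odds
        p_z[nonconserved] = odds / (1 + odds)
    u = rng.random(n)
    v = rng.random(n)
    frac_un_given_not_z = config.frac_unanchored / max(1e-12, 1 - config.frac_z)
    chrom = np.where(
        u < p_z, "Z", np.where(v < frac_un_given_not_z, "unanchored", "autosome")
    ).astype(object)

    sample_ids, groups = [], []
    for g in GROUPS:
        for r in range(config.replicates[g]):
            sample_ids.append(f"{g}_{r + 1}")
            groups.append(g)
    n_samples = len(sample_ids)
    lo, hi = config.size_factor_range
    size_factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    group_mu = {"parent1": mu_p1, "parent2": mu_p2, "hybrid": mu_h}
    counts = np.empty((n, n_samples), dtype=np.int64)
    r_shape = 1.0 / alpha
    for j, g in enumerate(groups):
        mu_j = size_factors[j] * group_mu[g]
        lam = rng.gamma(shape=r_shape, scale=mu_j / r_shape)
        counts[:, j] = rng.poisson(lam)

    gene_ids = np.array([f"gene{i + 1:05d}" for i in range(n)], dtype=object)
    cm = CountMatrix(gene_ids, np.array(sample_ids, dtype=object), counts)
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "tissue": config.tissue}
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_mode": modes,
            "mu_p1": mu_p1,
            "mu_p2": mu_p2,
            "mu_h": mu_h,
            "dispersion": alpha,
            "chromosome": chrom,
        }
    )
    truth.attrs["size_factors"] = dict(zip(sample_ids, size_factors))
    return cm, samples, truth
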