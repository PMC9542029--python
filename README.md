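# hybriddom

Inheritance-mode analysis of hybrid gene expression from bulk RNA-seq
counts.

When a hybrid lineage carries an intermediate genome, its transcriptome
need not be intermediate: expression of individual genes can match one
parent, sit between the parents, or escape the parental range entirely
(*transgressive* expression), as happens spectacularly in the testis of
the homoploid hybrid Italian sparrow.  `hybriddom` implements the full
analysis that turns three groups of count profiles — two parent species
and their hybrid — into per-gene inheritance calls and the summary
statistics such studies report, plus a negative-binomial simulator with
known per-gene truth so every stage can be validated end to end.

## The model

Counts for gene *i* in sample *j* are modelled as negative binomial,

&nbsp;&nbsp;&nbsp;&nbsp;K<sub>ij</sub> ~ NB(mean = s<sub>j</sub> μ<sub>i,g(j)</sub>, var = μ + α<sub>i</sub>μ²),

with median-of-ratios size factors s<sub>j</sub>, group means fitted by
a log-link GLM, and gene-wise dispersions α<sub>i</sub> estimated by
Cox–Reid adjusted maximum likelihood and shrunk in log space toward a
fitted trend α(μ) = a₀/μ + a₁.  Each pairwise contrast yields a Wald
test of the log2 fold change (LFC), an empirical-Bayes shrunken LFC
(zero-centred normal prior, posterior mean LFC·τ²/(τ²+SE²)), and
Benjamini–Hochberg adjusted p-values.  A gene is differentially
expressed when p<sub>adj</sub> < 0.05 and |shrunken LFC| > 0.32
(a 1.25-fold change).

Inheritance is then read off the two hybrid-vs-parent contrasts.  With
D₁/D₂ = "hybrid differs from parent 1/2":

| pattern | call |
|---|---|
| ¬D₁ ∧ ¬D₂ | conserved |
| D₁ ∧ D₂, both LFC > +0.32 | over-dominant |
| D₁ ∧ D₂, both LFC < −0.32 | under-dominant |
| D₁ ∧ D₂, opposite signs | additive |
| D₂ only / D₁ only | dominant for parent 1 / parent 2 |

Over- plus under-dominant genes are the transgressive set.  The module
surface also provides hypergeometric over-representation tests (Z
chromosome among DE genes, flat GO ORA with BH control), the up/down
asymmetry chi-squared, and the divergence ratio — the mean
hybrid-vs-parent DE count over the parent-vs-parent DE count.

## Worked example

```python
from hybriddom import RunConfig, SimConfig, run_pipeline

sim = SimConfig(n_genes=4000, effect_lfc=2.0, seed=5)   # 20% transgressive truth
out = run_pipeline(RunConfig(sim=sim, seed=5))
print(out["de_summary"].round(2).to_string(index=False))
```

prints (see `examples/05_full_pipeline.py` for the full script):

```
          contrast  n_tested  n_significant  n_up  n_down  pct_of_tested
parent2_vs_parent1      3931             98    46      52           2.49
 hybrid_vs_parent1      3930            895   443     452          22.77
 hybrid_vs_parent2      3923            883   439     444          22.51

divergence ratio: 9.07 (rounded 9)
transgressive share: 19.58% of 3918 background genes (truth: 19.60%)
```

The two hybrid contrasts each flag ~23% of tested genes while the
parents differ in only 2.5% — a 9-fold divergence ratio — and the
reported transgressive share recovers the simulated truth (19.6%)
almost exactly.  The `examples/` directory has one narrative script per
capability: simulation, a single contrast, classification, enrichment,
and the full pipeline; a thin CLI (`hybriddom simulate|normalize|de|
classify|enrich|report|run`) wraps the same functions for shell use.

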