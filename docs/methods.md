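# Methods

## Scope and data model

`hybriddom` analyses a three-group bulk RNA-seq design — two parent
species and a hybrid — given a genes × samples matrix of raw read
counts (htseq-count style), sample metadata, and optionally a GFF3 gene
annotation and a flat gene→GO table.  It does not touch reads or
alignments: counting, mapping and quality control are upstream of the
artifact.  All stages operate on integer counts; fractional input is
rejected rather than truncated, since it usually signals accidentally
pre-normalized data.

## Normalization

Size factors use the median-of-ratios estimator: with geometric means
g_i of each gene across samples (computed in log space), sample j's
factor is the median over reference genes of c_ij / g_i, where the
reference set is the genes with no zero count.  With an even number of
reference genes the median is the arithmetic mean of the two central
ratios.  If no gene is positive in every sample the estimator is
undefined and the package raises rather than silently falling back.

## Differential expression

Each pairwise contrast is a negative-binomial GLM with log link,
design `intercept + group`, and offsets log s_j.  Because the design is
group-saturated, each group's log-mean has an exact one-dimensional
MLE; we solve the score equation Σ_j (c_j − μ_j)/(1 + αμ_j) = 0 by
Newton iteration (the score is strictly decreasing in the log-mean, so
the iteration is globally stable), vectorized across genes.  Standard
errors come from the expected Fisher information Σ μ/(1 + αμ) per
group.  The per-gene tests statsmodels produces for the identical GLM
serve as an independent cross-check in the test suite.

**Prefilter.**  A gene enters a contrast when its raw count is ≥ 10 in
at least half of that contrast's samples (both knobs configurable).
Untested genes are excluded from every denominator downstream.

**Dispersions.**  Gene-wise α is estimated by maximizing the Cox–Reid
adjusted profile likelihood (the −½ log det(XᵀWX) term corrects the
downward bias from estimating the group means on the same data; at 10
samples the uncorrected MLE is ~25% low, which visibly inflates type-I
error).  The search is a vectorized golden-section on log α over
[1e-8, 10].  A trend α(μ) = a₀/μ + a₁ is fitted by non-negative least
squares with iterative exclusion of genes whose ratio to the trend
falls outside [1e-4, 15], skipping genes at the likelihood floor.  The
final value combines gene and trend estimates in log space, weighting
the gene-wise likelihood by the trigamma((m−p)/2) approximation to its
sampling variance against a normal prior of variance 0.25 centred on
the trend; floored genes (no dispersion signal) take the trend value.
The prior width is fixed rather than estimated for stability at small
gene counts.

**Wald test and shrinkage.**  LFC = (β_a − β_b)/ln 2, two-sided normal
p-value, BH adjustment across the contrast's tested genes.  Shrunken
LFCs use a zero-centred normal prior: posterior mean
LFC·τ²/(τ² + SE²), with τ² either supplied or estimated by method of
moments, max(var(LFC) − mean(SE²), 1e-6).  This preserves sign and
never increases magnitude; the DE rule (p_adj < 0.05 and |LFC| > 0.32,
i.e. 1.25-fold) is applied to the shrunken estimate in all three
contrasts uniformly.  Genes with an all-zero group are refitted after
adding a 0.5 pseudo-count and flagged.  No independent-filtering or
outlier-replacement machinery is applied; this is a documented
difference from heavier DE frameworks.

## Inheritance classification

The background is the intersection of genes tested in both
hybrid-vs-parent contrasts; this denominator choice is recorded in the
run manifest (the alternative — genes DE against at least one parent —
changes only the conserved row).  With D₁/D₂ the DE indicators against
each parent (shrunken LFC oriented hybrid-over-parent), the decision
table maps ¬D₁∧¬D₂ → conserved; D₁∧D₂ same-sign → over-/under-dominant
(jointly "transgressive"); D₁∧D₂ opposite-sign → additive; exactly one
deviation → dominant for the similar parent.  "Similar to a parent" is
operationalized as *not DE* versus that parent.  An explicit
`ambiguous` bin exists for configurations other gating rules could
produce (e.g. joint significance with one sub-threshold magnitude); it
is unreachable under the default rule but prevents silent misfiling.
The parent–parent contrast is computed and reported but deliberately
not consulted by the decision table.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
P(X ≥ k) (scipy's stable log-space implementation; the convention
includes the observed k).  The chromosome test draws from an urn of
tested genes on the focal category plus autosomes — unanchored
scaffolds are excluded because their category is unknown.  GO ORA is
flat (no term hierarchy), tests terms with at least 5 background
genes, and controls FDR across the tested terms by BH.

## Summary statistics

The divergence ratio is mean(n_DE hybrid-vs-p1, n_DE hybrid-vs-p2) /
n_DE parent-vs-parent; both the raw value, its integer rounding and
the two single-contrast ratios are reported, since either convention
rounds to the same headline figure on realistic counts.  The up/down
asymmetry test is a Pearson chi-squared (df = 1) on the 2×2
direction-by-contrast table, without continuity correction by default;
a Yates flag exists and the choice is recorded in the manifest.

## The simulator

`simulate_experiment` draws, per gene: an inheritance mode from a
configurable mixture; a baseline mean from a log-normal (default
median e^5.5 ≈ 245 counts, log-sd 1.5, giving a realistic spread from
filtered-out to highly expressed); a dispersion from the trend
α(μ) = a₀/μ + a₁ (defaults 3.0/μ + 0.05, typical of bulk tissue
replicates); and chromosome labels (5% Z, 7% unanchored, echoing a
passerine annotation).  Counts are gamma–Poisson draws with per-sample
size factors log-uniform in [0.7, 1.4].  The default design is 5/5/5
replicates; an `ovary_like` preset gives the unbalanced 5/3/5 design.

Truth construction fixes the classification geometry: conserved genes
have equal parent and hybrid means (the strictest notion of
conservation, giving unambiguous labels); additive genes have parents
separated by 2·`effect_lfc` in log2 with the hybrid at their geometric
midpoint; dominant genes equal one parent with the other offset by
2·`effect_lfc`; over/under-dominant genes have equal parents with the
hybrid `effect_lfc` above/below them.  The 2× parental separation for
additive and dominant modes guarantees that every non-conserved truth
is classifiable at the 0.32 threshold, so recovery failures reflect
the pipeline rather than the truth construction.  `effect_lfc`
defaults to 1.0; published parental divergences are not known, so the
magnitude is deliberately exposed.  A `z_de_odds` knob plants
non-conserved genes on Z with elevated odds to exercise the
enrichment stage.

What the simulator does *not* emulate: GC/length bias, batch effects,
isoform switching, allele-specific expression, correlated genes, and
outlier samples.  Passing tests therefore demonstrate correctness of
the statistical machinery under the stated NB model, not robustness to
every artefact of real libraries.

## Numerical choices and problem sizes

Dispersion search floor/ceiling 1e-8/10 in α, with estimates within
two log-units of the floor treated as floored; golden-section runs 60
iterations (interval ~3e-13 of the range).  Newton fits iterate to a
1e-12 step tolerance.  BH is implemented directly (sorted cummin) and
cross-checked against statsmodels.  The statistical suites run at
5000 genes × 5/5/5 replicates — large enough for the KS and recovery
bands to be stable across seeds (calibration KS ≈ 0.02, recovery
≈ 100%, transgressive-share error < 0.3 points at seeds 1, 2, 7, 42)
while keeping the whole pipeline under a few seconds per run.

## Known limitations

The Wald test relies on asymptotic normality; at very low means or
2–3 replicates it is only approximately calibrated (the prefilter
removes the worst cases).  The LFC prior is a single global normal, so
very heavy-tailed effect distributions are over-shrunk relative to
heavier-tailed priors.  The GO test treats terms independently,
ignoring the ontology DAG.  Multi-factor designs, likelihood-ratio
tests and surrogate-variable correction are out of scope.
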