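"""Simulate a three-group RNA-seq experiment with known inheritance truth.

Builds a parent1/parent2/hybrid design (5 replicates each), draws
negative-binomial counts with a decreasing mean-dispersion trend, and
prints the true mode mixture the downstream stages will try to recover.
"""

from hybriddom import SimConfig, simulate_experiment

config = SimConfig(n_genes=2000, effect_lfc=2.0, seed=1)
counts, samples, truth = simulate_experiment(config)

print(f"count matrix: {counts.n_genes} genes x {counts.n_samples} samples")
print(samples.groupby("group").size().rename("replicates").to_string())
print("\ntrue inheritance modes (what a perfect classifier would report):")
print(truth["true_mode"].value_counts().to_string())
print("\nfirst genes of the truth table:")
print(truth.head(5).to_string(index=False))
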