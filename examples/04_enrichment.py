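"""Over-representation tests: sex-chromosome enrichment and GO ORA.

The simulation plants non-conserved genes on the Z chromosome with 4x
odds, so the hypergeometric test should fire; the GO example plants one
term heavily inside the DE set and shows it surfacing past BH control.
"""

import numpy as np
import pandas as pd

from hybriddom import RunConfig, SimConfig, go_ora, run_pipeline

sim = SimConfig(n_genes=3000, effect_lfc=2.0, frac_z=0.06, z_de_odds=4.0, seed=4)
out = run_pipeline(RunConfig(sim=sim, seed=4))

print("Z-chromosome enrichment among DE genes, per contrast")
print("(k DE genes on Z of n DE, against K Z genes of N on Z+autosomes):")
print(out["enrichment"][["contrast", "k", "K", "n", "N", "pvalue"]].to_string(index=False))

# a small synthetic GO annotation: one term planted in the DE set
res = out["contrasts"]["hybrid_vs_parent1"]
tested = res[res["tested"]]
de = list(tested.loc[tested["de"], "gene_id"])
bg = list(tested["gene_id"])
rng = np.random.default_rng(4)
planted = de[:40] + bg[:10]
decoy = list(rng.choice(bg, 60, replace=False))
ann = pd.DataFrame(
    [(g, "GO:planted", "planted term") for g in planted]
    + [(g, "GO:decoy", "decoy term") for g in decoy],
    columns=["gene_id", "term_id", "term_name"],
).drop_duplicates(["gene_id", "term_id"])

ora = go_ora(de, bg, ann)
print("\nGO over-representation (padj < 0.05 marks enrichment):")
print(ora.to_string(index=False))
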