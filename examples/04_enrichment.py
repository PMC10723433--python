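"""Pathway enrichment with permulation correction.

Shows the method's central claim at pathway level: a pathway whose member
genes co-vary (a "co-shifting clique" sharing a latent branch effect, with
no true category association) looks enriched under the parametric rank-sum
test but is demoted once enrichment statistics are recomputed under
permulated nulls, which preserve the inter-gene correlation.
"""

import numpy as np
import pandas as pd

from catrer import pipeline, synthetic
from catrer.catasr import assign_edge_states
from catrer.enrichment import enrichment_table, permulation_enrichment, rank_statistic
from catrer.permulation import PermulationConfig

spec = synthetic.SyntheticSpec(
    n_tips=30, k=3, n_genes=400, fraction_shifted=0.0, missing_rate=0.0,
    clique_size=30, clique_sd=2.0, rng_seed=41,
)
tree = synthetic.gen_tree(spec)
tips, truth_states = synthetic.gen_phenotype(
    tree, synthetic.default_q(spec), seed=42, min_categories=3
)
edge_truth = assign_edge_states(tree, truth_states)
rers, truth = synthetic.gen_rer_matrix(tree, edge_truth, spec, seed=43)
asr = pipeline.reconstruct(tree, tips, rate_model="ER", categories=["cat0", "cat1", "cat2"])

analysis = pipeline.run_permulation_pvalues(
    tree, rers, asr, PermulationConfig(n_permulations=100, rng_seed=44)
)

gene_ids = np.asarray(rers.gene_ids)
pathways = synthetic.gen_pathways(gene_ids, n_pathways=8, size_range=(15, 40), truth=truth, seed=45)
scores = pd.Series(rank_statistic(analysis.omnibus["p"].to_numpy(), mode="omnibus"), index=gene_ids)
obs = enrichment_table(scores, pathways, min_size=10)
null_scores = rank_statistic(analysis.nulls["omnibus_p"], mode="omnibus")
corrected = permulation_enrichment(obs, null_scores, gene_ids, pathways)

print(corrected[["pathway", "W", "z", "p", "p_adjusted", "perm_p"]].to_string(index=False))
clique = corrected[corrected.pathway == "clique"].iloc[0]
print(f"\nclique pathway: parametric p = {clique['p']:.3g}, permulation p = {clique['perm_p']:.3g}")
# The permulation p is (much) larger: the parametric rank-sum test treats
# gene ranks as independent, which correlated gene sets violate.
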