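"""Permulation-corrected gene-level p-values.

Generates phylogenetically plausible null phenotypes — simulated under the
fitted CTMC, constrained to the observed category counts, with internal
states permuted and re-annealed — and converts null association statistics
into empirical p-values.
"""

import numpy as np

from catrer import pipeline, synthetic
from catrer.catasr import assign_edge_states
from catrer.permulation import PermulationConfig

spec = synthetic.SyntheticSpec(n_tips=40, k=3, n_genes=300, fraction_shifted=0.1, rng_seed=31)
tree = synthetic.gen_tree(spec)
tips, truth_states = synthetic.gen_phenotype(
    tree, synthetic.default_q(spec), seed=32, min_categories=3
)
edge_truth = assign_edge_states(tree, truth_states)
rers, truth = synthetic.gen_rer_matrix(tree, edge_truth, spec, seed=33)
asr = pipeline.reconstruct(tree, tips, rate_model="ER", categories=["cat0", "cat1", "cat2"])

config = PermulationConfig(n_permulations=200, relaxation=0.0, rng_seed=34)
analysis = pipeline.run_permulation_pvalues(tree, rers, asr, config)

perms = analysis.permulations
print(f"{len(perms)} permulations; median simulation attempts per permulation:",
      int(np.median([p.attempts for p in perms])))
print("log-likelihood medians (simulation -> after internal permutation -> annealed):")
print(f"  {np.median([p.log_likelihood_simulation for p in perms]):.1f} -> "
      f"{np.median([p.log_likelihood_after_permute for p in perms]):.1f} -> "
      f"{np.median([p.log_likelihood for p in perms]):.1f}")
# The annealing step restores the likelihood lost when internal states are
# replaced by a permutation of the originally reconstructed states.

shifted = truth["shifted"]
omni = analysis.omnibus
print("\nomnibus permulation p (one-sided on epsilon^2), medians:")
print(f"  planted genes : {np.nanmedian(omni['perm_p'][shifted]):.4f}")
print(f"  null genes    : {np.nanmedian(omni['perm_p'][~shifted]):.2f}")
print(f"null genes with perm_p < 0.05: {np.nanmean(omni['perm_p'][~shifted] < 0.05):.3f}"
      " (calibrated near 0.05)")
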