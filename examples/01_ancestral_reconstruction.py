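"""Ancestral reconstruction of a categorical trait under an Mk model.

Builds a small synthetic study (40-species Yule tree, 3 diet-like
categories evolved under an equal-rates CTMC), fits ER/SYM/ARD rate
models, compares them with likelihood-ratio tests, and reconstructs
ancestral states from the marginal likelihoods.
"""

import numpy as np

from catrer import pipeline, synthetic
from catrer.catasr import symmetric_transition_counts

spec = synthetic.SyntheticSpec(n_tips=40, k=3, rng_seed=11)
tree = synthetic.gen_tree(spec)
tips, truth_states = synthetic.gen_phenotype(
    tree, synthetic.default_q(spec), seed=12, min_categories=3
)

fits, table, selected = pipeline.compare_rate_models(tree, tips, rng=np.random.default_rng(0))
print("rate-model comparison (LRT of each model vs its more complex peers):")
print(table.to_string(index=False))
print(f"selected rate model: {selected}")

asr = pipeline.reconstruct(tree, tips, rate_model=selected, categories=["cat0", "cat1", "cat2"])
internal = np.flatnonzero(~tree.is_tip)
acc = np.mean(asr.node_states[internal] == truth_states[internal])
print(f"\nfitted log-likelihood: {asr.fit.log_likelihood:.3f}")
print(f"internal-state recovery vs simulated truth: {acc:.0%}")
print("direct transitions between categories (a<->b, from the reconstruction):")
print(symmetric_transition_counts(asr.transition_counts))
# Each off-diagonal entry counts edges whose endpoints differ in state —
# every such transition is a potential independent convergent event.
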