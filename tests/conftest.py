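import numpy as np
import pytest

from catrer import pipeline, synthetic
from catrer.phylo import read_newick


@pytest.fixture
def quartet():
    """Balanced 4-tip tree; post-order ids: A=0 B=1 (AB)=2 C=3 D=4 (CD)=5 root=6."""
    return read_newick("((A:1.0,B:1.0):0.5,(C:2.0,D:2.0):0.5);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_study():
    """One 40-tip synthetic study with a fitted ER reconstruction (shared)."""
    spec = synthetic.SyntheticSpec(n_tips=40, k=3, n_genes=200, fraction_shifted=0.1, rng_seed=11)
    tree = synthetic.gen_tree(spec)
    tips, truth_states = synthetic.gen_phenotype(
        tree, synthetic.default_q(spec), seed=12, min_categories=3
    )
    from catrer.catasr import assign_edge_states

    edge_truth = assign_edge_states(tree, truth_states)
    rers, truth = synthetic.gen_rer_matrix(tree, edge_truth, spec, seed=13)
    asr = pipeline.reconstruct(tree, tips, rate_model="ER")
    return {
        "spec": spec,
        "tree": tree,
        "tips": tips,
        "truth_states": truth_states,
        "edge_truth": edge_truth,
        "rers": rers,
        "truth": truth,
        "asr": asr,
    }
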