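# catrer — categorical-trait evolutionary-rate association

`catrer` asks, for every gene in a genome-wide set, whether its **relative
evolutionary rate** (RER — how much faster or slower the gene evolves than
the genome-wide average on each branch of a phylogeny) differs among the
branches of a **multi-category phenotype** (for example carnivore /
omnivore / herbivore diet across mammals). It is aimed at comparative
genomicists who already have a master phylogeny, a genes × branches RER
matrix, and a species phenotype table, and who need category-aware
ancestral reconstruction, association tests, and p-values that survive the
strong non-independence phylogenetic data carry.

## The method

1. **Ancestral reconstruction (Mk model).** The phenotype with k
   categories evolves along the master tree under a continuous-time Markov
   model with instantaneous rate matrix Q. A *rate model* constrains Q —
   ER (one shared rate), SYM (symmetric rates), ARD (all k(k−1) rates
   free), or any custom zero/equality pattern. Q is fit by maximum
   likelihood (Felsenstein pruning, polytomies and unrooted trees
   supported); rate models are compared by likelihood-ratio tests
   (χ² with df = Δ free parameters when nested, parametric bootstrap
   otherwise). Each node receives the state with the maximum *marginal*
   ancestral likelihood, and each branch the state of its descendant node,
   so extant branches always carry the observed phenotype.

2. **Association.** Per gene, the RERs on the branches of each category
   are compared with a Kruskal–Wallis omnibus test (effect size
   ε² = H/(n−1)) followed by pairwise Dunn Z tests, or optionally ANOVA
   (η² = SS_effect/(SS_effect+SS_residual)) with Tukey HSD.

3. **Permulations.** Parametric p-values are unreliable here because
   branches and genes are correlated. A *permulation* is a null phenotype
   *simulated* under the fitted Q (so it respects the phylogeny) and
   *constrained* to the observed category counts: simulations are
   rejection-sampled until extant counts match (exactly, or within a
   percentage *relaxation* band), internal states are replaced by a
   likelihood-weighted permutation of the originally reconstructed ones
   (internal counts stay exact), and a simulated-annealing pass
   (u = exp(−dh/T_k), T_k = T₀/(1+αk), T₀ = 10, α = 0.9, 100 cycles × 10
   proposals) restores the assignment's tree likelihood with
   count-preserving swaps. Re-testing every gene under each permulated
   labeling yields empirical p-values: one-sided on ε² for the omnibus
   test, two-sided on Z for the pairwise tests, with the add-one
   estimator (b+1)/(N+1).

4. **Enrichment.** Pathways (GMT gene sets) are scored by Wilcoxon
   rank-sum on per-gene −log₁₀(p) scores; recomputing the enrichment
   statistic under every permulation corrects for non-independence of
   gene ranks.

## Worked example

`examples/` holds one narrative script per capability. A condensed run
(seeds as in `examples/03_permulations.py` and `04_enrichment.py`):

```python
from catrer import pipeline, synthetic
from catrer.permulation import PermulationConfig

spec = synthetic.SyntheticSpec(n_tips=40, k=3, n_genes=300, fraction_shifted=0.1, rng_seed=31)
tree = synthetic.gen_tree(spec)
tips, truth = synthetic.gen_phenotype(tree, synthetic.default_q(spec), seed=32, min_categories=3)
# ... gen_rer_matrix, reconstruct (see examples/03) ...
analysis = pipeline.run_permulation_pvalues(
    tree, rers, asr, PermulationConfig(n_permulations=200, rng_seed=34))
```

which prints

```
log-likelihood medians (simulation -> after internal permutation -> annealed):
  -40.8 -> -75.7 -> -42.1
omnibus permulation p (one-sided on epsilon^2), medians:
  planted genes : 0.0050
  null genes    : 0.54
null genes with perm_p < 0.05: 0.052 (calibrated near 0.05)
```

Reading: replacing simulated internal states by a permutation costs ~35
log-likelihood units; annealing recovers nearly all of it, so the nulls
are evolutionarily plausible. Genes with a planted +2 SD category shift
get small permulation p-values while null genes are calibrated (5.2%
below 0.05). At pathway level (`examples/04_enrichment.py`), a clique of
30 correlated but phenotype-independent genes shows parametric enrichment
p = 5.7e-08 yet permulation p = 0.158 — the correction the permulation
machinery exists to make.

The same stages are scriptable via the thin CLI:

```bash
catrer simulate --n-tips 40 --n-genes 500 --seed 3 --out data/
catrer asr --tree data/master.nwk --phenotype data/phenotype.tsv --rate-model auto --out asr/
catrer permulate --tree data/master.nwk --phenotype data/phenotype.tsv \
    --rer data/rers.tsv --n 1000 --relaxation 0.10 --seed 17 --out perm/
catrer enrich --omnibus perm/permulation_omnibus.tsv --gmt data/pathways.gmt \
    --null-scores perm/null_omnibus_effect.tsv --out enrich/
```

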