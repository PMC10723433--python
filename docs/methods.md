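# Methods

This note records the models, algorithms, numerical choices and open
design decisions behind `catrer`, and what the synthetic experiments do
and do not demonstrate.

## Mk model and ancestral reconstruction

The phenotype is a k-state character evolving along the master tree under
a continuous-time Markov chain with rate matrix Q (off-diagonals ≥ 0, rows
sum to 0; units: expected events per branch-length unit, branch lengths
being expected substitutions per site). A rate model is an integer k×k
pattern: 0 forbids a transition, equal positive indices share one free
rate. ER/SYM/ARD are provided; custom patterns are accepted. Nestedness of
two patterns is decided structurally: the simpler model must forbid every
transition the more complex forbids, and every equality class of the
complex pattern must fall within a single class (or the forbidden set) of
the simple one.

**Likelihood.** Felsenstein pruning with per-node rescaling; polytomies
are handled by taking products over all children, and an unrooted tree is
pruned from its stored (multifurcating) root. Transition matrices
exp(Qt) are obtained by diagonalizing Q once and exponentiating all unique
branch lengths in one vectorized step (verified against
scaling-and-squaring at ~1e-14; expm is the automatic fallback when the
eigenbasis condition number exceeds 1e8). Rows are clipped to [0,1] and
renormalized to protect stochasticity against roundoff. Zero-length
branches get the identity matrix.

**Root prior.** Configurable: `flat` (default, 1/k), `stationary` (left
null vector of Q), or user-supplied. Flat keeps the likelihood-ratio test
well defined for non-reversible (ARD) fits; for symmetric models flat and
stationary coincide, which is why the root-invariance property of
marginals on unrooted trees is stated (and tested) for symmetric Q.

**Fitting.** Bounded L-BFGS-B on log-rates (bounds e^-20..e^12), three
deterministic starts at 0.1, 1 and 10 expected events per tree height,
ftol 1e-10. Non-convergence is flagged on the result, never raised. Every
declared category must be observed in at least one tip; with fewer than
two categories the fit is refused.

**Reconstruction.** Marginal ancestral likelihoods come from the standard
two-pass (inside/outside) algorithm; each node takes the argmax state,
ties break to the lowest state index with a warning. This is deliberately
the marginal, not the max-joint, assignment. Branches take their
descendant node's state, so extant branches always carry the observed
phenotype; when species are dropped, composite edges take the state of
their most tipward spanned master edge, preserving that guarantee.

**Rate-model comparison.** Nested pairs: 2ΔlogL ~ χ² with df = Δ free
parameters. Non-nested pairs: parametric bootstrap under the simpler fit;
replicates are refit from a single start at the generating parameters to
bound runtime (a documented approximation), and the p-value is the plain
proportion of null LR ≥ observed.

## Tree representation and paths

Nodes carry post-order integer ids assigned at parse time (children before
parents, root last), so the id of a non-root node doubles as its branch
column index; RER matrices join on that ordering. Newick parsing is
delegated to dendropy (polytomies and multifurcating roots preserved);
writing is a deterministic serialization with full-precision lengths.

Pruning to a species subset roots the induced subtree at the MRCA of the
kept tips, suppresses internal degree-2 nodes, and concatenates their
incident master edges into composite edges whose spans are contiguous
ancestor→descendant chains; a degree-2 induced root is kept rather than
suppressed so the chain invariant holds for every composite edge. Spanned
length is conserved exactly under pruning, and pruning is idempotent;
both are property-tested.

## Association tests

Per gene, branches with missing RERs are dropped; a gene is testable when
at least two categories have ≥ 2 usable branches and ≥ 8 usable branches
remain in total (configurable; untestable genes get NA with a reason
code). Internal and extant branches both contribute, since internal
branches carry much of the convergence signal; an extant-only restriction
is available through the path machinery.

Kruskal–Wallis uses midranks with the standard tie correction; ε² =
H/(n−1). Dunn Z uses the tie-corrected pooled variance
N(N+1)/12 − Σ(t³−t)/(12(N−1)); pairwise p-values are two-sided and
BH-adjusted within gene by default (holm/bonferroni/none available).
ANOVA/η²/Tukey–Kramer are the parametric alternative; zero residual
variance flags the p-value as undefined while η² (=1) is still reported.

Everything is implemented as a vectorized engine over the genes × branches
matrix: ranks and tie terms depend only on the RER values, so they are
computed once and reused across the thousands of permulated branch
labelings. The engine is cross-checked in the tests against
scipy.stats.kruskal, f_oneway, tukey_hsd and hand-computed rank sums.

## Permulations (complete-case)

Step 1 — rejection sampling: trait histories are simulated from the fitted
Q (root state from the prior, children from exp(Qt) rows, vectorized over
batches of 256) until the extant per-category counts match the observed
counts within floor(relaxation × count) per category; relaxation 0 means
exact. Small categories therefore get tolerance 0 until the relaxation
covers one individual — the floor convention is a deliberate reading of
"a percentage of the original counts". A per-permulation attempt ceiling
(default 1e6) raises an error that advises increasing the relaxation.

Step 2 — internal permutation: internal nodes, visited in random order,
draw states from the remaining multiset of the *originally reconstructed*
internal states with probability proportional to the marginal ancestral
likelihood recomputed from the simulated tips (renormalized over the
states still available per node). Internal category counts match the
original reconstruction exactly, at every relaxation level.

Step 3 — annealed reorganization: proposals pick a node i (state y) and
alternative state x with probability increasing in ratio = A[i,x]/A[i,y],
restricted to ratios > 1 when any exist (else uniform; softmax weighting
available), then a partner j currently in x by the mirrored ratio; the
swap i→x, j→y preserves counts by construction. Improving swaps are always
kept; worsening swaps are kept with u = exp(−dh/T_k), dh the
log-likelihood drop and T_k = 10/(1+0.9k) over 100 cycles of 10 proposals.
The printed source formula for dh reads as a raw likelihood ratio; the
log-difference reading is the default because it gives u = 1 for neutral
swaps, which matches the annealing intent — the raw-ratio reading is
available via `dh_scale="ratio"`. The tree likelihood is the product over
edges of (exp(Qt))_{ancestor,descendant} with no root-prior factor;
likelihood bookkeeping is in log space with local (touched-edge) updates,
and the proposal loop runs over plain Python lists, which profiles several
times faster than array arithmetic at tens of internal nodes.

Each permulation consumes an independent child stream of the master seed
(`SeedSequence.spawn`), which makes runs reproducible and lets the two
arms of a relaxation comparison share random streams — whenever the first
accepted simulation in a stream happens to match counts exactly, the two
arms produce the identical null, which removes a large share of the
Monte-Carlo noise from the relaxation-fidelity comparison.

Empirical p-values use (b+1)/(N+1) so p = 0 is impossible (the plain
proportion is available via `estimator="proportion"`); the omnibus test is
one-sided on the effect size, pairwise tests two-sided on the statistic.
NA nulls shrink the denominator; NA observed statistics propagate. Null
statistics reuse the observed RER matrix — only the branch-category labels
change per permulation (complete-case design; no per-gene tree
recomputation, species-subset-matched permulations are out of scope).

## Enrichment

Genes are scored −log₁₀(p) from the omnibus parametric p (unsigned — the
omnibus test is one-sided), or sign(statistic)·−log₁₀(p) in pairwise mode.
Pathways intersected with the non-NA universe and sized within
[min_size=10, max_size=500] are tested by Wilcoxon rank-sum (normal
approximation with tie and continuity corrections; W is the in-set rank
sum). Parametric p-values are BH-adjusted across pathways; the permulation
p — (#{|null z| ≥ |obs z|}+1)/(N+1) with the z recomputed per permulated
null score set — is reported alongside, unadjusted, mirroring the dual
reporting convention. The universe is fixed at the observed analysis;
permulations in which a pathway loses its in/out split contribute NA and
shrink the denominator.

## Synthetic data

The generator emulates, at configurable scale, a ~hundred-species mammal
diet study: a Yule tree (unit birth rate; exponential waiting times; tips
extended to the next unrealized split so the tree is ultrametric), an
Mk phenotype simulated under an ER rate of 0.3 — roughly 0.3–0.6 expected
transitions per tip, giving multiple independent transitions per category
pair as in the motivating data — and a genes × branches RER matrix of
unit-variance branch-independent noise (Student-t df=5 optional for
heavier tails). A planted fraction (default 5%) of genes gains
effect_size × SD (default 2) on the branches whose *true* simulated state
equals the target category; an optional clique of null genes shares one
latent N(0, 2²) branch-effect vector, giving pairwise RER correlation 0.8
with no category association in expectation — the stylized analog of a
co-regulated gene family. Entries are masked missing uniformly (default
5%).

What the generator does **not** emulate: RERs derived from actual
sequence alignments (their noise is branch-length-dependent and
heavy-tailed in structured ways), gene-specific species subsets
(missingness here is uniform), and phenotype-correlated missingness.
Passing tests therefore demonstrate correctness of the machinery and the
statistical behavior of the method under idealized noise, not performance
on real alignments.

## Experiment configurations

Chosen once, as study conditions, with these rationales:

- Pipeline fits use the ER rate model: a 40-tip tree carries too little
  information for six ARD parameters, and the generating process is ER.
- Relaxation fidelity: 40 tips, k=3, 500 genes (5% planted), 300
  permulations per arm, arms coupled by shared per-permulation streams;
  reported as the max over the omnibus and the three pairwise tests of
  the mean |Δp| across genes.
- Type-I calibration: 2,000 fully null genes, 200 unrelaxed permulations,
  missingness 0 — with no missingness each gene's per-category branch
  counts are identical across labelings, so the observed statistic is
  exchangeable with its nulls and the nominal 5% level is exact up to
  Monte-Carlo error.
- Annealing diagnostic: 200 permulations of a 30-tip study; medians of
  the three log-likelihood checkpoints plus a two-sample KS statistic
  between final and accepted-simulation likelihoods.
- Clique demotion: 100 replicate studies (30 tips, 400 genes, clique of
  30 at correlation 0.8, 60 permulations each), comparing parametric and
  permulation enrichment p for the clique pathway.

## Numerical and degenerate-input conventions

- All likelihood arithmetic in log space; zero-probability transitions
  yield −inf and a proposed swap into one is always rejected.
- Argmax ties in state assignment break to the lowest state index, with a
  warning.
- A Kruskal–Wallis sample whose values are all tied defines H = 0.
- Zero-length branches are legal everywhere (identity transition matrix).
- Empirical p-value comparisons use a 1e-12 slack so ties count as "at
  least as extreme".
- Seeds: every stochastic routine takes an explicit seed or Generator;
  derived seeds come from `SeedSequence` children.

## Known limitations

- The marginal-ML reconstruction understates joint uncertainty; no
  hidden-rate or covarion models.
- The Monte-Carlo LRT's single-start refits can underestimate null LR
  values in multimodal likelihoods.
- Permulation cost grows quickly with category count and with phenotype
  clustering (a dominant category concentrated in one clade leaves few
  acceptable simulations); the relaxation exists precisely for those
  regimes, and internal counts remain strictly matched even then.
- Tukey HSD p-values rely on the studentized-range distribution and are
  slower than the rank-based path; the rank-based route is the default.
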