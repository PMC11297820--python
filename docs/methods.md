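# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not emulate.

## Character codings

Reproductive systems are scored in three nested schemes. The eight-type
morphological scheme distinguishes heterotristyly, several forms of
heterodistyly and semihomostyly, dioecism and homostyly; it collapses to
five states — distyly, tristyly, semihomostyly, dioecy, homostyly — by
lumping the distyly variants (which differ in the missing morph and stamen
number) and the semihomostyly variants. The binary scheme scores morph
number: tristyly and semihomostyly are trimorphic (semihomostyly occurs only
in a tristylous context), distyly is dimorphic, and the two states known
from single species each (homostyly, dioecy) are pruned rather than forced
into a morph class. State 0 of the binary space is trimorphism, which fixes
the orientation of λ₀ and q₀₁ everywhere downstream.

Missing states are kept in the five-state analysis as uniform (all-ones) tip
partials, the standard ambiguity treatment; for the binary analysis
missing taxa are pruned together with the homostylous/dioecious ones (3 of
35 taxa in the shipped table, leaving 32). The AICc sample size is the
number of tips with observed data (34 for the five-state table, 32 for the
binary), a choice the literature leaves open; it is configurable through the
fit functions' inputs.

## Mk-n likelihood and ancestral states

Felsenstein pruning with per-node rescaling (log-compensated) guards
against underflow. Per-branch transition matrices exp(Qt) come from one
eigendecomposition of Q per likelihood evaluation, applied to all branches
at once; if the eigenvector matrix is ill-conditioned (condition number
above 1e8, possible for strongly asymmetric ARD matrices) the code falls
back to scaling-and-squaring per branch. Rows are clipped at zero and
renormalised to absorb 1e-15-scale eigendecomposition noise.

Root treatments: `weighted` uses the FitzJohn weighting (root-state weights
proportional to each state's likelihood of producing the data), `flat` a
uniform prior, `fixed:<state>` a known root. Maximum-likelihood fitting is
bounded L-BFGS-B on log-rates in [1e-8, 1e3] events per unit relative time,
with seeded random restarts (default 5 in the fit API, log-uniform around
1); a monomorphic dataset legitimately drives the rate to the lower bound.

Marginal ancestral states use the standard two-pass (tipward D, rootward U)
algorithm; the marginal at a node is the normalised product D·U. In the
rootward pass the root prior is flat for both the `weighted` and `flat`
treatments, so the root's marginal is its normalised likelihood profile
D/ΣD; under `fixed:<state>` the prior is an indicator and the constraint
propagates to all nodes. (Applying the FitzJohn weights *inside* the ASR
pass would square the root profile; we deliberately do not, so that the
reported root marginal is the profile itself.) Transition tallies assign
each internal node its argmax state — ties resolved to the lowest state
index and recorded — keep observed states at tips, drop edges leading to
missing-data tips, and count edges whose endpoints differ.

## BiSSE likelihood

The extinction probabilities E_i(t) and data partials D_i(t) are integrated
tipward-to-rootward along each branch with an adaptive embedded Cash–Karp
Runge–Kutta 4(5) scheme (rtol 1e-8, atol 1e-10, step growth capped at 5×,
shrink floor 0.1×), compiled with numba. Tip conditions are D_obs = ρ,
D_other = 0, E = 1 − ρ, with the sampling fraction ρ applied identically to
both states (ρ = 32/200 = 0.16 for the shipped binary table under the
assumed 200 extant species). D is renormalised with log-compensation at
every node and after every branch. Node combination is
D_i = λ_i·D_i^left·D_i^right. Root treatments mirror the Mk module;
conditioning on survival (dividing by Σ w_i λ_i (1−E_i)²) is available but
off by default, matching common practice for this model family. The tree
must be strictly bifurcating and ultrametric.

The model ladder comprises the unconstrained six-parameter model and five
simplifications: symmetric transitions (k=5); no extinction (k=4); no
extinction + symmetric speciation (k=3); symmetric transitions + no
extinction (k=3); and symmetric transitions + no extinction + symmetric
speciation (k=2). Fitting across a posterior tree sample computes δAICc
within each tree and then averages (so "mean δAICc" is the mean of per-tree
deltas, not the difference of means — the alternative is one subtraction
away from the reported means). Parameter summaries are across-tree means
with 95% HPD intervals (shortest contiguous window containing ⌈0.95·n⌉
sorted points). BiSSE ancestral states clamp each internal node to each
state in turn and normalise the resulting likelihood profile; implied
transition counts reuse the Mk tally on the argmax states.

Because the BiSSE likelihood is a density over node times, rescaling the
tree by c and dividing all rates by c shifts lnL by −(n−1)·ln c (one λ
factor per internal node); the Mk likelihood, a probability, is exactly
invariant under the same rescaling. Tests assert both transformations.

## Concordance statistics

Robinson–Foulds distances operate on non-trivial bipartitions after
restricting both trees to their shared tips; the normalised form divides by
the total bipartition count of both trees (the maximum possible symmetric
difference), and the gene-shopping cutoff (default 0.15) is interpreted on
this normalised scale. Quartet scores are exact: all four-taxon subsets are
enumerated (≈52,000 for 35 taxa, vectorised via the four-point condition on
unit-branch-length path distances), and quartets unresolved by a polytomy
are excluded from numerator and denominator. Gene-tree support (gts) for a
clade is the percentage of gene trees containing the clade's bipartition
after restriction to each gene tree's sampled taxa, counting only trees
with at least two taxa remaining on each side.

QC filtering applies, in order: samples with fewer than 50 recovered loci
dropped; loci whose mean heterozygous-site percentage across remaining
samples exceeds 3% dropped; loci recovered in less than a third of the
remaining samples dropped. The mean-per-locus aggregation for the
heterozygosity rule is a documented choice (the rule's published phrasing
does not fix the aggregation); every exclusion is logged with its rule.

The MCC summary picks the sample tree maximising the product of clade
frequencies (candidates are the sampled trees only, matching standard
annotator behaviour; ties broken by a canonical topology ordering so the
result is order-independent), then replaces each node height with the
median age of its clade across the trees containing it. A child whose
median age exceeds its parent's is clamped to the parent (zero-length
branch) and logged.

## Synthetic data

The generators are deterministic under a fixed seed and emulate the
statistical structure the analyses assume:

* **Birth–death trees** by Gillespie simulation from a single lineage,
  conditioned on a tip count (the clock is advanced to the next would-be
  event so the youngest tips have positive pendant branches) or a stopping
  time, with extinct lineages pruned and the tree rescaled to root height 1.
* **BiSSE trees** from the state-dependent process with per-tip retention
  probability ρ; runs that die out or leave fewer than the minimum tips are
  retried up to 100 times, so returned samples are implicitly conditioned
  on survival (the test oracles use conditional expectations accordingly).
* **Mk characters** by sampling the embedded jump process along branches.
* **Pseudo-posteriors** by multiplying node ages with independent
  lognormal(0, σ) noise (default σ = 0.1), enforcing child-younger-than-
  parent, and renormalising to root height 1. This is an artifact stand-in
  for an MCMC sample: it has the right marginal height wobble but fixed
  topology and no autocorrelation structure, so passing tests say nothing
  about topological uncertainty in real posteriors.
* **The study fixture**: a 35-tip birth–death tree (birth 1, death 0.25 —
  a moderate plant-scale extinction fraction — conditioned on 35 tips, root
  height 1) carrying the real 35-taxon character table. Taxon names are
  attached by matching recorded states to a five-state ER character
  simulated on the tree at rate 2 per unit relative time (the scale implied
  by roughly 17 changes on a tree of total length ≈10), so the traits have
  realistic phylogenetic signal; attaching them in random order would make
  the character independent of the tree and drive rate estimates to
  saturation. The trait values themselves are never altered.

What the fixture does *not* emulate: the tree is not the study's tree, so
absolute AICc values, rate estimates and transition counts on the fixture
are not comparable to the published ones (the model *orderings* are); and
the fixture tree is completely sampled while the analysis assumes ρ = 0.16,
which inflates absolute diversification-rate estimates in the BiSSE ladder,
exactly as it would for any 35-of-200 analysis run on a complete tree.

## Problem sizes and defaults

The shipped pipeline defaults run the full analysis in minutes on one CPU:
100 pseudo-posterior trees generated, the BiSSE ladder fitted to a 25-tree
subsample (configurable up to the full sample), 60 synthetic loci for the
concordance stages, 3 optimiser restarts for Mk and 2 for BiSSE. The
acceptance script uses a 20-tree ladder and 100-replicate recovery
experiments. Simulation-recovery experiments use 200 extant species with
ρ = 0.16 (≈32 sampled tips) for BiSSE and 500 tips for the Mk rate.

## Known limitations

* No stochastic character mapping, rate heterogeneity across branches, or
  multi-state SSE models; polytomies are rejected by the BiSSE kernel.
* The BiSSE ASR reapplies the root treatment within each clamped
  evaluation, which follows the cited convention for marginal SSE
  reconstructions but means root-weighted marginals are not exactly
  posterior probabilities under a single prior.
* `summarize_mcc` only considers sampled topologies, so with very small
  samples the MCC tree can be a low-credibility topology.
* The QC module consumes precomputed heterozygosity tables; it does not
  re-map reads.
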