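# stylotrace

Comparative phylogenetics of floral polymorphism (heterostyly) on
target-capture phylogenomic trees: gene-tree/species-tree concordance
statistics and locus selection, multi-state Markov (Mk-n) ancestral-state
reconstruction with AICc model selection, and a BiSSE state-dependent
diversification model ladder fitted across a posterior sample of trees.

The package is aimed at plant systematists analysing an Angiosperms353-style
dataset: tens of taxa, a few hundred nuclear loci, a species tree with
relative-time branch lengths (root height 1), and a discrete reproductive
system character — here the Connaraceae, the family with the richest known
array of stylar polymorphisms (distyly, tristyly, semihomostyly, dioecy,
homostyly). It ships the family's 35-taxon character table in both a
five-state and a binary (dimorphism/trimorphism) coding, and a synthetic-data
module that generates every other input, so the entire pipeline runs without
downloads.

## Models

**Mk-n.** A continuous-time Markov chain on *n* character states along a
rooted tree with rate matrix *Q*; `ER` (all transition rates equal, 1
parameter), `SYM` (q<sub>ij</sub> = q<sub>ji</sub>, n(n−1)/2 parameters) and
`ARD` (all different, n(n−1) parameters). Likelihoods by Felsenstein pruning
with exp(*Qt*) per branch; marginal ancestral states at every node; the root
handled by FitzJohn weighting, a flat prior, or a fixed state. Models are
compared by AICc = −2lnL + 2k + 2k(k+1)/(n−k−1).

**BiSSE.** Joint likelihood of an ultrametric tree and binary tip states with
state-specific speciation (λ₀, λ₁), extinction (μ₀, μ₁) and transition rates
(q₀₁, q₁₀), plus a sampling fraction ρ, integrating the standard E/D ordinary
differential equations along each branch. A six-model constraint ladder
(k = 6, 5, 4, 3, 3, 2) combining symmetric transitions, zero extinction and
symmetric speciation is fitted by maximum likelihood to every tree in a
posterior sample; the summary reports per-model mean AICc, mean δAICc,
parameter means with 95% HPD intervals, and the implied number of character
transitions (argmax ancestral states, tallied per tree).

**Concordance.** Robinson–Foulds distances, exact normalized quartet scores
(all four-taxon subsets enumerated), per-clade gene-tree support (gts),
"gene shopping" (the k loci with full sampling and lowest RF to the species
tree, default k = 12, RF < 0.15), species-by-genes occupancy, and QC
filtering with the study thresholds (mean heterozygous sites > 3% per locus,
< 50 loci per sample, locus recovery < ⅓ of samples).

## Worked example

Run the full analysis on the synthetic study fixture (a simulated 35-tip
relative-time tree carrying the real character table, with a 100-tree
pseudo-posterior):

```bash
stylotrace run --seed 1 --out-dir my_run
```

Output (abridged; numbers printed by the command):

```
QC: kept 58 loci, 35 samples; 2 exclusions
Concordance: normalized quartet score 0.988; occupancy 98.6% (2070 sequences)
Gene shopping: selected 12 loci: g4007, g4015, g4017, ...

Mk-n model comparison:
  model  k        lnL       AICc  delta_AICc  best
 mk5-ER  1 -47.413587  96.952175    0.000000  True
mk5-SYM 10 -40.168671 109.902560   12.950385 False
mk5-ARD 20 -34.544538 173.704461   76.752286 False
  transitions (weighted root): 15
  transitions (fixed:tristyly root): 15
  root marginals (weighted): distyly=0.20, tristyly=0.20, semihomostyly=0.20, ...
```

Reading this: the equal-rates model wins decisively (ΔAICc ≈ 13 to the
symmetric model), the reconstruction implies ~15 reproductive-system
changes across the 35-taxon tree, and the root state is thoroughly
ambiguous — the same qualitative picture as on the real data, where
reproductive systems are highly labile. The BiSSE section of the report
ranks the six-model ladder by mean AICc across the tree sample, with λ, μ,
q means and 95% HPD intervals per model in a diversification-table layout.

Library use mirrors the CLI:

```python
from stylotrace import simulate, summarize_mcc, fit_mk, MkModelSpec

fx = simulate.make_study_fixture(seed=1)
mcc = summarize_mcc(fx.sample)
fit = fit_mk(mcc, fx.chars5, MkModelSpec(5, "ER"))
print(fit.aicc, fit.theta)
```

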