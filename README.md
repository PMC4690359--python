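# cladix

Maximum-parsimony phylogenetics for discrete morphological matrices,
with stratigraphic congruence and ancestral-area reconstruction —
the complete analysis stack a systematist needs to go from a coded
character matrix (think a fossil-vertebrate dataset of tens of taxa and
a few hundred characters) to a supported, time-calibrated, geographically
annotated phylogenetic hypothesis.

## What it does

**Inference.** Characters are unordered (non-additive); a tree's score is
its parsimony length `L = Σ_c l_c`, the minimum number of state changes
summed over characters, computed by Fitch optimization generalized to
polytomies (unit-cost Sankoff). The heuristic search runs replicated
random-addition sequences refined by tree bisection–reconnection (TBR)
branch swapping, saves all equally parsimonious trees, collapses branches
whose minimum possible length is zero, and pools/deduplicates across
replicates. Ensemble indices are reported as

    CI = Σ m_c / Σ l_c     RI = (Σ g_c − Σ l_c) / (Σ g_c − Σ m_c)     RCI = CI·RI

with `m_c` the minimum and `g_c` the star-tree maximum steps of character
`c`. Supports come from reverse-constraint searches (Bremer decay) and
character bootstrapping; alternative placements can be scored with
enforced/forbidden monophyly constraints.

**Stratigraphic congruence.** Minimum-age calibration places each tip at
its first-appearance age (Ma) and each node at the oldest age among its
children; the gap `t(parent) − t(child)` on a branch is its ghost
lineage. The metrics are MIG (total implied gap, myr),
`GER = (G_max − MIG)/(G_max − G_min)` and `MSM* = G_min/MIG`, where the
extreme gap sums over all topologies have the closed forms
`G_min = a_max − a_min` and `G_max = Σ_i (a_max − a_i)` (certified
against exhaustive topology enumeration in the test suite). Polytomies
and age intervals are handled by reporting the full range of each metric
over binary resolutions and age endpoints; trees with different taxon
samples are first trimmed to their shared taxa.

**Biogeography.** Each terminal carries one of six continental areas.
Ancestral areas are traced on a fixed topology by parsimony (MPR state
sets, uniform pie weights at equivocal nodes) and by marginal likelihood
under the one-parameter symmetric Mk model,
`P(i→j,t) = 1/k − e^{−kαt}/k` for `i≠j`, with the rate α fitted by
maximum likelihood and a flat root prior. Branch lengths are either all
1 (LEB) or the ghost-lineage durations in myr with zeros replaced by 1
(LFR), the latter letting older taxa dominate the deeper nodes.

**Synthetic data.** A first-class generator produces the full input
suite with known ground truth: Yule trees in Ma, Mk-evolved multistate
characters with missing/inapplicable/polymorphic degradation, first
appearances drawn below the nodes with interval noise, and an Mk-evolved
geographic character.

## Worked example

```
cladix simulate --preset desk --seed 42 --out-dir demo
cladix run-all --matrix demo/matrix.tnt --ages demo/ages.csv \
       --areas demo/areas.csv --replicates 5 --seed 1 --out-dir demo/out
```

prints

```
{
 "best_length": 156,
 "ci": 0.859,
 "ger_range": [0.6751690010693991, 0.8967260658411007],
 "mig_consensus": 129.3,
 "n_mpts": 14,
 "n_unambiguous_changes": 46,
 "rci": 0.7002,
 "ri": 0.8151
}
```

— the shortest trees found need 156 steps (14 equally parsimonious trees
after collapsing), with consistency index 0.86 (little homoplasy, as
expected for clean simulated data); the strict consensus implies
129.3 myr of ghost lineages against the simulated first appearances, and
its gap excess ratio lies between 0.68 and 0.90 across polytomy
resolutions and age-interval endpoints. `demo/out/` holds the consensus
trees, the calibrated tree, the per-branch list of unambiguous character
changes, and the three ancestral-area tables (PB/LEB/LFR); e.g. the
likelihood/ghost-length pass reconstructs node `t15,t16` as
North America with probability 1.000.

Other subcommands (`search`, `consensus`, `support`, `synapo`,
`calibrate`, `stratcong`, `biogeo`) expose each stage separately; the
same functionality is importable from `cladix` as a library.

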