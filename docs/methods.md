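# Methods

This note records the models, conventions and numerical choices behind
cladix, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Character matrices

A cell is an observed state set, missing (`?`) or inapplicable (`-`,
with the typographic minus `−` accepted on input). Both unscorable kinds
behave as "any state" in parsimony scoring — reductive coding of
inapplicables is out of scope — but they are stored distinctly and
round-trip losslessly through the TNT and NEXUS writers. The one-letter
polymorphism code `a` means `{0,1}`; any other letter is a parse error
(failing loudly beats guessing an undefined code). General observed sets
are written as `[..]` (TNT) / `{..}` (NEXUS) groups. Matrices are
0-based internally; reports use 1-based character numbers in the
`character:state` notation conventional for synapomorphy lists.

## Parsimony

All characters are unordered with unit change cost. Lengths are computed
by unit-cost Sankoff dynamic programming, which is exact on
multifurcating trees; on binary trees it coincides with classic Fitch
(property-tested). Characters that cannot vary (all-missing or a single
observed state) contribute zeros to every sum, so CI/RI denominators
remain well defined; because some programs exclude such
parsimony-uninformative characters instead, `ParsimonyScore` reports
both conventions (`ci` vs `ci_informative`, etc.).

Per-character bounds: `min = (#observed states − 1)` clamped at 0;
`max` is the star-tree length, `(#scorable taxa) − (best single-state
count)` with polymorphic cells resolved toward the majority state. The
star-tree identity is tested against scoring an explicit star tree.

MPR ("final") state sets are obtained from inside/outside cost vectors:
state `s` is in a node's set iff fixing the node to `s` still attains
the optimum. Sets are restricted to each character's observed state
universe. A change `c:s` on a branch is *unambiguous* iff the child's
final set is exactly `{s}` and `s` is absent from the parent's set —
i.e. every most-parsimonious reconstruction places the change there —
and, across a set of equally parsimonious trees, iff that holds in every
tree containing the branch's clade. All of this is verified against
explicit enumeration of optimal assignments at small n.

## Search

Trees are searched as unrooted binary topologies and rooted on a
designated outgroup (the first matrix taxon by default) for all
reporting; constraint clades are rooted the same way and may not contain
the outgroup. Random-addition starting trees insert each taxon at a
length-minimizing branch, ties broken uniformly under the seed. TBR
neighborhoods are evaluated without full rescoring: cutting an edge
yields two fragments whose lengths are rooting-invariant, and the length
after reconnecting at edges `g`, `f` is
`L_A + L_B + w·[R_A(g) ∩ R_B(f) = ∅]` with `R` the per-edge Fitch root
sets — an exact identity for binary trees, checked against full
rescoring through the exhaustive-search parity tests. Equal-length trees
are collected up to a cap and each saved tree is swapped to completion.

Branch collapsing follows the minimum-length-zero rule: a branch is
collapsible when every character admits an optimal reconstruction with
no change on it. Contracting one such branch never alters tree length,
but contracting several at once can, because different branches may
require different reconstructions; the implementation therefore applies
the batch only after verifying the length is preserved and otherwise
contracts one branch at a time in postorder. Duplicate trees are
detected by canonical rooted-clade fingerprints after collapsing.

Bremer supports forbid each strict-consensus clade in turn and report
the extra steps of the best constraint-satisfying tree. Clades
containing all taxa but one are skipped: rooted on the outgroup they are
present in every tree, so no reverse-constraint search can break them.
Bootstrap pseudoreplicates resample characters with replacement
(implemented as per-character weights), run a reduced search, and tally
strict-consensus clades.

Two named presets ship: a desk-scale default (50 replicates, hold 500)
and a publication-scale protocol (10,000 replicates, hold 10,000). The
test suite and the acceptance script use explicit small configs
(3–8 replicates, holds of 50–200) chosen so the whole suite runs in a
few minutes on one CPU; search quality at those sizes is pinned by the
exhaustive-oracle parity tests rather than by protocol size.

## Stratigraphic congruence

Calibration is minimum-age: no positive padding is added below nodes,
so ghost durations are the minimal gaps the topology implies, and
zero-length terminal ghosts are allowed. Ages are Ma before present,
durations myr, reported to 0.1 myr.

The extremal gap sums used by GER and MSM* are computed from derived
closed forms — `G_min = a_max − a_min` (oldest-first pectinate tree:
all gaps telescope along the spine) and `G_max = Σ (a_max − a_i)`
(youngest-first pectinate tree: every internal node is dragged to the
oldest age) — certified against exhaustive enumeration of all rooted
binary topologies for n ≤ 8 in the acceptance suite. Degenerate
denominators (all ages equal, or MIG = 0) yield an explicit `None`
rather than NaN.

Uncertainty handling reports `[min, max]` of each metric over (a) binary
resolutions of every polytomy — exhaustive while the resolution count is
within a configurable cap, otherwise seeded random pairings, flagged
`sampled` with the evaluation count — and (b) per-taxon age-interval
endpoints, enumerated exhaustively up to 12 uncertain taxa and otherwise
explored by a seeded endpoint sample that always includes the all-oldest
and all-youngest corners. MIG is convex in the age vector (each node age
is a max of leaf ages), so the upper endpoint search is exact; endpoint
enumeration is the stated convention for both ends.

## Ancestral areas

The area character has one state per continental area in a fixed order
(South America, Africa, Asia, North America, Europe, Australia), so the
taxon→state map never depends on input order. Parsimony tracing puts
uniform weight on each node's MPR set. Likelihood tracing uses the
single-rate symmetric Mk model — interpreted as the standard default of
ancestral-state tracing tools, the only one-parameter option — with the
rate fitted by bounded search on log α to an absolute tolerance of 1e−8
and a flat root prior (for this model the stationary distribution is
also flat, so the usual alternative prior coincides). Marginals come
from an inside–outside two-pass with per-node rescaling and are checked
against full enumeration over ancestral assignments at 1e−10. The ghost
branch-length scheme replaces exact zeros by 1 so transition matrices
stay non-degenerate while older taxa keep their leverage. Monomorphic
area data leave the rate unidentifiable and are rejected with a pointer
to the parsimony tracer.

## Synthetic data

The generator is a pure-birth (Yule) process — the simplest tree process
that, combined with first appearances drawn uniformly along terminal
branches, produces realistic ghost-lineage structure; extinction adds
nothing for testing these metrics. Defaults emulate a published-scale
basal-dinosaur study: 65 taxa × 255 characters with up to four states, a
birth rate of 0.03/lineage/myr (root depth on the order of 150 myr), a
character rate of 0.0015/myr (a few changes per character per tree, the
homoplasy level of real morphological matrices), 35% missing, 3%
inapplicable and 0.5% polymorphic cells, and ±2.5 myr (stage-level)
age-interval noise. Degradation is i.i.d. per cell; a `block_missing`
mode wipes a contiguous character range per taxon to mimic whole missing
anatomical regions. What passing tests on these data show is that the
algorithms are correct and the pipeline recovers known truth under the
model's assumptions; they do not certify performance under correlated
characters, ascertainment bias, or non-random fossil sampling, none of
which the generator emulates.

A measured limitation worth stating: with 100 independent Mk characters
on 16-taxon Yule trees at root-to-tip expected change ≈ 0.3 per
character, several percent of true internal branches acquire no
character change at all and homoplasy blurs more, so strict-consensus
clade recovery plateaus near 70% regardless of search effort (the
search itself is exhaustively verified optimal at small n). Recovery
statements on simulated data should therefore be read against that
data-limited ceiling.

## Reproducibility

Every stochastic component (addition order, tie-breaks, resampling,
simulation) draws from a NumPy generator seeded from a single integer;
identical seeds give bit-identical outputs, which the pipeline manifest
records alongside input digests and stage timings.
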