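# Methods

`flaxnet` reconstructs the history of a single candidate domestication
locus from an aligned set of wild and cultivated accessions.  The
pipeline is: segregating-site discovery → diversity and neutrality
statistics → haplotype collapse → reticulate parsimony network →
homoplasy-based recombination tests → calibrated node dating.  This
note records the models, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Coordinates, gaps, and missing data

All positions are 1-based, inclusive, on the alignment columns, so any
reported site can be compared directly with published alignment
positions.  `-` is a gap; any symbol outside `{A,C,G,T,-}` is missing.
Substitution statistics use complete deletion (columns containing a gap
are excluded); maximal runs of identical gap patterns are collapsed
into *indel events*, each carried as a single presence/absence
character.  Indel events never enter S, π, or the neutrality tests —
they are network characters only (default weight 1, configurable).
Nucleotide diversity defaults to pairwise deletion (`gap_mode`
exposes complete deletion as well), matching the behaviour of the
standard interactive packages for locus surveys of this kind.

## Diversity and neutrality statistics

* π (Nei): mean pairwise difference per analysed site over all
  unordered sample pairs.
* Watterson's θ from the segregating-site count and the harmonic
  number a₁ = Σ 1/i.
* Tajima's D contrasts π with θ_W under the standard variance
  normalisation; significance bands come from the generalized-beta
  approximation of D's null distribution given in the statistic's
  original derivation.  Undefined cells (S = 0 or n < 4) are reported
  as `nd`, never as zero.
* Fu & Li's D* and F* (outgroup-free) use the corrected variance
  coefficients in standard use; their significance bands use a normal
  approximation of the variance-normalised statistic and are labelled
  approximate.  The original critical-value tables were not re-keyed;
  the bands are reporting aids and nothing downstream consumes them.
* Hudson–Kaplan R_m: all biallelic site pairs showing four gametes are
  reduced — intervals containing a smaller incompatible interval are
  dropped, then a left-to-right greedy scan keeps a maximal set of
  disjoint open intervals.  The greedy scan is optimal for this
  interval-scheduling problem; tests verify it against an independent
  recursive maximiser.

## Haplotype network

Samples are collapsed over a binary-recoded character matrix: one 0/1
character per biallelic site (k−1 characters for a k-allele site, one
per non-majority allele) plus one character per indel event.  The
network is a median-joining-style parsimony graph at ε = 0:

1. connect haplotypes with every link that belongs to at least one
   minimum spanning tree (an edge of weight w is kept iff its endpoints
   are disconnected in the graph of strictly lighter edges), so that
   equally parsimonious alternatives remain visible as cycles;
2. for each connected node triple, insert the majority-consensus median
   vector when the star through it is strictly shorter than the
   existing two-link path; iterate to a fixed point;
3. prune unsampled nodes whose degree falls to ≤ 2 (they lie on a path
   and no longer shorten the graph).

Edges are labelled with the characters changing along them; the network
substitution count m counts label occurrences including repeats.  A
*homoplasy* is a character on ≥ 2 edges; the homoplasy count is
Σ (occurrences − 1) over substitution characters.  All iteration orders
are sorted, so identical inputs give byte-identical exports (GraphML,
DOT, haplotype TSV, NEXUS).

The domestication common ancestor (DCA) is the node minimising the
total shortest parsimony path length to every node containing
cultivated members, ties broken by fewest homoplasious characters on
the connecting paths, then node id.

## Homoplasy model and recombination tests

Under uniform mutation over L sites, a new mutation repeats an earlier
one (same position and same derived base, hence the factor 1/3) with
probability p = (1/3)(1/L)·m, where m is the network substitution
count; the expected number of homoplasies among the m mutations is
E = m²/(3L).  Each reticulation cycle is tested by the branch carrying
homoplasious characters: with N substitutions of which H are repeats,
the upper-tail binomial P(X ≥ H | N, p) scores how implausible repeat
mutation is as the explanation — small P favours recombination.  When
several branches of one cycle carry homoplasies, all are tested and the
event keeps the smallest P with an ambiguity flag.  The network-wide
count is reported both as the point probability P(X = H_net) and the
upper tail P(X ≥ H_net) under Binomial(m, p); published summaries of
this kind sometimes print the point value while describing a tail test,
so both are labelled.  Tests use full-precision p, not a rounded
mirror; the printed mirrors (one significant figure for p, truncation
to two decimals for E) are exposed separately.

For each event the two ancestral candidates are the cycle neighbours of
the recombinant corner (the endpoint of the tested branch farther from
the DCA) — the opposite corners of the reticulation.  Events are
labelled R1…Rk ordered by distance of the cycle from the DCA.

## Chronology

A single calibration (node of known age T over L sites) fixes the clock
r = k/(L·T) with k the node's substitution depth, and every node is
dated as age = d/(r·L).  Depth d is measured to the node's *strict*
sampled descendants — an extant ancestral haplotype is dated by the
lineages it founded, not by its own persistence — with `depth_mode`
choosing the mean (default), maximum, or minimum tip path.  Descent is
oriented from a root (the DCA unless overridden): a sampled node t
counts as a descendant of v when v lies on a shortest parsimony path
from the root to t.  On reticulations the minimum-substitution route is
used and flagged in the log.  The calibration node's own age reproduces
T exactly under every depth mode, and halving T doubles the rate and
halves every age (tested invariants).

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
a genealogy whose nodes are all sampled haplotypes (extant ancestral
states), infinite-sites mutations (fixed count or Poisson per branch),
exact-repeat homoplasies, optional recombinant mosaics appended as
extra nodes, one multi-base indel carried by a clade, and
group-structured sampling.  Key properties:

* A planted homoplasy is placed on a branch that neither shares a node
  with nor is ancestrally related to the original branch; under that
  placement a single-origin explanation is never shorter, so the
  planted count is exactly recoverable from the network.  Sibling or
  nested placements would be silently absorbed — the generator refuses
  them.
* A recombinant is detectable only if its parents' differences
  interleave around the breakpoint; `breakpoint=None` searches balanced
  breakpoints for one that verifiably produces a four-gamete pair among
  the realised nodes and raises an error when none exists.  Even a
  detectable mosaic between very distant parents can be absorbed by
  median nodes in an ε = 0 network (a known property of such networks);
  the preset plants the recombinant where the reticulation survives.
* The truth record (root sequence, per-branch mutations, homoplasies,
  breakpoints, indel carriers, sample map) replays to a byte-identical
  alignment, and a fixed seed makes the whole output reproducible.

`paperlike_preset()` fixes a survey-scale configuration: 113 samples in
8 groups over 11 haplotypes (one a recombinant mosaic), L = 2560, four
substitutions per branch (~40 network substitutions), two planted
repeats, and a 46-bp indel at columns 562–607 shared by a wild clade
and the primitive cultivated group; wild groups span more haplotypes
than the bottlenecked cultivated groups, so wild π exceeds cultivated
π.  What the generator does **not** emulate: sequencing error,
alignment ambiguity, rate heterogeneity along the locus, gene
conversion, and coalescent-with-recombination genealogies (mosaics are
single or chained crossovers between realised haplotypes).  Passing
tests therefore demonstrate correctness of the estimators and the
detection machinery under the stated generative model, not robustness
to real-data artefacts.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale inputs: the
homoplasy/binomial/calibration values are closed-form; oracle
comparisons use hundreds of small random fixtures (n ≤ 10, L ≤ 50);
the Monte-Carlo calibration check uses 1000 replicates of an 8-branch
genealogy at L = 500, with agreement judged within three standard
errors.  Every stochastic component is driven by an explicit seed, and
all tie-breaks (haplotype ids, node orderings, event labels) are
deterministic, so repeated runs are byte-identical.
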