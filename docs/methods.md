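# Methods

This note documents the models, parameter choices, and numerical
behaviour of `picobirnatax`, and what the synthetic-data generators do
and do not emulate.

## Tree model and Newick dialects

Trees are stored as rooted node hierarchies; an unrooted tree is kept
rooted at an arbitrary node and flagged, and every bipartition-based
computation is invariant to that choice. Branch support values are
percentages in [0, 100] attached to internal nodes and are treated as a
property of the edge above the node: rerooting moves them with their
edge, and rooting *on* an edge leaves the support on the surviving lower
half (the two root-adjacent edges of a rooted binary tree represent the
same split). Two support dialects are read: numeric internal-node labels
(IQ-TREE style) and bracketed numeric comments. Numeric labels outside
[0, 100] are kept as clade names, not supports. Polytomies are first
class and never silently resolved; tip-label matching is exact and
case-sensitive after stripping surrounding quotes.

Midpoint rooting requires all branch lengths, examines every tip pair
(ties on path length are broken by the lexicographically smallest sorted
tip pair, making the operation deterministic), and is idempotent.
Outgroup rooting requires the outgroup to form one side of an edge under
some rooting and otherwise raises an error naming the intruding tips.

## Consensus genus classification

The classification procedure has three tunable thresholds:

* `min_support` (percent, default 80) — the clade support below which a
  grouping is not trusted;
* `min_stem_factor` (default 2.0) — a seed clade's stem branch must be at
  least this multiple of the median internal branch length, formalizing
  "long branch to the common ancestor";
* `purity` (default 0.90) — the minimum fraction of a candidate clade's
  tips that must be seed members.

Seed detection scans every internal node and keeps the maximal
non-nested clades satisfying all three criteria plus a minimum size
(default 5). Automatic detection formalizes what is otherwise a visual
judgement; user-supplied seeds bypass it.

Within each ensemble tree, a seed's *representative clade* is the
qualifying node (support ≥ `min_support`, purity ≥ `purity`) containing
the most seed members, ties broken by higher purity, then smaller clade,
then lexicographically smallest tip set. A strict reading — requiring
the entire seed to be monophyletic at ≥ 80% support — would unclassify a
whole genus whenever a single rogue taxon moved, which contradicts how
such screens retain the vast majority of sequences in practice; the
purity-tolerant representative rule is our operationalization. Tips
inside the representative clade in **every** tree are core members;
everything else is unclassified. By default all ensemble trees must
share the tip set (`allow_missing_tips` relaxes this to "consistent in
every tree where present"). One exclusion pass is performed; seeds are
evaluated independently of one another. The assigned **count** is
monotone non-increasing in `min_support`, but individual tips may flip
when a threshold change alters which clade is the representative.

## nPH85 distance

`nPH85 = |B_v Δ B_h| / (|B_v| + |B_h|)` over non-trivial bipartition
sets of the two unrooted trees; 0 iff the split sets coincide, 1 iff
they are disjoint, and 0 by convention when neither tree has a
non-trivial split. Because virus tips usually map many-to-one onto host
taxa, the comparison needs a bridging convention, and the choice is
exposed rather than hidden:

* `expanded-host-tree` (default): each host tip is replaced by a
  polytomy of its mapped virus tips, so both trees share a leaf set. The
  host-side polytomies contribute no splits of their own, so structure
  *within* a host is never penalized.
* `resample-one-per-host`: draw one virus per host uniformly (seeded),
  restrict both trees to the draw, and average the normalized split
  distance over replicates (default 100).

Both modes give 0 for a perfectly co-diverging history; they differ in
how intra-host radiations are weighted.

## DTL reconciliation

The reconciliation is an undated duplication–transfer–loss parsimony
model: the host tree is a cladogram without dates, so transfers are
allowed between any two non-ancestrally-related host edges, with no
further time consistency imposed. Event costs default to 0 for
co-divergence and 1 each for cross-species transmission (transfer),
duplication, and extinction (loss); both vocabularies are emitted in
machine-readable output.

Model choice: a transferred child lands *directly* on its recipient
node, and losses are charged only along within-subtree descents. With a
positive loss cost this yields the same minimum cost as formulations
that let a transfer land high and lose its way down (those solutions are
strictly costlier), and it makes "the number of optimal reconciliations"
a well-defined count of distinct event-labelled embeddings — the
quantity the MPR counter and the uniform sampler operate on. The dynamic
program runs in O(|V|·|H|²) time over (virus node, host node) pairs;
optima are compared with an absolute tolerance of 1e-9, and MPR counts
use exact big-integer arithmetic.

Event likelihoods are estimated by stochastic backtracking through the
DP tables with choices weighted by optimal-solution counts, which draws
uniformly from the MPR set; each sample's event proportions use all
events (losses included) in the denominator, and the reported likelihood
is the mean over samples (default 100, seeded, reproducible
bit-for-bit). The virus tree must be fully resolved; host polytomies are
binarized by a seeded random caterpillar expansion with zero-length
branches, and the resolved tree and polytomy count are reported for
audit.

## RBS scanning

The scanner extracts the 24 nt immediately 5ʹ of each annotated ORF's
start codon (CDS features define ORFs; the first codon is taken as the
start without requiring ATG, since alternative genetic codes occur in
these viruses). Motif classes are searched longest-first — AGGAGG, then
AGGAG/GGAGG, then AGGA/GGAG/GAGG — and an ORF is assigned the longest
class with a match wholly inside the window, making the classes mutually
exclusive and the per-class counts additive to the motif-bearing total.
A match may not overlap the start codon. Windows of non-first ORFs may
overlap upstream coding sequence and are scanned as-is; windows shorter
than 24 nt (possible only for non-first ORFs, since segments without a
full 5ʹ UTR ahead of their first ORF are filtered out) are scanned at
their available length and flagged. Minus-strand ORFs are
reverse-complemented into plus orientation before windowing, with a
warning. Percentages are computed per dataset as 100 × count / ORFs and
rounded half-up to one decimal — the convention used when such tables
are printed, and the reason the `decimal` module is used rather than
binary floating-point rounding.

## Synthetic-data generators

All generators are reproducible bit-for-bit from (parameters, seed).

* **Cophylogeny histories.** A virus lineage descends a binary host tree
  from the root. At each host bifurcation it co-diverges with probability
  `1 − (p_transfer + p_duplication + p_loss)`; otherwise it transfers
  (the donor descendant continues down one uniformly chosen side of the
  bifurcation and the recipient jumps to a uniformly chosen
  non-ancestral host node), duplicates (both copies re-enter the same
  bifurcation), or dies. Having the donor lineage keep descending after
  a transfer keeps the branching process subcritical, so realized tree
  sizes stay near the host size even at transfer rates of 0.5.
  Branching events with one side entirely lost collapse out of the
  realized tree; recorded event counts refer to surviving internal nodes
  (each tagged with its event) plus drawn losses, so internal virus
  nodes = cospeciations + transfers + duplications by construction. The
  generator shares the reconciliation's event vocabulary, making
  rate-recovery experiments well-posed, but it is *not* the DP run in
  reverse: reconciliation of a simulated history recovers rates up to
  parsimony's usual compression of loss-heavy scenarios.
* **Planted ensembles.** Each tree re-draws within-cluster topologies
  and supports (default range 85–100) above long cluster stems (default
  1.0 vs within-cluster branches of 0.05–0.15), and joins clusters on a
  weakly supported backbone (supports 30–75, mirroring the instability
  of deep relationships across outgroup choices). Migrant tips are
  relocated into foreign clusters — distinct targets per tree where
  possible, so a 12-tip cluster receiving one migrant keeps purity
  12/13 ≈ 0.92 above the 0.9 default — in at least one tree each; the
  relocation schedule is recorded as ground truth.
* **Planted segments.** Upstream windows are built on background
  sequence rejected until it contains no RBS 4-mer (hence no 5/6-mer),
  with the drawn class's motif spliced at a random admissible offset and
  the whole window re-checked so flanking bases cannot upgrade the
  class. This makes scanner tests exact rather than statistical. A
  deterministic composition mode plants exact per-class ORF counts.
  Default per-ORF class probabilities (0.5, 0.2, 0.1, 0.2) for
  (6-mer, 5-mer, 4-mer, none) correspond to a strongly motif-enriched
  genome of the kind the scanner is designed to flag. ORF bodies are
  random stop-free codons behind an ATG — there is no codon-usage or
  secondary-structure realism, and windows never overlap real coding
  sequence, so passing these tests demonstrates correct window
  arithmetic and classification, not robustness to messy annotations.

The bundled animal-host cladogram (`ANIMAL_HOST_CLADOGRAM`) is a
synthetic, hand-built stand-in following textbook vertebrate and
invertebrate relationships over the host source categories; it asserts
no published phylogeny.

## Problem sizes and numerical conventions

The test suite verifies the reconciliation DP against exhaustive
enumeration of every event-labelled embedding on instances of up to 5
virus and 5 host tips (200 random instances plus randomized-cost
variants), uniformity of MPR sampling at 10,000 draws on an instance
with exactly two optima, and monotone recovery of planted host-switch
rates over 10 levels × 20 replicates on 16-tip hosts — sizes chosen so
the full suite completes in well under a minute while the brute-force
oracles remain tractable. Larger trees are exercised without oracles
(property tests on up to 40 tips). Percentages use decimal half-up
rounding; DP cost comparisons use a 1e-9 absolute tolerance; all random
streams derive from explicit integer seeds.

## Known limitations

* The undated DTL model cannot distinguish time-consistent from
  time-inconsistent transfer scenarios; with a dated host tree a dated
  model would be preferable.
* Event likelihoods are frequencies over *optimal* reconciliations only;
  they carry no posterior uncertainty.
* `nPH85` treats all splits equally; branch lengths and supports do not
  weight the comparison.
* The classification screen assumes the ensemble trees are estimates of
  one underlying topology; it has no concept of reticulate history.
* RBS scanning is descriptive — no enrichment test between groups, no
  spacing or free-energy model of ribosome binding.
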