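# Methods

`phyloplace` places anonymous sequence fragments onto a *fixed*
reference phylogeny by maximum likelihood (or maximum parsimony),
mirroring the classic marker-gene binning workflow for environmental
shotgun data: detect a marker on a raw nucleotide fragment, extract and
align the peptide, trim unreliable columns, and insert the aligned row
into every branch of a reference tree, reporting the best-scoring
branch.

## The placement model

The reference is a tree with branch lengths in expected substitutions
per site and an amino-acid alignment over its leaves.  Likelihoods use
a reversible empirical model: exchangeabilities `S` and equilibrium
frequencies `π` combine into `Q_ij = c·S_ij·π_j` with `c` normalizing
`−Σ π_i Q_ii = 1`.  Among-site rate variation is the discrete-Gamma
mixture with `K = 4` equal-probability categories whose rates are the
category *means* of Gamma(α, α), renormalized to mean exactly 1 (the
convention of the common ML phylogenetics engines; medians are the
other convention and give slightly different rates).  WAG is the
default matrix; RtREV, cpREV and Blosum62 (in its rate-matrix form) are
shipped for families where they fit better.  Published frequencies are
used; alignment-derived ("+F") frequencies are not.

Likelihood is computed by Felsenstein pruning on the unrooted view of
the tree (a degree-2 root is a modelling fiction under reversibility;
the two root-adjacent edges act as one placement branch, and results
are mapped back to the rooted edges for reporting).  Columns are
compressed to unique site patterns; underflow is handled by per-node,
per-pattern scaling factors shared across rate categories so the Gamma
mixture stays exact.

**Reference fitting.**  Branch lengths are optimized one at a time by
bounded derivative-free 1-D search (`[1e-8, 20]`, xatol 1e-8 at the
optimizer level), sweeping all branches and then the Gamma shape
(`α ∈ [0.02, 100]`) until a sweep gains less than `1e-4` log units
(at most 100 sweeps; non-convergence is an error).  Every conditional
vector is recomputed after each accepted change, so the total
log-likelihood is non-decreasing by construction.  Fitting works on an
internal copy: the caller's tree object is never modified.

**Insertion.**  For each placement branch the engine caches conditional
likelihood vectors toward both branch ends.  Attaching a query splits
the branch at distance `d` from the distal end and adds a pendant edge
of length `p`; `(d, p)` are optimized by coordinate sweeps (at most 8
rounds, stop when a round gains < 1e-6; 1-D tolerance 1e-6) starting
from `d = t/2`, `p = 0.1` — the mid-branch start is symmetric and the
0.1 pendant is a typical within-genus distance.  `d + (t−d) = t` holds
exactly, so the reference branch is conserved.  Scoring one branch
costs O(sites × states) and touches no reference vectors.  Rank 1 is
the highest log-likelihood; ties below 1e-9 go to the smaller branch
id.  Likelihood weight ratios are the softmax of per-branch log
likelihoods over all evaluated branches (the jplace convention).

**Bootstrap.**  Non-parametric bootstrap resamples post-trim query
columns with replacement, implemented as reweighting of joint
(reference-pattern, query-residue) site patterns.  Following the
candidate heuristic, only the top `⌈0.10·B⌉` branches ranked on the
original alignment are re-scored per replicate (the ceiling guarantees
at least one candidate, and the rank-1 branch is always included);
each replicate is awarded to its best candidate and support is the
win fraction.  Replicates warm-start from the original optimum and use
a coarser 1-D tolerance (1e-4) — support values are reported to two
decimals, far above that resolution.  Seeded runs are bit-reproducible.

**Parsimony engine.**  Fitch sets over the 20-letter alphabet are
20-bit masks; gaps/X/* are wildcards.  Down- and out-sets toward both
ends of every branch are precomputed; because the Fitch length of a
binary tree is invariant under rerooting, rooting the joined tree at
the query tip yields the exact insertion score from the cached sets.
Multifurcating inputs are combined pairwise in branch-id order (exact
for binary trees, a standard convention otherwise).  Uniform-cost
Fitch is used, not Sankoff.

## Preprocessing

Six-frame translation uses the standard genetic code; ambiguous codons
become `X` and internal stops stay `*` (both are missing data
downstream).  Frames `−1..−3` translate the reverse complement.  The
marker profile is the per-column residue frequency of the reference
alignment with pseudocount 0.1 per residue; the background is the
model's `π`.  Frame selection takes the best glocal log-odds alignment
score over the six translations (ties in the order +1,+2,+3,−1,−2,−3);
a fragment is considered marker-free when its score does not exceed the
99th percentile of scores of residue-shuffled copies (seeded).  The
glocal aligner is an affine-gap dynamic program (open 11, extend 1)
with free flanks on both sequences; peptide residues aligned as
insertions relative to the reference are discarded, so the output row
has exactly one symbol per reference column.

Column trimming follows the conserved-block scheme: a column is
*conserved* when more than half the rows share one residue, *highly
conserved* when at least `b2 = max(⌈0.55·rows⌉, ⌊rows/2⌋+1)` do;
columns with more than half gaps are removed outright (the "half" gap
allowance).  Stretches of more than `b3 = 15` contiguous nonconserved
columns are rejected, remaining blocks are trimmed back to highly
conserved flank positions, and blocks shorter than `b4 = 3` are
dropped.  Trimming masks query residues rather than deleting reference
columns, so placement always sees the same coordinate system.  Rows
with fewer than 50 residues after trimming are discarded (inclusive
boundary: 50 is kept).  When several markers occur on one fragment
their aligned rows are concatenated column-wise in a fixed marker
order over a shared reference taxon set, gap-filling absent markers.

## Synthetic data

The generator supplies everything the validation design needs without
external data.  Topologies come from sequential random attachment
(uniformly chosen edge split per added leaf) with exponential branch
lengths of mean 0.1 substitutions/site — a typical marker-gene scale;
sequences evolve from stationary root states with per-site Gamma(α=1)
rate categories.  Planted queries re-derive the same realization from
the package seed, draw the branch midpoint state as a bridge
conditioned on *both* branch-end states, and evolve a pendant of 0.05
substitutions/site (a within-genus distance; a separate query seed
varies queries against one reference).  Synthetic genomes back-translate
marker peptides with uniform synonymous codons, embed them on random
strands between uniform-ACGT spacers, and record coordinates and frames
for truth checking.  Lineages (7 ranks) are derived from tree
structure, so two leaves agree at rank *k* exactly when they share the
ancestor *k*+1 steps below the root.

What the generator does **not** emulate: indels (reference alignments
are gap-free, so trimming on synthetic data is nearly a no-op),
sequencing errors and frameshifts, codon usage bias, compositional
heterogeneity across lineages, and paralogy.  Passing tests therefore
demonstrate correctness of the algorithms and calibrated behavior
under the model's own assumptions, not robustness to real-data
artifacts.

## Validation harness

Leave-one-out: remove a target leaf (or the clade `depth` ancestors
around it), record the branch its attachment point collapses onto,
fragment its synthetic genome into non-overlapping 1000-bp pieces
(remainder discarded), and run every fragment through the full
pipeline against the reduced, refitted reference.  Correctness is the
node distance between observed and true branch — the number of nodes
on the unrooted path strictly between the two branches (0 = same
branch, 1 = sharing an endpoint), pinned by a breadth-first-search
oracle; a placement within two nodes counts as correct.  Taxonomic
assignment takes the leaf set *below* the placement branch (leafward in
the rooted orientation) and returns the longest lineage prefix shared
by all of it; accuracy at phylum/order/family asks whether that prefix
agrees with the target's true lineage through the respective rank.

Problem sizes used by the test suite and the acceptance script — 20
leaves / 300 columns for placement recovery (50 planted queries),
10 leaves / 5000 sites for branch-length recovery, 14–16 leaves for
leave-one-out with 3–4 targets, B = 100 bootstrap replicates, and
10 000 replicates for the distinct-column statistic — were chosen as
the smallest sizes at which the checked effects are comfortably
resolved.

## Known limitations

* The detection stage is a profile-score gate, not a homology search
  against decoys; deep paralogs of real families would not be screened
  out.
* Frameshifted fragments yield at best the longer consistent-frame
  piece; there is no frameshift correction.
* The α estimate is a point estimate by the same 1-D optimizer; no
  proportion-of-invariant-sites term is available.
* jplace output reports all evaluated branches per query; consumers
  expecting a truncated list should filter on `like_weight_ratio`.
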