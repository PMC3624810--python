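# Methods

This note records the models, defaults and numerical choices behind
`gapguide`, and what the simulated benchmarks do and do not establish.

## Sequence simulation (`seqsim`)

Evolution runs root-to-tips along a user tree. Per branch of length *t*
(expected substitutions/site):

- **Substitutions.** Each residue is replaced with probability
  `1 − exp(−λ_s · t)` (default substitution rate λ_s = 1.0); the
  replacement is drawn from the residue frequency vector, so a fraction of
  "replacements" silently restore the same residue, as in standard
  exchangeability-free models. Frequencies default to uniform over the 20
  amino acids: residue identity is irrelevant to gap bookkeeping, and an
  empirical matrix (WAG/LG) would add realism the gap analyses never read.
- **Indels.** The number of events is Poisson with mean
  `λ_i · L · t`, where L is the branch-start residue count and the indel
  rate λ_i defaults to 0.02 events/site/unit branch length — 2% of the
  substitution rate, inside the 1–10% range usually quoted for protein
  families. Event lengths are geometric with p = 1/3 (mean 3 residues);
  insertions and deletions are equally likely. Insertions place fresh
  residues between two existing ones and create new alignment columns that
  are gaps in every lineage not descending from the event; deletions turn
  residues into gaps in the affected lineage only. A deletion is truncated
  so that no lineage ever loses its last residue.

The master-column bookkeeping makes the emitted *true alignment* exact by
construction. Columns retained by no leaf (insertions later deleted along
every surviving path) are dropped, so no all-gap column is ever emitted;
events whose columns all vanished are logged with site −1. Per-set seeds of
multi-set datasets are derived from the master seed via
`numpy.random.SeedSequence((master, index))`, so any gene set can be
regenerated in isolation.

Default study conditions: trees are balanced ("symmetric") or caterpillar
("asymmetric") with every branch 0.25 substitutions/site, 32 taxa and root
length 300 for full-size datasets; the scripted experiments use a
desk-scale replica of 20 gene sets × 16 taxa, which already yields a few
hundred gapped columns per set.

What the simulator does *not* emulate: rate heterogeneity across sites,
empirical exchangeabilities, length-dependent indel hotspots, domain-level
rearrangements. Conclusions drawn from these benchmarks are therefore
about the *mechanics* of guide-tree-driven gap placement, not about the
absolute accuracy any aligner would reach on real proteins.

## Progressive aligner (`aligner`)

A deliberately minimal aligner whose contract is guide-tree fidelity:
profiles are merged exactly in the post-order of the supplied tree, and
the merge log records every step so that fidelity is testable. Scoring is
Gotoh affine-gap dynamic programming; the substitution term between two
profile columns is the mean sum-of-pairs BLOSUM62 score over residue pairs
(gap open −10, extend −1, both configurable). Gap penalties are charged
once per profile, not per sequence.

Numerical choices: the DP is vectorised row-wise (the within-row "left"
state is resolved with a prefix-cummax identity), the traceback recovers
states with 1e-9-tolerant score comparisons, and ties are broken
deterministically diagonal > up > left — identical inputs always give
byte-identical alignments. Guide-trees without a root are midpoint-rooted
by an explicit longest-path search that always roots on an *edge* (never
absorbing a leaf); zero-length or star trees fall back to merging the
root polytomy in child order. When no guide-tree is given, one is
estimated by neighbour joining (scikit-bio) on pairwise distances
(1 − fractional identity over aligned residue pairs, from pairwise Gotoh
alignments); negative NJ branch-length estimates are clamped to zero.

## Gap-placement scoring (`gapscore`)

A gap opening is anchored by the number of the row's residues strictly
preceding the gap block (0 = before the first residue, L = after the
last); adjacent gap characters form a single block. Because two blocks in
one row cannot open at the same site, a binary per-(sequence, site)
indicator is lossless. Every slot 0..L of every sequence is classified
TP/FP/FN/TN. Terminal slots are scored like internal ones by default
(`include_terminal=False` to exclude), since no exclusion rule is obvious
a priori; precision with TP+FP = 0 is reported as `None` — not 0 or 1 —
and excluded from averages rather than silently biasing them.

## Tree comparison and wrong trees (`treemetrics`)

The normalized split distance is `|S1 Δ S2| / (|S1| + |S2|)` over
nontrivial bipartitions. For fully resolved trees this equals the familiar
"fraction of wrong splits" (Robinson–Foulds / 2(n−3)); the
symmetric-difference normalisation is preferred because it degrades
gracefully on partially resolved (e.g. consensus) trees. Rooted inputs are
unrooted before split extraction; branch lengths are ignored.

Wrong trees (split distance exactly 1) are found by seeded rejection
sampling: caterpillars over random leaf permutations first — they almost
never share a split with a fixed tree — then uniformly grown random
topologies, with the attempt budget and best-reached distance reported on
failure. Many maximally wrong trees exist; the seed picks one
reproducibly, and sampling several seeds reproduces the robustness control
of using alternative wrong trees. Trees at intermediate target distances
are produced by a seeded NNI random walk accepting moves that shrink
|distance − target| (sideways moves accepted with probability 0.3 to
escape plateaus); distances on resolved n-leaf trees are quantised to
multiples of 1/(n−3), so callers must allow a tolerance of at least half a
step.

## Gap parsimony (`gapparsimony`)

Each alignment column containing at least one gap becomes one unweighted
binary character (gap = 1). Adjacent columns of one long gap block are
deliberately *not* merged — the character definition is per column;
block-level coding would change character counts and is left to the
caller. Scoring is unit-cost small parsimony via a Sankoff down-pass
(exact for polytomies, identical to Fitch/Wagner on binary characters),
vectorised across characters.

Search: exhaustive enumeration of all resolved unrooted topologies up to 9
taxa (an oracle for the heuristic), otherwise steepest-descent SPR
hill-climbing from a neighbour-joining start on Hamming distances plus
seeded random starts (default 10 restarts; the scripted desk-scale
experiments use 2–3, which already matches the exhaustive optimum on ≥95%
of random 7-taxon matrices). All equally parsimonious topologies
encountered are retained; downstream distances average over the tie set
rather than collapsing it to a consensus, so tie-rich genes do not get a
single arbitrary tree. A matrix with no variable character is flagged
`uninformative` and returns score 0 with a single arbitrary topology.

## Guidescore (`guidescore`)

A tree set is projected to the mean of its members' (distance-to-canonical,
distance-to-wrong) pairs — mean coordinates, not the coordinates of a
consensus tree, keeping the score decomposable per gene. In multi-gene
experiments coordinates are averaged first within a gene's tie set, then
across genes, so genes with many equally parsimonious trees carry the same
weight as genes with one. Both per-gene scores and aggregate
mean-coordinate scores appear in the report so either convention can be
read off. The guidescore itself is the Euclidean distance between two
projected points sharing the same (canonical, wrong) reference pair;
mismatched reference pairs are rejected.

## Heads-or-tails trimming (`hottrim`)

The forward alignment is compared with the alignment of the reversed
sequences mapped back to forward coordinates. A forward column's score is
the fraction of its co-aligned residue pairs that are also co-aligned in
the back-mapped alignment; columns with fewer than two residues are
vacuously consistent (1.0) because they carry exactly the gap patterns
under study. Columns scoring below the cutoff (default 0.05) are removed.

Scoring gap precision *after* trimming needs care: trimming removes
residues, so the trimmed alignment no longer aligns the same sequences as
the reference. The package therefore scores the openings of the untrimmed
alignment whose gap block survives trimming (at least one block column
kept), in original residue coordinates — directly comparable to the
reference opening map. Two blocks merged by a trimmed-out spacer still
count as their original openings. Only the forward alignment is scored;
n-way consistency across aligners is an extension point.

## Experiment driver (`experiment`, CLI `gapguide run`)

For each simulated gene set and each condition (own / canonical / wrong
guide-tree) the driver aligns, recodes, searches MP trees, and reports
split distances, gap precision/accuracy and pairwise condition
guidescores as TSV plus a JSON manifest; identical configs and seeds
reproduce reports byte for byte. Partial failures are isolated per gene
and reported in the table. Desk-scale defaults (20 sets × 16 taxa,
restarts 2–3) keep a full three-condition run in single-digit minutes on
one CPU; `n_sets`, `n_taxa` and `restarts` scale it up.

## Known limitations

- The aligner is a stand-in covering the progressive mechanism only — no
  consistency scoring, iterative refinement or phylogeny-aware gap
  placement; external aligner outputs can be imported as FASTA instead.
- The heads-or-tails consistency formula is one reasonable dialect of
  consistency scoring, not a re-implementation of any specific trimming
  tool.
- Simulated benchmarks use equal branch lengths and homogeneous rates;
  directions of effects (guide-tree pull on gap patterns, trimming
  enriching reliable gaps) are expected to transfer to real data, exact
  percentages are not.
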