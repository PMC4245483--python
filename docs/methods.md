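# Methods

This note documents the models, conventions and numerical choices behind
plastocmp, and what its simulation-based tests do and do not demonstrate
about real data.

## Quadripartite structure detection

The detector searches for the maximal pair of disjoint segments that are
*exact* reverse complements of each other, at least `min_ir_length` long
(default 1,000 bp — plastid inverted repeats are 20–26 kb, and the
threshold keeps tRNA-scale dispersed repeats out of consideration).
Seeding uses 31-mers shared between the sequence and its reverse
complement; seed pairs lying on one inverted-repeat pair share the
anti-diagonal `i + j`, so each repeat is extended exactly once, and
extension intervals are recorded per anti-diagonal so a fragment truncated
by the sequence start cannot shadow the full repeat. Of the two arcs
between the repeat copies (walking the circle), the shorter is the SSC and
the longer the LSC; all reported coordinates are 1-based inclusive on the
LSC-first linearization. Exactness is deliberate: the repeats of the
genomes this package targets are perfect, and an exact criterion gives a
sharp, parameter-free boundary. Degenerate cases raise typed errors: no
qualifying pair (structure not found), two equally maximal overlapping
pairs (ambiguous), adjacent copies with a zero-length single-copy arc
(not quadripartite).

Inputs are assumed already linearized; `rotate=True` runs the search on
the doubled sequence so a repeat copy may wrap the origin, and reports the
left-rotation that restores the LSC-first frame.

**IR reduction** removes the IR_B copy (LSC + IR + SSC remain). Because
the two repeats are identical, keeping both would give every
repeat-resident site twice the weight of a single-copy site in parsimony
and distance calculations; reduction makes each site count once. All
distances and trees are computed on reduced sequences by default; the full
genome is used for composition and structure reporting.

## Pairwise alignment and reference projection

Plastomes of congeneric taxa are collinear at sub-percent divergence, so
no rearrangement handling (locally collinear blocks) is needed: a
reference-pivot alignment suffices and is this package's deliberate
replacement for progressive whole-genome aligners. Consequences: the
multiple-alignment column count is not comparable bit-for-bit with other
aligners' output, but variant events, site classes and tree statistics
are.

The aligner chains *k*-mer anchors (default *k* = 21, unique in both
sequences, merged along diagonals, heaviest colinear chain by weighted
longest-increasing-subsequence) and closes inter-anchor gaps with exact
affine dynamic programming (biopython's `PairwiseAligner` is the DP
engine). Scoring: match +1, mismatch −1, and a gap of length *L* costs
4 + *L* (an opening penalty of 4 plus 1 per gap column — the convention is
stated because "open/extend" pairs are ambiguous about the first column,
and the test oracle uses the identical definition). Inputs of ≤ 5 kb are
aligned by full DP outright, which is optimal by construction; the test
suite checks that the anchored path reaches the same optimum on
low-divergence pairs. Gap runs are normalized by left-shifting within
equal-letter runs of the opposite row, which changes neither the degapped
sequences nor the score but makes output deterministic.

`project_to_reference` unions the insertion columns of the per-taxon
pairwise alignments on reference coordinates. Insertions of different taxa
at the same reference position share columns (padded to the longest);
their bases are not re-aligned against each other — at these divergences
multi-taxon insertions at one position are rare and almost always private
to one taxon.

## Variant conventions

* One *event* per maximal run: a run of contiguous substituted columns of
  length 1 is a SNP, of length ≥ 2 an MNV; a maximal gap run in the query
  row is a deletion, in the reference row an insertion. Events are counted
  once regardless of length.
* An indel abutting a substitution remains two events — event classes
  never merge.
* Insertions are anchored to the preceding reference base (position 0 for
  an insertion before base 1); deletions to their first deleted base.
* The ambiguity code N is inert: a column containing N contributes
  neither a variant nor a nucleotide difference.
* *Nucleotide differences* count every non-identical column once (a 5-bp
  deletion is 1 event but 5 differences). Both matrices are reported; they
  answer different questions (mutational events vs. raw divergence).
* Transitions are A↔G and C↔T; everything else is a transversion.
* Deletion/insertion polarity is relative to the reference (first-named)
  taxon.

VCF output follows v4.2 anchoring (indels left-anchored on the preceding
reference base); the native TSV keeps the empty-allele event view. An
indel before base 1 has no anchor base and is kept in the TSV only.

## Protein effects

Effects are computed on the reference annotation. The CDS is rebuilt by
concatenating exons in genome order and reverse-complementing for minus-
strand genes; genome position → CDS index maps handle both strands.
Translation uses NCBI table 11 (bacterial/plastid), configurable — plastid
genes follow the bacterial code, and the choice only matters for a handful
of codons. Substitution runs are applied to the CDS and the affected codon
range is translated before and after: identical → synonymous, else
nonsynonymous with the 1-based residue index. An MNV inside one codon is
one codon change, not independent SNPs. Coding indels with length ≢ 0
(mod 3) are frameshifts; the truncated length is the number of residues
before the first in-frame stop of the mutated CDS. In-frame coding indels
are reported as `inframe_indel` (outside the three headline classes). A
variant overlapping an exon boundary is flagged `composite` rather than
dropped. Effects of repeat-resident genes are computed once on the IR_A
copy and tagged duplicated.

The annotation sanity gate — every intact protein gene translates with a
terminal stop and no internal stops — is enforced by the simulator's gene
builder and asserted in the tests.

## Clade partitioning

Given per-taxon alleles at candidate positions (from the multiple
alignment, with adjacent columns carrying the same taxon partition and gap
pattern merged into one event) and a clade map assigning each ingroup
taxon to one of {Australian, Asian, focal}:

* a position is **clade-specific** when every Australian member carries
  one allele and every Asian member a different one, the focal taxon
  carrying one of the two (it is counted with the clade it matches; the
  output set name — `australian_specific` vs `asian_specific` — records
  which side that was, since without an outgroup allele the derived side
  is not identifiable from the ingroup alone);
* a position is **focal-unique** when the focal taxon's allele occurs in
  no other genome.

The sets are pairwise disjoint by construction. The outgroup is excluded
by leaving it out of the clade map. Positions with a missing allele are
skipped and counted.

## Maximum parsimony

Characters are unordered and equally weighted; gap and N are missing data
and contribute the full state set in the Fitch pass (they can never force
a step). Site patterns are compressed with multiplicities; constant
patterns are excluded from tree-length evaluation (they contribute zero
steps) but retained for site-class counts and index denominators, where
they also contribute zero.

* Site classes: constant (≤ 1 observed state among non-missing),
  parsimony-informative (≥ 2 states each in ≥ 2 taxa), otherwise variable-
  uninformative.
* `exhaustive_search` enumerates unrooted topologies by stepwise leaf
  insertion. With the default branch-and-bound pruning, partial trees
  longer than the incumbent are abandoned — adding a leaf can never
  shorten a tree, so the returned optimum (and the complete set of optimal
  trees) is identical to plain enumeration, which remains available via
  `prune=False` and is cross-checked in the tests. Above 9 taxa
  ((2n−5)!! > 135,135) the function refuses and points to the heuristic.
* `heuristic_search` repeats random-addition-order greedy stepwise
  addition followed by TBR branch swapping (bisect at every edge,
  reconnect every edge of one fragment to every edge of the other) to
  local optimality. Deterministic given the seed; all equally parsimonious
  trees found are kept, ordered by canonical Newick string.
* CI = Σm/Σs, RI = (Σg−Σs)/(Σg−Σm), with m the minimum steps per site
  (observed states − 1), s the realized steps and g the star-tree maximum
  (non-missing taxa − largest state class). When Σg = Σm the RI is
  reported as 1 with a warning. "CI excluding uninformative" restricts the
  sums to parsimony-informative sites. Indices are kept at full precision;
  round for reporting.
* Bootstrap: columns are resampled to the original length (a multinomial
  draw over patterns); support of each bipartition of the full-data best
  tree is its frequency among replicate best trees. Replicate searches use
  one random-addition replicate plus TBR, which is exhaustive-equivalent
  in practice at these matrix sizes.
* Neighbor joining uses the canonical Q-criterion agglomeration
  (scikit-bio's implementation behind this module's surface); negative
  branch lengths are clamped to zero with a warning. It serves as an
  independent cross-check on the distance matrices, not as the primary
  inference.
* Outgroup rooting places the root on the outgroup's pendant edge
  (half-way along it when lengths exist); ingroup bipartitions are
  unchanged.

Likelihood and Bayesian inference are deliberately out of scope: the MP
statistics and the NJ cross-check carry the comparative analysis.

## Simulator

The generator's defaults are the study conditions, not tunables:

| parameter | default | rationale |
|---|---|---|
| LSC / IR / SSC | 80,604 / 20,803 / 12,347 bp | published structure of the focal genome (total 134,557 bp) |
| AT content | 0.61 | AT-rich plastome background, applied to genes and spacers |
| gene layout | 75 + 8 single protein genes, 10 IR-duplicated; 24 + 8 tRNA; 4 rRNA (1490/2810/103/121 bp); 11 one-intron genes; introns ~1 kb | reproduces the published composition profile: ~58% coding (≈49% protein, ≈7% rRNA, ≈2% tRNA), ~33% intergenic, ~9% intron |
| tree | two clades (3 Australian incl. the focal taxon; 4 Asian) + outgroup; branch lengths 2×10⁻⁵–2.5×10⁻⁴, outgroup 6×10⁻³ | calibrated so pairwise event counts emulate the published distance table: closest pair ~25–40 events, ingroup ≤ ~150, outgroup ~900 |
| κ (Ts/Tv rate ratio) | 2.0 | plastid-typical transition bias; yields Ts/Tv counts near parity across 2 transversion targets |
| mnv_rate / indel_rate | 0.06 / 0.20 × the substitution rate | SNP-dominated spectra with minority MNV and indel classes, as observed |
| indel length | geometric, mean 3 bp | short indels dominate organellar alignments |
| region multipliers | intergenic 4.5, intron 2.0, coding 1.0 | places ~60–70% of variants in intergenic sequence (which is ~33% of the genome), ~25–30% in coding, ~5–10% in introns |
| min_event_spacing | 2 bp | keeps events well separated so truth and calls correspond one-to-one |

Branch lengths are expected substitutions per (rate-averaged) site;
`mnv_rate`/`indel_rate` are events per site per unit branch length, i.e.
their ratio to the substitution rate. Events per branch are a Poisson
draw of counts followed by multiplier-weighted, non-overlapping positions
— a per-branch shortcut to a full Gillespie simulation that is accurate
while multiple hits are negligible, which holds at the ≤ 1% divergences
emulated (the deep two-taxon runs used for κ recovery stay below 10%,
where the shortcut slightly undercounts multiple hits but leaves the
Ts/Tv ratio unbiased). Substitutions pick a transition with probability
κ/(κ+2); under equal base usage the recovery estimate is κ̂ = 2·Ts/Tv.

Mutation operates on the IR-reduced sequence; each leaf's full genome is
rebuilt as `reduced + revcomp(IR segment)`, which *is* concerted
evolution: an event in the repeat appears identically in both copies and
leaf repeats stay exact reverse complements. Truth is recorded per branch
in the parent's coordinates; replaying a branch's events on the parent
reproduces the child byte-for-byte (asserted), and root→leaf coordinate
maps lift the ancestral annotation onto each leaf.

What the simulator does **not** model — and hence what green tests do not
show about real data: selection (synonymous/nonsynonymous ratios are
neutral, so real purifying selection will shift effect tables toward
synonymous changes), rate heterogeneity beyond the three region classes,
context-dependent mutation, tandem-repeat slippage (real indel hotspots),
IR boundary expansion/contraction as a distinct process, base-composition
drift, and sequencing/assembly error. Alignment and variant-calling
accuracy on simulated genomes therefore bounds, but does not guarantee,
accuracy on real genomes with repeat-induced alignment ambiguity.

## Numerical and degenerate-input choices

* Event runs at homopolymer boundaries: left-shift normalization means a
  deletion inside a repeated motif is reported at the leftmost equivalent
  position; simulator truth and caller output are compared by event type
  and length where positions are not identifiable, and by exact position
  otherwise.
* Ties among equally parsimonious trees: all retained; reported statistics
  use the first under canonical Newick ordering.
* Per-operation RNG streams: the pipeline derives independent seeds for
  search and bootstrap from one master seed, so each stage is
  independently reproducible.
* Empty inputs, duplicate ids, illegal symbols, label mismatches,
  asymmetric distance matrices and infeasible gene layouts all raise typed
  exceptions from one hierarchy (`plastocmp.errors`).

## Problem sizes used in the checks

The automated checks run entirely on simulated data: study-scale genomes
(134.5 kb, 8 taxa) for the end-to-end pipeline, topology and bootstrap
checks, and scaled-down genomes (~16.5 kb) for per-operation tests; the
oracle batteries use 200 random pairs of 250–700 bp for alignment
optimality, every 4- and 5-taxon topology for Fitch scoring, and 25
simulated 8–9-taxon matrices for heuristic-vs-exact search agreement. The
mutation-parameter recovery runs a 34 kb two-taxon simulation deep enough
to yield ≥ 2,000 SNP events. The acceptance script's bootstrap uses 2,000
pseudoreplicates, matching the study conditions.
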