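# Methods

This note documents the models, algorithms, parameter choices, and known
limitations behind `spidarch`, in the order data flows through the package.

## Sequence model and conventions

All coordinates are 0-based half-open on the forward strand; 1-based
inclusive conventions (tabular BLAST, GFF3) are converted at I/O boundaries.
Translation uses the standard codon table with stops rendered `*`; any codon
containing `N` (or another non-ACGT symbol) renders `X`, even where the
ambiguity would resolve (e.g. `GGN`), so downstream identity computations
can treat `X`/`N` uniformly as never matching.  Open reading frames are
defined stop-to-stop in all six frames with no start-codon requirement: the
retention rule downstream asks only for the longest ORF above a length
cutoff, and requiring a methionine would silently truncate partial
transcripts.  ORF coordinates include the terminal stop codon when present;
the peptide does not.

One alignment convention is used package-wide: BLOSUM62 substitution
scores with affine gaps (open 10, extend 1, matrix score units), and one
identity convention: matches / scored columns, where gap-vs-residue columns
are scored mismatches, gap-vs-gap columns are excluded, and `X`/`N` never
match.  "AAAA" vs "AA" therefore has identity 0.5.  Keeping a single
documented convention makes every percentage in the package's outputs
comparable.

## Transcriptome curation

The decision pipeline assigns each transcript of a Trinity-style assembly a
retention category from four inputs: a forward (transcript → database) and a
reverse (database → transcript) tabular hit file with a companion
subject-lengths table, a transcripts × libraries TPM matrix, and a list of
structural-RNA transcript ids (rRNA/tRNA identification is an external
search; its output list is the input contract here).

* *Hit significance.*  Rows with e-value above 1e-10 are dropped at parse
  time (configurable).
* *"Best match"* is by bitscore, ties broken by lower e-value then
  lexicographic id, so reruns are deterministic.
* *Subject coverage* is the length of the union of subject intervals across
  all HSPs of one (query, subject) pair divided by subject length.  The
  cutoff defaults to 0.20.
* *Chimeras.*  A transcript is chimeric iff two distinct subjects each reach
  the coverage cutoff and their query spans overlap by less than 20% of the
  shorter span — two database genes matched side-by-side.  Both parameters
  are exposed; fully overlapping subjects are alternative homologs, not
  chimeras.
* *Category precedence* is structural RNA → chimeric → BEST → 2BEST → GOOD →
  LONGORF → DISCARD, with the first failing reason recorded (coverage before
  expression).  BEST/2BEST are exempt from the coverage and expression
  filters: they are the best hits to the database genes, and discarding a
  reciprocal best hit for low expression would delete the gene's only
  representative.  "Top match of a database gene" (the 2BEST trigger) is
  evaluated on the reverse search, the same direction reciprocal-best-hit
  uses; the rule sits in one function so an alternative reading can be
  swapped in.
* *Representative selection* keeps exactly one non-discarded isoform per
  Trinity gene: category rank, then best-hit bitscore, then longest ORF,
  then lexicographic id.  Raising the TPM or coverage cutoff can only
  shrink the retained set (asserted as a property test).

Expression must cover every transcript that has a hit; a transcript present
in the hit table but absent from the TPM matrix is an input error, not a
zero.

## Repeat architecture

**Domain partitioning.**  Reference terminal-domain sequences are locally
aligned against the protein; the N boundary is the end of the best
N-reference alignment and the C boundary the start of the best C-reference
alignment, each accepted only at local score ≥ 100 (BLOSUM62 units, about
the score of a 20-residue exact match — low enough to find diverged domains,
high enough that random 100-aa sequences do not qualify).  An unmatched
terminus yields an empty region; a C boundary before the N boundary raises,
since it indicates a truncated or rearranged input.

**Period estimation.**  Every pair of equal 3-mers at offset d adds one
count to a histogram over d.  Candidate periods are local maxima of the raw
histogram, each weighted by a ±2-neighbourhood sum: indels make the offset
between repeat copies drift a few residues, splitting the fundamental peak
across adjacent bins, and without the neighbourhood weighting an integer
multiple of the true period can outweigh the fundamental.  A floor of twice
the mean histogram weight suppresses random self-matches.  The fundamental
period is chosen as the smallest candidate reaching half the strongest
candidate's weight.

**Wrap-around segmentation.**  The repetitive region is aligned globally
against the circularized seed unit: the DP matrix has one column per seed
position, the diagonal transition wraps from the last column to the first,
and each wrap of the traceback path marks a unit boundary.  Scoring is
match +2 / mismatch −1 / gap −3 (identity scale; `X` never matches); the
alignment may start at any seed phase.  After each pass the seed is refined
to the column-majority consensus of the current units, mapped column-wise
onto the seed by pairwise alignment.  Two details matter for boundary
accuracy and were found necessary in development:

* consensus columns unsupported by more than half the units are dropped,
  but *insertion* columns supported by more than half the units are
  restored — otherwise a seed carrying a deletion relative to the ancestral
  unit shrinks the consensus a little every iteration and forces a spurious
  wrap just before the region end;
* if the converged cut set leaves a short leading fragment, the consensus
  has converged to a rotated version of the unit; the seed is rotated by
  the fragment length and the region re-cut once, re-anchoring unit phase
  to the region start.

Iteration stops at a fixed point or after 10 rounds.  Flanking partial
units shorter than 50% of the consensus length are dropped.  All parameters
(k, scores, partial floor, iteration cap) are exposed.  On the synthetic
study condition (ten ~357-aa units, 5% substitutions, 1% indels) the
segmentation recovers the exact unit count with boundary error ≤ 3 aa in
≥ 95% of 100 seeded replicates; the acceptance script recomputes this.

For architectures whose units fall into several diverged types, the
self-match histogram peaks at the higher-order period (the distance between
same-type units), not at the unit length; segmenting such proteins requires
passing the unit length or a seed unit as `unit_hint`.  This mirrors
practice: ensemble-repeat boundaries in published spidroins are themselves
calibrated against the sequence rather than detected blind.

**Typing and consensus.**  Pairwise identities of all units (global
alignment, convention above) feed average-linkage (UPGMA) clustering on
distance 1 − identity.  The tree is cut at cophenetic distance 0.35
(≈ 65% identity), chosen so that module types with within-type identities in
the 69–86% range fall inside one type while diverged types (typically
≤ 40% identity) separate; the cut is configurable.  Type labels are
assigned by order of first appearance along the protein.  Per-type
consensus modules come from a progressive MSA of the type's units:
column-wise modal residue, columns more than half gap dropped, ties broken
toward the residue most frequent across the whole alignment, then
alphabetically.

**Higher-order arrangement.**  For each candidate period p ≥ 2 up to half
the label-string length, the modal label per residue class i mod p defines a
pattern; the smallest p whose pattern mismatches at most 10% of positions is
reported.  A constant pattern is excluded — a uniform label string has
trivial period 1, not higher-order structure.  Cross-protein architecture
comparison maps one protein's type labels onto the other's by maximum-weight
bipartite matching of consensus-vs-consensus identities, then scores a
unit-cost edit-distance alignment of the label strings, normalized by the
longer length.

## Sequence statistics

Motif censuses count overlapping occurrences left-to-right (a tandem
`GPGPG` contains two `GPG`); cores may contain residue classes in square
brackets.  Spacers are operationalized as maximal segments with glycine
fraction ≤ 0.1, length 8–20, flanked on both sides by 10-residue windows
with glycine fraction ≥ 0.3; hits are non-overlapping, leftmost-first.
These windows bracket the verbal description of an 11–13 aa glycine-poor
interruption of glycine-rich sequence; with realistic (not idealized)
composition, only planted spacers whose flanks meet the windows are
reported, which is the definition doing its job rather than a recall
failure.  Mean pairwise identity of an MSA averages the pairwise convention
over all row pairs; conserved-column fraction asks whether the modal
residue reaches the threshold (default 75%) of non-gap rows per column.

## Terminal-domain gene trees

The paper-scale workflow aligns N- and C-terminal regions separately,
concatenates them (ids missing from one region are padded with gaps, so
partial sequences lacking one terminus remain analyzable), computes
p-distances (1 − pairwise identity; a pair with zero scored columns gets
distance 1 with a warning), and builds distance trees.

Distance methods replace maximum-likelihood inference deliberately: they
are desk-scale, dependency-free, fully deterministic, and sufficient to
reproduce clade-membership and duplication statements; externally computed
ML trees can be imported as newick and fed directly to the duplication
flagging step.  Neighbor joining is canonical, with Q-criterion ties broken
by lexicographic taxon pair and negative branch lengths clamped to zero
with the deficit moved to the sister branch; it reconstructs additive
matrices exactly (asserted over random 4/5-taxon cases).  UPGMA node
heights are half the cophenetic merge distance.  Bootstrap support
resamples alignment columns with replacement; an internal edge's support is
the percentage of replicate trees containing the same bipartition
(bipartitions normalized to the side not containing the lexicographically
smallest taxon).  The progressive aligner used upstream scores
profile-profile columns by expected BLOSUM62 substitution (residue-vs-gap
pairs at the gap-extension penalty) and merges along a UPGMA guide tree on
k-mer distances; with two sequences it reduces exactly to the pairwise
Gotoh alignment, which is score-verified against an independent
implementation in the tests.

Duplication nodes use the species-overlap rule on a rooted tree: a node is
a duplication iff the species sets of its child subtrees intersect.  Flags
are reported where bootstrap support exceeds 50 (configurable); nodes
without support values are always reported.  Rooting is by user-specified
outgroup or midpoint.  Species overlap is a deliberate simplification of
full gene-tree/species-tree reconciliation: it cannot distinguish deep
coalescence or lateral noise from duplication, and it is isolated in one
function so a reconciliation method could replace it.

## Synthetic data

The generators define the study conditions and are first-class, tested
code.

*Spidroins* are built as nterm + mutated unit copies + cterm.  Unit
templates are drawn per type from a biased residue distribution
(serine/alanine/glycine-enriched by default, matching aciniform-like
composition; a glycine/proline-rich bias for the pseudoflagelliform-like
condition), optionally prefixed by a shared conserved spacer block — the
shared block is what lets a single circular seed tile heterogeneous unit
types, mirroring the real architecture of a conserved spacer interrupting
type-specific motif-rich sequence.  Mutation applies per-site substitutions
(uniform over the 19 alternatives, so the expected Hamming fraction equals
the substitution rate) and geometric indels (p = 2/3, mean length 1.5),
insertion/deletion equiprobable.  Truth records exact post-mutation
boundaries, labels, and arrangement period.  The two bundled 100-aa
terminal templates are synthetic sequences from a fixed seed, not copies of
any database entry.

*Transcriptomes* plant one scenario per gene (RBH, RBH + second-best
sibling, good-coverage allele, ORF-only, and the discard variants), cycling
scenarios across 60 genes with isoform counts 1–4 summing to 200
transcripts; 5% of transcripts are replaced by chimeras (two side-by-side
subjects) and 5% by structural RNAs.  Hit tables are synthesized from the
planted homology rather than by running an aligner, which removes search
tools from the test loop; coordinates, bitscores and reverse-best decoys
are constructed so each transcript's category follows from the documented
rules, and the truth table (including which isoform wins representative
selection) is computed from the planted attributes by those same documented
rules — never by running the pipeline.  Transcripts that must lack a
qualifying ORF are kept under 150 nt (no frame can reach 50 aa); transcripts
with an exact planted ORF length are rejection-sampled against spurious
long runs on the other five frames, with random synonymous codon usage so
such runs actually terminate.

What passing on these fixtures does *not* show: robustness to real BLAST
HSP fragmentation and e-value noise, to expression-estimation uncertainty,
to assembly artifacts other than the modeled chimeras, or to repeat
architectures with length heterogeneity far beyond the modeled indel
process.  The paper-scale inputs (deposited assemblies and alignments) are
the territory of the download-gated comparisons, not of this test bed.

## Problem sizes and determinism

The verification suite and the reproduction script use: 200 transcripts /
60 genes for curation; 100 replicate proteins of ten 357-aa units for
repeat recovery; one 48-unit, four-type, period-4 protein for higher-order
structure; 20 random additive matrices and a 4-taxon two-clade alignment
with 100 bootstrap replicates for the tree oracles.  These sizes keep a
full run in the low minutes on one core while leaving the statistical
assertions (≥ 95% recovery over 100 replicates) meaningful.  Every random
draw flows from an explicit seed; reruns are byte-identical.
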