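# spidarch

Spidroin repeat-architecture analysis and transcriptome curation.

Spider silk proteins (spidroins) share a common plan: short conserved
N- and C-terminal domains flank a very long repetitive region built from
tandem "ensemble repeats", which may themselves recur in higher-order
patterns.  Characterizing a newly assembled spidroin therefore means
answering a chain of questions — where do the terminal domains end, how is
the repetitive core tiled into units, how many module types do the units
fall into, how are the types arranged, which sequence motifs dominate — and,
upstream of all that, which transcripts of a noisy de novo assembly are
worth keeping at all.  `spidarch` is a toolkit for that chain, aimed at
people annotating silk-gene (or other tandem-repeat protein) catalogs from
transcriptome and genome assemblies.

## What it does

**Transcriptome curation** (`spidarch.curation`).  A Trinity-style assembly
is pruned to one high-confidence allele per gene using tabular BLAST hits
against a curated protein database (plus the reverse search), per-library
TPM expression, and a list of structural-RNA transcripts.  Each transcript
receives one of five categories:

* `BEST` — reciprocal best hit with a database gene;
* `2BEST` — best match of a database gene while a sibling isoform of the
  same Trinity gene holds the reciprocal best hit;
* `GOOD` — a significant hit with subject coverage ≥ 20% and ≥ 1 TPM in at
  least one library;
* `LONGORF` — no hit, but a six-frame ORF ≥ 50 aa and ≥ 1 TPM;
* `DISCARD` — everything else, with a machine-readable reason (chimeric,
  structural RNA, low coverage, low expression, no ORF, not representative).

Chimeras (two database genes matched side-by-side on one transcript) are
excluded up front; finally one isoform per Trinity gene is retained by
category rank, bitscore, ORF length, then id.

**Repeat architecture** (`spidarch.repeat_arch`).  Terminal domains are
located by local alignment against reference terminal sequences.  The
repetitive core is tiled by aligning it against a *circularized* seed unit
with wrap-around dynamic programming; each wrap of the alignment path marks
a unit boundary, and the seed is iteratively refined to the column-majority
consensus of the current units.  Units are clustered into module types by
UPGMA on pairwise alignment identities (cut at cophenetic distance 0.35 ≈
65% identity by default), per-type consensus modules are built from a
progressive MSA, and the type-label string is scanned for its smallest
higher-order period.  Architectures of homologous proteins are compared by
label-string edit distance after matching types across proteins by
consensus-vs-consensus identity.

**Sequence statistics** (`spidarch.seq_stats`).  Amino-acid composition,
overlapping tripeptide motif censuses (e.g. GPS/KPS/QPS/GPG with residue
classes like `[GSAQED]PS`), glycine-poor spacer detection inside
glycine-rich context, mean pairwise identity of an MSA, and conserved-column
fractions.

**Terminal-domain gene trees** (`spidarch.phylo`).  Progressive alignment
(UPGMA guide tree over k-mer distances, profile-profile Gotoh merges with
BLOSUM62, gap open 10 / extend 1), separate N- and C-region alignments
concatenated with gap padding for partial sequences, p-distance matrices,
neighbor-joining and UPGMA trees, column-bootstrap support, midpoint or
outgroup rooting, and gene-duplication flags by the species-overlap rule
(a node whose child subtrees share a species, reported where bootstrap
support exceeds 50%).

**Synthetic fixtures** (`spidarch.synth`).  Seeded generators produce
spidroin proteins and whole transcriptome fixtures with complete planted
truth (unit boundaries, type labels, arrangement period, per-transcript
retention category), so every analysis above is testable without downloads.

## Worked example

`python examples/02_repeat_architecture.py` builds an aciniform-like
protein — ten ~357-residue tandem repeats at 5% substitutions and 1% indels
between 100-aa terminal domains — and annotates it from scratch:

```
protein length: 3775 aa
N-terminal domain: [0, 100)   C-terminal domain: [3675, 3775)
recovered repeat units: 10 (truth: 10)
unit lengths: min 348, mean 357.5, max 366
repeat fraction of protein: 0.947
worst boundary error vs construction truth: 0 aa
```

The partition matches the construction exactly, the wrap-around DP recovers
all ten units with their mutated lengths, and the repeat fraction (share of
residues inside repeat units) is 94.7% for this construction.  The other
examples cover transcriptome curation (`01`), repeat typing, higher-order
period and motif statistics on a pseudoflagelliform-like architecture
(`03`), and terminal-domain trees with duplication flags (`04`).

A thin CLI mirrors the library: `spidarch orfs`, `spidarch trtap`,
`spidarch repeats`, `spidarch stats`, `spidarch phylo`,
`spidarch synth spidroin|transcriptome`.

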