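"""Prune a de novo transcriptome to one high-confidence allele per gene.

Builds a seeded 200-transcript Trinity-style fixture with planted retention
categories (reciprocal-best-hit genes, good-coverage alleles, ORF-only
transcripts, chimeras, structural RNAs), runs the full decision pipeline, and
compares every call against the construction truth.
"""

from spidarch import curation
from spidarch.synth import TranscriptomeSpec, make_transcriptome

fixture = make_transcriptome(TranscriptomeSpec(seed=1))
fwd = curation.parse_hit_rows(fixture.forward_rows, fixture.subject_lengths)
rev = curation.parse_hit_rows(
    fixture.reverse_rows, {r.id: len(r) for r in fixture.records}
)
result = curation.run_curation(
    fixture.records, fwd, rev, fixture.expression, fixture.rna_ids
)

print(f"transcripts in: {len(fixture.records)}")
print(f"category counts: {result.report.category_counts}")
print(f"retained (one allele per Trinity gene): {len(result.retained)}")

truth = fixture.truth.set_index("transcript_id")
calls = result.calls_frame().set_index("transcript_id")
merged = truth.join(calls, lsuffix="_truth")
disagree = int((merged.category_truth != merged.category).sum())
print(f"disagreements with planted truth: {disagree}")
print(
    "\nEach retained transcript is the best allele of its gene by category\n"
    "rank (BEST > 2BEST > GOOD > LONGORF), bitscore, then ORF length; a\n"
    "disagreement count of 0 means the pipeline reproduced every planted call."
)
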