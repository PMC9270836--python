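"""Decompose a tandem-repeat silk protein into terminal domains and
ensemble repeat units.

Builds an aciniform-like synthetic spidroin — ten ~357-residue tandem
repeats at 5% substitutions / 1% indels between conserved 100-aa terminal
domains — then partitions the protein, segments the repetitive core by
wrap-around dynamic programming, and reports the recovered architecture.
"""

from spidarch import repeat_arch
from spidarch.synth import CTERM_TEMPLATE, NTERM_TEMPLATE, acsp1_like_spec, make_spidroin

record, truth = make_spidroin(acsp1_like_spec(seed=1))
annotation = repeat_arch.annotate_repeats(
    record.residues, [NTERM_TEMPLATE], [CTERM_TEMPLATE]
)

part = annotation.partition
print(f"protein length: {part.length} aa")
print(f"N-terminal domain: [0, {part.a})   C-terminal domain: [{part.b}, {part.length})")
print(f"recovered repeat units: {len(annotation.units)} (truth: {len(truth.units)})")
lengths = [len(u) for u in annotation.units]
print(f"unit lengths: min {min(lengths)}, mean {sum(lengths)/len(lengths):.1f}, max {max(lengths)}")
print(f"repeat fraction of protein: {annotation.repeat_fraction:.3f}")
worst = max(
    max(abs(u.start - t.start), abs(u.end - t.end))
    for u, t in zip(annotation.units, truth.units)
)
print(f"worst boundary error vs construction truth: {worst} aa")
print(
    "\nThe repeat fraction is the share of residues inside repeat units; the\n"
    "boundary error shows how closely the wrap-around segmentation recovers\n"
    "the planted unit boundaries despite the mutational noise."
)
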