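"""Build a terminal-domain gene tree with bootstrap support and flag
gene duplications.

Simulates a small silk-gene family in three species by mutating ancestral
N- and C-terminal domains along two paralog lineages, aligns each region,
concatenates them, infers a neighbor-joining tree from p-distances with a
column bootstrap, midpoint-roots it, and applies the species-overlap rule.
"""

import numpy as np

from spidarch import phylo
from spidarch.synth import mutate_sequence

rng = np.random.default_rng(42)
AA = list("ACDEFGHIKLMNPQRSTVWY")
anc_n = "".join(rng.choice(AA, size=100))
anc_c = "".join(rng.choice(AA, size=80))

# two paralogs (deep split), each sampled in three species (shallow splits)
paralog_n = {p: mutate_sequence(anc_n, 0.25, 0.01, rng) for p in ("SpA", "SpB")}
paralog_c = {p: mutate_sequence(anc_c, 0.25, 0.01, rng) for p in ("SpA", "SpB")}
species = ("udiv", "osyb", "smim")
n_seqs, c_seqs, species_of = [], [], {}
for p in ("SpA", "SpB"):
    for sp in species:
        name = f"{p}_{sp}"
        n_seqs.append((name, mutate_sequence(paralog_n[p], 0.05, 0.01, rng)))
        c_seqs.append((name, mutate_sequence(paralog_c[p], 0.05, 0.01, rng)))
        species_of[name] = sp

n_msa = phylo.progressive_align(n_seqs)
c_msa = phylo.progressive_align(c_seqs)
concat = phylo.concat_alignments(n_msa, c_msa)
print(f"concatenated alignment: {len(concat.rows)} sequences x {concat.length} columns")

tree = phylo.bootstrap_support(concat, phylo.nj_tree, n_replicates=100, seed=42)
tree = phylo.midpoint_root(tree)
tree = phylo.flag_duplications(tree, species_of, support_min=50)

print(phylo.write_newick(tree))
dups = [
    sorted(t.name for t in node.tips())
    for node in tree.non_tips(include_self=True)
    if getattr(node, "duplication", False)
]
for leaves in dups:
    print(f"duplication node above: {', '.join(leaves)}")
print(
    "\nInternal labels are bootstrap percentages; a duplication flag marks a\n"
    "well-supported node whose child subtrees share at least one species —\n"
    "here the deep SpA/SpB split, as planted."
)
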