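"""Shared pairwise-alignment helpers.

One scoring convention is used package-wide: BLOSUM62 substitution scores with
affine gaps (open 10, extend 1, in matrix score units), and one identity
convention: identity = matching columns / scored columns, where a gap aligned
to a residue is a scored mismatch, a gap aligned to a gap is excluded, and the
ambiguity symbols X/N never match anything.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

GAP_OPEN = 10.0
GAP_EXTEND = 1.0
AMBIGUOUS = frozenset("XN")


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = mode
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def _clean(seq: str) -> str:
    """Map symbols missing from BLOSUM62 onto its wildcard column."""
    return seq.upper().replace("U", "*").replace("O", "*")


def global_align(a: str, b: str) -> tuple[str, str, float]:
    """Optimal global alignment; returns (gapped_a, gapped_b, score)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner("global").align(_clean(a), _clean(b))[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb, float(aln.score)


def local_align(a: str, b: str) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Best local alignment score and the aligned [start, end) intervals."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner("local").align(_clean(a), _clean(b))[0]
    a_blocks, b_blocks = aln.aligned
    a_iv = (int(a_blocks[0][0]), int(a_blocks[-1][1]))
    b_iv = (int(b_blocks[0][0]), int(b_blocks[-1][1]))
    return float(aln.score), a_iv, b_iv


def aligned_identity(row_a: str, row_b: str) -> float:
    """Identity of two equal-length gapped rows under the package convention."""
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    matches = scored = 0
    for x, y in zip(row_a, row_b):
        if x == "-" and y == "-":
            continue
        scored += 1
        if x == y and x not in AMBIGUOUS:
            matches += 1
    if scored == 0:
        return 0.0
    return matches / scored


def pairwise_identity(a: str, b: str) -> float:
    """Align two unaligned sequences globally and score identity."""
    ga, gb, _ = global_align(a, b)
    return aligned_identity(ga, gb)
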