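"""Composition, motif, spacer, and alignment-identity statistics.

These are the descriptive statistics used when characterising a silk protein:
amino-acid composition of a repeat region, counts of tripeptide motifs such as
GPS(X)/KPS(X)/QPS(X), glycine-poor spacer segments interrupting glycine-rich
runs, and identity summaries over multiple sequence alignments of terminal
domains.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

from .align import aligned_identity


@dataclass
class CompositionProfile:
    fractions: dict[str, float]
    length: int


def aa_composition(seq: str) -> CompositionProfile:
    """Exact residue fractions; ``X`` counts toward length and is reported."""
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq)
    total = len(seq)
    return CompositionProfile(
        fractions={aa: n / total for aa, n in sorted(counts.items())}, length=total
    )


@dataclass
class MotifCensus:
    counts: dict[str, int]

    @property
    def dominant(self) -> str:
        best = max(self.counts.values())
        return min(m for m, n in self.counts.items() if n == best)


def motif_census(seq: str, cores: list[str]) -> MotifCensus:
    """Count all (overlapping) occurrences of tripeptide core patterns.

    A core may be a literal tripeptide (``"GPS"``) or contain residue classes
    in square brackets (``"[GSAQED]PS"``).  Occurrences are scanned left to
    right with overlaps allowed; the dominant motif is the argmax with a
    lexicographic tie-break.
    """
    counts: dict[str, int] = {}
    for core in cores:
        pattern = re.compile(f"(?=({core}))")
        counts[core] = sum(1 for _ in pattern.finditer(seq))
    return MotifCensus(counts=counts)


@dataclass(frozen=True)
class SpacerHit:
    """A glycine-poor segment flanked by glycine-rich sequence."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _g_fraction(segment: str) -> float:
    if not segment:
        return 0.0
    return segment.count("G") / len(segment)


def find_spacers(
    seq: str,
    len_range: tuple[int, int] = (8, 20),
    spacer_g_max: float = 0.1,
    flank_len: int = 10,
    flank_g_min: float = 0.3,
) -> list[SpacerHit]:
    """Locate spacer motifs: short glycine-poor interruptions of G-rich runs.

    A hit is a maximal segment with G fraction <= ``spacer_g_max`` whose length
    is within ``len_range`` and whose two flanking windows of ``flank_len``
    residues each have G fraction >= ``flank_g_min``.  Hits are reported
    non-overlapping, leftmost first.
    """
    lo, hi = len_range
    if len(seq) < 2 * flank_len + lo:
        return []
    hits: list[SpacerHit] = []
    i = flank_len
    limit = len(seq) - flank_len
    while i < limit:
        if seq[i] == "G":
            i += 1
            continue
        # longest extent from i (capped at hi, not eating the right flank)
        # whose running G fraction stays within the spacer ceiling
        g = 0
        end = i
        best = -1
        while end < limit and end - i < hi:
            if seq[end] == "G":
                g += 1
            end += 1
            if g <= spacer_g_max * (end - i) and end - i >= lo:
                best = end
        if best > 0:
            left = seq[i - flank_len : i]
            right = seq[best : best + flank_len]
            if (
                len(right) == flank_len
                and _g_fraction(left) >= flank_g_min
                and _g_fraction(right) >= flank_g_min
            ):
                hits.append(SpacerHit(i, best))
                i = best
                continue
        i += 1
    return hits


def _check_msa(rows: list[str]) -> None:
    if len(rows) < 2:
        raise ValueError("an alignment needs at least two rows")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows have unequal lengths")


def mean_pairwise_identity(rows: list[str]) -> float:
    """Mean identity over all unordered row pairs of an MSA.

    Per pair: matching columns / columns where at least one of the two rows has
    a residue (both-gap columns excluded); gap-vs-residue is a mismatch.
    """
    _check_msa(rows)
    values = [aligned_identity(a, b) for a, b in combinations(rows, 2)]
    return sum(values) / len(values)


def conserved_column_fraction(rows: list[str], threshold: float = 0.75) -> float:
    """Fraction of columns whose modal residue reaches >= threshold of non-gap rows."""
    _check_msa(rows)
    length = len(rows[0])
    conserved = 0
    scored = 0
    for col in range(length):
        residues = [r[col] for r in rows if r[col] != "-"]
        if not residues:
            continue
        scored += 1
        top = Counter(residues).most_common(1)[0][1]
        if top / len(residues) >= threshold:
            conserved += 1
    return conserved / scored if scored else 0.0
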