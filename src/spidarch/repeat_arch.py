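"""Spidroin repeat-architecture decomposition.

A spidroin protein is a long repetitive core flanked by short conserved
N- and C-terminal domains.  This module partitions the protein into the three
regions, tiles the repetitive core into ensemble repeat units by wrap-around
dynamic programming against a circularized seed unit (with iterative consensus
refinement), clusters the units into module types by average-linkage (UPGMA)
agglomeration of pairwise identities, builds per-type consensus modules, and
detects higher-order periodicity in the resulting type-label string
(e.g. a recurring 4-mer arrangement of four module types).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment

from .align import global_align, local_align, pairwise_identity
from .phylo import progressive_align

# wrap-around DP scoring (identity scale, integer scores)
MATCH = 2
MISMATCH = -1
GAP = -3


@dataclass
class DomainPartition:
    """0-based half-open boundaries: N-terminal [0, a), repeats [a, b),
    C-terminal [b, L).  Empty termini mean no recognizable domain."""

    a: int
    b: int
    length: int

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.b <= self.length):
            raise ValueError(
                f"inconsistent domain boundaries a={self.a}, b={self.b}, L={self.length}"
                " (C-terminal region before N-terminal suggests a truncated or"
                " fragmented input)"
            )

    @property
    def nterm(self) -> tuple[int, int]:
        return (0, self.a)

    @property
    def repeat_region(self) -> tuple[int, int]:
        return (self.a, self.b)

    @property
    def cterm(self) -> tuple[int, int]:
        return (self.b, self.length)


@dataclass
class RepeatUnit:
    start: int
    end: int
    seq: str
    type_label: str = ""

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ArchitectureString:
    labels: list[str]
    period: int | None = None
    period_mismatch: float = 0.0


@dataclass
class ConsensusModel:
    """Per-type consensus sequence plus per-column residue frequency profile."""

    consensus: dict[str, str] = field(default_factory=dict)
    profiles: dict[str, list[dict[str, float]]] = field(default_factory=dict)


@dataclass
class RepeatAnnotation:
    partition: DomainPartition
    units: list[RepeatUnit]
    consensus: ConsensusModel
    architecture: ArchitectureString

    @property
    def repeat_fraction(self) -> float:
        return sum(len(u) for u in self.units) / self.partition.length


# ---------------------------------------------------------------------------
# domain partitioning
# ---------------------------------------------------------------------------

def partition_domains(
    protein: str,
    nterm_refs: list[str] | None = None,
    cterm_refs: list[str] | None = None,
    min_score: float = 100.0,
) -> DomainPartition:
    """Locate the conserved terminal domains by best local alignment of
    reference terminal sequences.

    The N boundary is the end of the best-scoring N-reference alignment, the
    C boundary the start of the best C-reference alignment; a reference only
    counts if its local score reaches ``min_score`` (BLOSUM62 units).  An
    unmatched terminus yields an empty region.
    """
    L = len(protein)
    a = 0
    b = L
    if nterm_refs:
        best = max(
            (local_align(ref, protein) for ref in nterm_refs), key=lambda r: r[0]
        )
        score, _, (p_start, p_end) = best
        if score >= min_score:
            a = p_end
    if cterm_refs:
        best = max(
            (local_align(ref, protein) for ref in cterm_refs), key=lambda r: r[0]
        )
        score, _, (p_start, p_end) = best
        if score >= min_score:
            b = p_start
    return DomainPartition(a=a, b=b, length=L)


# ---------------------------------------------------------------------------
# period estimation
# ---------------------------------------------------------------------------

def _period_candidates(
    seq: str, k: int = 3, min_weight: float | None = None
) -> list[tuple[int, float]]:
    """Ranked (period, weight) candidates from the self-match k-mer offset
    histogram, smoothed over +-2 offsets to absorb indel drift."""
    L = len(seq)
    if L < 2 * k:
        raise ValueError("sequence shorter than 2k")
    positions: dict[str, list[int]] = {}
    for i in range(L - k + 1):
        positions.setdefault(seq[i : i + k], []).append(i)
    weights = np.zeros(L + 3, dtype=float)
    for pos in positions.values():
        if len(pos) < 2:
            continue
        arr = np.asarray(pos)
        diffs = (arr[None, :] - arr[:, None]).ravel()
        diffs = diffs[diffs > 0]
        np.add.at(weights, diffs, 1.0)
    # candidate offsets are local maxima of the raw histogram; each is
    # weighted by a +-2 neighbourhood sum because indels make the offset
    # between repeat copies drift a few residues, splitting one fundamental
    # peak across neighbouring bins
    smooth = np.convolve(weights, np.ones(5), mode="same")
    n = max(2, L // 2 + 1)
    if min_weight is None:
        positive = weights[1:n]
        min_weight = max(2.0, 2.0 * float(positive.mean())) if positive.size else 2.0
    candidates = []
    for d in range(2, n):
        w = weights[d]
        if w < min_weight:
            continue
        left = weights[d - 1] if d - 1 >= 1 else -1.0
        right = weights[d + 1] if d + 1 < n else -1.0
        if w > left and w >= right:
            candidates.append((d, float(smooth[d])))
    candidates.sort(key=lambda c: (-c[1], c[0]))
    return candidates


def estimate_period(seq: str, k: int = 3, min_weight: float | None = None) -> list[int]:
    """Candidate repeat periods from the self-match k-mer offset histogram.

    For every pair of equal k-mers at offset d > 0 the histogram gains one
    count; candidates are local maxima of the (lightly smoothed) histogram,
    ranked by weight with ties toward the smaller period.  ``min_weight``
    defaults to twice the mean histogram weight, a floor under which random
    self-matches are not reported.
    """
    return [d for d, _ in _period_candidates(seq, k=k, min_weight=min_weight)]


def _choose_period(seq: str, k: int = 3) -> int | None:
    """The fundamental period: the smallest candidate whose weight reaches
    half the strongest candidate's (integer multiples of the true unit length
    carry comparable but lower weight)."""
    candidates = _period_candidates(seq, k=k)
    if not candidates:
        return None
    top = candidates[0][1]
    strong = [d for d, w in candidates if w >= 0.5 * top]
    return min(strong)


# ---------------------------------------------------------------------------
# wrap-around segmentation
# ---------------------------------------------------------------------------

def _wrap_dp_boundaries(seq: str, unit: str) -> list[int]:
    """Align ``seq`` against the circularized ``unit`` and return the
    positions where the alignment path wraps (unit starts), as a sorted list
    of 0-based cut positions including 0 and len(seq)."""
    L, u = len(seq), len(unit)
    unit_arr = np.frombuffer(unit.encode(), dtype=np.uint8)
    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    x_code = ord("X")
    H = np.zeros((L + 1, u), dtype=np.int32)
    NEG = np.int32(-(10**8))
    gap = np.int32(GAP)
    for i in range(1, L + 1):
        c = seq_arr[i - 1]
        if c == x_code:
            srow = np.full(u, MISMATCH, dtype=np.int32)
        else:
            srow = np.where(unit_arr == c, MATCH, MISMATCH).astype(np.int32)
        prev = H[i - 1]
        diag = np.roll(prev, 1) + srow
        vert = prev + gap
        cur = np.maximum(diag, vert)
        # circular horizontal relaxation: cur[j] = max(cur[j], cur[j-1] + gap)
        for _ in range(2):
            shifted = np.roll(cur, 1) + gap
            relaxed = np.maximum.accumulate(
                np.maximum(cur, shifted) + (-gap) * np.arange(u, dtype=np.int64)
            ) - (-gap) * np.arange(u, dtype=np.int64)
            if np.array_equal(relaxed, cur):
                break
            cur = relaxed.astype(np.int32)
        H[i] = cur
    # traceback, preferring diagonal > vertical > horizontal
    j = int(np.argmax(H[L]))
    i = L
    starts: list[int] = []
    while i > 0:
        jp = (j - 1) % u
        c = seq_arr[i - 1]
        s = MATCH if (c == unit_arr[j] and c != x_code) else MISMATCH
        if H[i][j] == H[i - 1][jp] + s:
            if j == 0:
                starts.append(i - 1)
            i -= 1
            j = jp
        elif H[i][j] == H[i - 1][j] + gap:
            i -= 1
        else:
            if j == 0:
                starts.append(i)
            j = jp
    boundaries = sorted(set(starts) | {0, L})
    return boundaries


def _units_from_boundaries(seq: str, boundaries: list[int], offset: int = 0) -> list[RepeatUnit]:
    return [
        RepeatUnit(start=offset + a, end=offset + b, seq=seq[a:b])
        for a, b in zip(boundaries[:-1], boundaries[1:])
        if b > a
    ]


def _quick_consensus(units: list[str], seed: str) -> str:
    """Majority-rule consensus over seed columns, each unit mapped onto the
    seed by pairwise global alignment.

    Columns unsupported by more than half the units are dropped, and
    insertion columns supported by more than half the units are restored
    (a seed carrying a deletion relative to the ancestral unit would
    otherwise shrink the consensus a little every iteration).  The seed's
    phase (position of column 0) is preserved.
    """
    counts: list[Counter] = [Counter() for _ in seed]
    insertions: dict[int, list[Counter]] = {}  # boundary index -> rank counters
    n = len(units)
    for unit in units:
        ga, gb, _ = global_align(seed, unit)
        col = 0
        rank = 0
        for x, y in zip(ga, gb):
            if x == "-":
                ranks = insertions.setdefault(col, [])
                if len(ranks) <= rank:
                    ranks.append(Counter())
                if y != "-":
                    ranks[rank][y] += 1
                rank += 1
            else:
                rank = 0
                if y != "-":
                    counts[col][y] += 1
                col += 1

    out: list[str] = []

    def modal(counter: Counter) -> str | None:
        covered = sum(counter.values())
        if covered * 2 <= n:
            return None
        top = max(counter.values())
        return min(r for r, c in counter.items() if c == top)

    def emit_insertions(boundary: int) -> None:
        for counter in insertions.get(boundary, []):
            residue = modal(counter)
            if residue is not None:
                out.append(residue)

    for col, counter in enumerate(counts):
        emit_insertions(col)
        residue = modal(counter)
        if residue is not None:
            out.append(residue)
    emit_insertions(len(seed))
    return "".join(out)


def segment_repeats(
    seq: str,
    unit_hint: int | str | None = None,
    k: int = 3,
    max_iter: int = 10,
    min_partial: float = 0.5,
) -> list[RepeatUnit]:
    """Tile a repetitive region into ensemble repeat units.

    The region is aligned against a circularized seed unit by wrap-around DP;
    cuts fall at wrap positions.  The seed is then refined to the
    column-majority consensus of the current units and the DP repeated to a
    fixed point (at most ``max_iter`` rounds).  Flanking partial units shorter
    than ``min_partial`` of the consensus length are dropped.  ``unit_hint``
    may be a period (int) or an explicit seed unit (str); without it the top
    candidate of :func:`estimate_period` is used.  Returns an empty list when
    no periodicity is detectable.
    """
    if unit_hint is None:
        unit_hint = _choose_period(seq, k=k) if len(seq) >= 2 * k else None
        if unit_hint is None:
            return []
    if isinstance(unit_hint, int):
        if unit_hint < 2 or unit_hint > len(seq):
            return []
        seed = seq[:unit_hint]
    else:
        seed = unit_hint
    prev_seed = None
    boundaries = [0, len(seq)]
    for _ in range(max_iter):
        if prev_seed == seed or not seed:
            break
        prev_seed = seed
        boundaries = _wrap_dp_boundaries(seq, seed)
        units = [seq[a:b] for a, b in zip(boundaries[:-1], boundaries[1:]) if b > a]
        if len(units) < 2:
            break
        seed = _quick_consensus(units, seed)
    units = _units_from_boundaries(seq, boundaries)
    floor = min_partial * len(seed) if seed else 0
    # a short leading fragment means the converged consensus is a rotated
    # version of the unit; re-anchor its phase to the region start and re-cut
    if len(units) >= 2 and seed and 0 < len(units[0]) < floor:
        d = len(units[0])
        if d < len(seed):
            rotated = seed[-d:] + seed[:-d]
            boundaries = _wrap_dp_boundaries(seq, rotated)
            units = _units_from_boundaries(seq, boundaries)
    if units and len(units[0]) < floor:
        units = units[1:]
    if units and len(units[-1]) < floor:
        units = units[:-1]
    if len(units) <= 1:
        return []
    return units


# ---------------------------------------------------------------------------
# typing, consensus, architecture
# ---------------------------------------------------------------------------

def pairwise_identity_matrix(units: list[RepeatUnit] | list[str]) -> np.ndarray:
    """Symmetric matrix of global-alignment identities (diagonal 1)."""
    seqs = [u.seq if isinstance(u, RepeatUnit) else u for u in units]
    if len(seqs) < 2:
        raise ValueError("need at least two units")
    n = len(seqs)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_identity(seqs[i], seqs[j])
    return m


def cluster_repeat_types(matrix: np.ndarray, cut: float = 0.35) -> list[str]:
    """UPGMA clustering of units on distance 1 - identity, cut at cophenetic
    distance ``cut``; labels ("1", "2", ...) assigned by order of first
    appearance along the protein."""
    n = matrix.shape[0]
    dist = 1.0 - np.asarray(matrix, dtype=float)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(n, k=1)]
    raw = fcluster(linkage(condensed, method="average"), t=cut, criterion="distance")
    relabel: dict[int, str] = {}
    labels: list[str] = []
    for r in raw:
        if r not in relabel:
            relabel[r] = str(len(relabel) + 1)
        labels.append(relabel[r])
    return labels


def build_consensus(units: list[RepeatUnit] | list[str]) -> tuple[str, list[dict[str, float]]]:
    """Majority-rule consensus of one type's units from a progressive MSA.

    Columns with gap fraction > 0.5 are dropped; residue ties break toward the
    residue most frequent across the whole alignment, then alphabetically.
    """
    seqs = [u.seq if isinstance(u, RepeatUnit) else u for u in units]
    if not seqs:
        raise ValueError("no units")
    if len(seqs) == 1:
        profile = [{r: 1.0} for r in seqs[0]]
        return seqs[0], profile
    msa = progressive_align([(f"u{i}", s) for i, s in enumerate(seqs)])
    rows = msa.sequences()
    global_counts = Counter("".join(rows).replace("-", ""))
    n = len(rows)
    consensus = []
    profile: list[dict[str, float]] = []
    for col in zip(*rows):
        gaps = col.count("-")
        if gaps / n > 0.5:
            continue
        residues = Counter(r for r in col if r != "-")
        top = max(residues.values())
        tied = [r for r, c in residues.items() if c == top]
        winner = min(tied, key=lambda r: (-global_counts[r], r))
        consensus.append(winner)
        total = sum(residues.values())
        profile.append({r: c / total for r, c in sorted(residues.items())})
    return "".join(consensus), profile


def higher_order_period(
    arch: ArchitectureString | list[str], tol: float = 0.1
) -> tuple[int | None, float]:
    """Smallest period p >= 2 whose modal per-phase pattern mismatches at most
    ``tol`` of positions.  A constant pattern (uniform label string) does not
    count as higher-order structure."""
    labels = arch.labels if isinstance(arch, ArchitectureString) else list(arch)
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 labels")
    for p in range(2, n // 2 + 1):
        pattern = []
        for r in range(p):
            phase = labels[r::p]
            counts = Counter(phase)
            top = max(counts.values())
            pattern.append(min(l for l, c in counts.items() if c == top))
        if len(set(pattern)) < 2:
            continue
        mism = sum(1 for i, l in enumerate(labels) if l != pattern[i % p]) / n
        if mism <= tol:
            return p, mism
    return None, 1.0


def match_type_labels(
    consensus_a: dict[str, str], consensus_b: dict[str, str]
) -> dict[str, str]:
    """Best bipartite matching of type labels across two proteins by
    consensus-vs-consensus identity; returns a b-label -> a-label map."""
    a_labels = sorted(consensus_a)
    b_labels = sorted(consensus_b)
    score = np.zeros((len(b_labels), len(a_labels)))
    for i, bl in enumerate(b_labels):
        for j, al in enumerate(a_labels):
            score[i, j] = pairwise_identity(consensus_b[bl], consensus_a[al])
    rows, cols = linear_sum_assignment(-score)
    return {b_labels[i]: a_labels[j] for i, j in zip(rows, cols)}


def compare_architectures(
    a: ArchitectureString,
    b: ArchitectureString,
    type_map: dict[str, str] | None = None,
) -> tuple[float, list[str], list[str]]:
    """Edit-distance alignment of two type-label strings.

    ``type_map`` translates b's labels into a's label space (see
    :func:`match_type_labels`); unmapped labels mismatch everything (with a
    warning).  Returns (normalized distance in [0, 1], aligned a, aligned b).
    """
    la = list(a.labels)
    lb_raw = list(b.labels)
    lb = []
    for l in lb_raw:
        if type_map is None:
            lb.append(l)
        elif l in type_map:
            lb.append(type_map[l])
        else:
            warnings.warn(f"unmapped type label {l!r}; treated as mismatch", stacklevel=2)
            lb.append(f"?{l}")
    n, m = len(la), len(lb)
    if n == 0 and m == 0:
        return 0.0, [], []
    if n == 0 or m == 0:
        return 1.0, la + ["-"] * m, ["-"] * n + lb
    D = np.zeros((n + 1, m + 1), dtype=int)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if la[i - 1] == lb[j - 1] else 1
            D[i, j] = min(D[i - 1, j - 1] + cost, D[i - 1, j] + 1, D[i, j - 1] + 1)
    # traceback (diagonal preferred)
    i, j = n, m
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        cost = 0 if (i > 0 and j > 0 and la[i - 1] == lb[j - 1]) else 1
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + cost:
            out_a.append(la[i - 1])
            out_b.append(lb[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            out_a.append(la[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(lb[j - 1])
            j -= 1
    return D[n, m] / max(n, m), out_a[::-1], out_b[::-1]


# ---------------------------------------------------------------------------
# end-to-end annotation
# ---------------------------------------------------------------------------

def annotate_repeats(
    protein: str,
    nterm_refs: list[str] | None = None,
    cterm_refs: list[str] | None = None,
    unit_hint: int | str | None = None,
    cut: float = 0.35,
    hor_tol: float = 0.1,
) -> RepeatAnnotation:
    """Partition, segment, type, and summarize one spidroin protein."""
    partition = partition_domains(protein, nterm_refs, cterm_refs)
    a, b = partition.repeat_region
    region = protein[a:b]
    units = segment_repeats(region, unit_hint=unit_hint)
    units = [RepeatUnit(u.start + a, u.end + a, u.seq) for u in units]
    consensus = ConsensusModel()
    if len(units) >= 2:
        matrix = pairwise_identity_matrix(units)
        labels = cluster_repeat_types(matrix, cut=cut)
        for u, l in zip(units, labels):
            u.type_label = l
        for label in sorted(set(labels), key=int):
            members = [u for u in units if u.type_label == label]
            cons, prof = build_consensus(members)
            consensus.consensus[label] = cons
            consensus.profiles[label] = prof
        arch = ArchitectureString(labels=labels)
        if len(labels) >= 4:
            period, mism = higher_order_period(arch, tol=hor_tol)
            arch.period, arch.period_mismatch = period, mism
    else:
        arch = ArchitectureString(labels=[u.type_label for u in units])
    return RepeatAnnotation(
        partition=partition, units=units, consensus=consensus, architecture=arch
    )


def annotation_to_gff3(annotation: RepeatAnnotation, seqid: str) -> str:
    """Render an annotation as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    src = "spidarch"
    p = annotation.partition
    if p.a > 0:
        lines.append(f"{seqid}\t{src}\tregion\t1\t{p.a}\t.\t+\t.\tName=N-terminal")
    if p.b > p.a:
        lines.append(f"{seqid}\t{src}\tregion\t{p.a + 1}\t{p.b}\t.\t+\t.\tName=repetitive")
    if p.b < p.length:
        lines.append(
            f"{seqid}\t{src}\tregion\t{p.b + 1}\t{p.length}\t.\t+\t.\tName=C-terminal"
        )
    for idx, u in enumerate(annotation.units, 1):
        attrs = f"ID=repeat_{idx};Type={u.type_label or '.'}"
        lines.append(
            f"{seqid}\t{src}\trepeat_unit\t{u.start + 1}\t{u.end}\t.\t+\t.\t{attrs}"
        )
    return "\n".join(lines) + "\n"
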