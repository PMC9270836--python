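"""Terminal-domain gene trees: alignment, distance matrices, NJ/UPGMA,
bootstrap support, and duplication flagging.

Spidroin gene families are classified by their conserved N- and C-terminal
domains: the two regions are aligned separately, concatenated, and a gene tree
is inferred from p-distances.  Duplication nodes are inferred by the
species-overlap rule (a node whose child subtrees share a species implies a
duplication predating the split).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from skbio import TreeNode

from .align import aligned_identity
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
_B62_ALPHA = _B62.alphabet
_B62_INDEX = {a: i for i, a in enumerate(_B62_ALPHA)}

GAP_OPEN = 10.0
GAP_EXTEND = 1.0


@dataclass
class Alignment:
    """An ordered multiple sequence alignment (equal-length gapped rows)."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in alignment")
        if self.rows and len({len(s) for _, s in self.rows}) != 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def sequences(self) -> list[str]:
        return [s for _, s in self.rows]


# ---------------------------------------------------------------------------
# profile-profile Gotoh alignment (the progressive-MSA engine)
# ---------------------------------------------------------------------------

def _subst(x: str, y: str) -> float:
    i = _B62_INDEX.get(x, _B62_INDEX["*"])
    j = _B62_INDEX.get(y, _B62_INDEX["*"])
    return float(_B62[i, j])


def _column_freqs(rows: list[str]) -> list[Counter]:
    return [Counter(col) for col in zip(*rows)]


def _profile_score(col_a: Counter, na: int, col_b: Counter, nb: int) -> float:
    """Expected substitution score between two profile columns.

    Residue-residue pairs score BLOSUM62; residue-gap pairs score the gap
    extension penalty; gap-gap pairs score zero.
    """
    total = 0.0
    for x, cx in col_a.items():
        for y, cy in col_b.items():
            if x == "-" and y == "-":
                continue
            if x == "-" or y == "-":
                total += cx * cy * (-GAP_EXTEND)
            else:
                total += cx * cy * _subst(x, y)
    return total / (na * nb)


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Global affine-gap (Gotoh) alignment of two profiles.

    Deterministic traceback preference: diagonal > up (gap in B) > left
    (gap in A).  Columns of each input profile are never reordered.
    """
    la, lb = len(rows_a[0]), len(rows_b[0])
    na, nb = len(rows_a), len(rows_b)
    fa, fb = _column_freqs(rows_a), _column_freqs(rows_b)
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A column)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A (consume B column)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -GAP_OPEN - GAP_EXTEND * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = -GAP_OPEN - GAP_EXTEND * (j - 1)
    score = np.empty((la, lb))
    for i in range(la):
        for j in range(lb):
            score[i, j] = _profile_score(fa[i], na, fb[j], nb)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + score[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] - GAP_OPEN, X[i - 1, j] - GAP_EXTEND)
            Y[i, j] = max(M[i, j - 1] - GAP_OPEN, Y[i, j - 1] - GAP_EXTEND)
    # traceback with deterministic tie preference M (diagonal) > X (up) > Y (left)
    def pick(vm: float, vx: float, vy: float) -> str:
        best = max(vm, vx, vy)
        if vm == best:
            return "M"
        if vx == best:
            return "X"
        return "Y"

    i, j = la, lb
    state = pick(M[i, j], X[i, j], Y[i, j])
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            ops.append("AB")
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = pick(M[i, j], X[i, j], Y[i, j])
        elif state == "X":
            ops.append("A-")
            if M[i - 1, j] - GAP_OPEN >= X[i - 1, j] - GAP_EXTEND:
                state = "M"
            i -= 1
        else:
            ops.append("-B")
            if M[i, j - 1] - GAP_OPEN >= Y[i, j - 1] - GAP_EXTEND:
                state = "M"
            j -= 1
    ops.reverse()
    ops_a = [op[0] for op in ops]
    ops_b = [op[1] for op in ops]
    new_rows_a = []
    for row in rows_a:
        it = iter(row)
        new_rows_a.append("".join(next(it) if op == "A" else "-" for op in ops_a))
    new_rows_b = []
    for row in rows_b:
        it = iter(row)
        new_rows_b.append("".join(next(it) if op == "B" else "-" for op in ops_b))
    return new_rows_a, new_rows_b


def pairwise_align(a: str, b: str) -> Alignment:
    """Optimal global pairwise alignment (BLOSUM62, affine gaps 10/1)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    ra, rb = _align_profiles([a], [b])
    return Alignment(rows=[("a", ra[0]), ("b", rb[0])])


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    kb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    shared = sum((ka & kb).values())
    denom = min(sum(ka.values()), sum(kb.values()))
    if denom == 0:
        return 1.0
    return 1.0 - shared / denom


def progressive_align(seqs: list[tuple[str, str]]) -> Alignment:
    """Progressive multiple alignment over a UPGMA k-mer guide tree.

    Profiles are merged pairwise by global profile DP following the guide
    tree's merge order; columns are never reordered, so the result is
    deterministic.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_align needs at least two sequences")
    if len(seqs) == 2:
        (ia, sa), (ib, sb) = seqs
        ra, rb = _align_profiles([sa], [sb])
        return Alignment(rows=[(ia, ra[0]), (ib, rb[0])])
    n = len(seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _kmer_distance(seqs[i][1], seqs[j][1])
    condensed = dm[np.triu_indices(n, k=1)]
    Z = linkage(condensed, method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([seqs[i][0]], [seqs[i][1]]) for i in range(n)
    }
    for step, (ci, cj, _, _) in enumerate(Z):
        ids_a, rows_a = clusters.pop(int(ci))
        ids_b, rows_b = clusters.pop(int(cj))
        new_a, new_b = _align_profiles(rows_a, rows_b)
        clusters[n + step] = (ids_a + ids_b, new_a + new_b)
    ids, rows = clusters.popitem()[1]
    order = {sid: k for k, (sid, _) in enumerate(seqs)}
    merged = sorted(zip(ids, rows), key=lambda pair: order[pair[0]])
    return Alignment(rows=list(merged))


def concat_alignments(n_msa: Alignment, c_msa: Alignment) -> Alignment:
    """Row-wise concatenation of two region alignments.

    Ids present in only one region are padded with all-gap segments for the
    other (partial sequences lacking one terminus stay in the analysis).
    """
    n_map = dict(n_msa.rows)
    c_map = dict(c_msa.rows)
    all_ids = list(dict.fromkeys(n_msa.ids + c_msa.ids))
    ln, lc = n_msa.length, c_msa.length
    rows = [
        (i, n_map.get(i, "-" * ln) + c_map.get(i, "-" * lc))
        for i in all_ids
    ]
    return Alignment(rows=rows)


# ---------------------------------------------------------------------------
# distances and trees
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix not symmetric")
        self.matrix = m


def p_distance_matrix(msa: Alignment) -> DistanceMatrix:
    """1 - pairwise identity per row pair (both-gap columns excluded)."""
    if len(msa.rows) < 2:
        raise ValueError("need at least two rows")
    n = len(msa.rows)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = msa.rows[i][1], msa.rows[j][1]
            if all(x == "-" or y == "-" for x, y in zip(a, b)):
                warnings.warn(
                    f"no scored columns between {msa.ids[i]} and {msa.ids[j]}; distance set to 1",
                    stacklevel=2,
                )
                d = 1.0
            else:
                d = 1.0 - aligned_identity(a, b)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(ids=msa.ids, matrix=m)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining.

    Negative branch lengths are clamped to zero with the deficit moved to the
    sister branch; ties in the Q criterion break by lexicographic (smaller,
    larger) taxon-pair name so the result is deterministic.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    labels = list(dm.ids)  # representative (lexicographically smallest leaf) per cluster
    D = dm.matrix.copy().astype(float)
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((labels[i], labels[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = D[i, j] - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = TreeNode()
        nodes[i].length = float(vi)
        nodes[j].length = float(vj)
        parent.extend([nodes[i], nodes[j]])
        # reuse slot i for the new cluster
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
            D[i, k] = D[k, i] = dk
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)
    i, j, k = active
    vi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    vj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    vk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = TreeNode()
    for idx, v in ((i, vi), (j, vj), (k, vk)):
        nodes[idx].length = float(max(v, 0.0))
        root.append(nodes[idx])
    return root


def upgma_tree(dm: DistanceMatrix) -> TreeNode:
    """Rooted ultrametric tree by average-linkage agglomeration.

    Node heights are half the cophenetic merge distance, so two leaves at
    distance d coalesce at height d/2.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        root = TreeNode()
        h = dm.matrix[0, 1] / 2.0
        for name in dm.ids:
            root.append(TreeNode(name=name, length=h))
        return root
    condensed = dm.matrix[np.triu_indices(n, k=1)]
    Z = linkage(condensed, method="average")
    nodes: dict[int, TreeNode] = {i: TreeNode(name=dm.ids[i]) for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for step, (ci, cj, dist, _) in enumerate(Z):
        h = dist / 2.0
        parent = TreeNode()
        for c in (int(ci), int(cj)):
            child = nodes.pop(c)
            child.length = h - heights.pop(c)
            parent.append(child)
        nodes[n + step] = parent
        heights[n + step] = h
    return nodes.popitem()[1]


# ---------------------------------------------------------------------------
# bootstrap and duplication flags
# ---------------------------------------------------------------------------

def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> dict[int, frozenset[str]]:
    """Non-trivial bipartitions keyed by node id; each side normalized to the
    half not containing the lexicographically smallest taxon."""
    anchor = min(taxa)
    out: dict[int, frozenset[str]] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        if anchor in side:
            side = taxa - side
        out[id(node)] = side
    return out


def bootstrap_support(
    msa: Alignment, tree_builder, n_replicates: int = 100, seed: int = 0
) -> TreeNode:
    """Column-resampling bootstrap; supports as % of replicates containing
    each internal bipartition of the full-data tree."""
    tree = tree_builder(p_distance_matrix(msa))
    if n_replicates <= 0:
        return tree
    rng = np.random.default_rng(seed)
    taxa = frozenset(msa.ids)
    ref = _bipartitions(tree, taxa)
    counts = {nid: 0 for nid in ref}
    L = msa.length
    seq_arr = np.array([list(s) for _, s in msa.rows])
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rows = ["".join(r) for r in seq_arr[:, cols]]
        rep = Alignment(rows=list(zip(msa.ids, rows)))
        rep_tree = tree_builder(p_distance_matrix(rep))
        rep_parts = set(_bipartitions(rep_tree, taxa).values())
        for nid, side in ref.items():
            if side in rep_parts:
                counts[nid] += 1
    for node in tree.non_tips(include_self=False):
        if id(node) in counts:
            node.support = 100.0 * counts[id(node)] / n_replicates
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    return tree.root_at_midpoint()


def flag_duplications(
    tree: TreeNode, species_of: dict[str, str], support_min: float = 50.0
) -> TreeNode:
    """Species-overlap duplication inference on a rooted gene tree.

    An internal node is a duplication iff the species sets of its child
    subtrees intersect.  The flag is *reported* only where the node's bootstrap
    support exceeds ``support_min`` (nodes without support are always
    reported).
    """
    if len(tree.children) > 2:
        raise ValueError(
            "tree is unrooted (basal multifurcation); root it first, "
            "e.g. with midpoint_root() or an outgroup"
        )
    missing = [t.name for t in tree.tips() if t.name not in species_of]
    if missing:
        raise ValueError(f"leaves without species mapping: {missing[:5]}")
    for node in tree.postorder():
        if node.is_tip():
            node._species = {species_of[node.name]}
            node.duplication = False
            continue
        child_sets = [c._species for c in node.children]
        node._species = set().union(*child_sets)
        overlap = False
        for i in range(len(child_sets)):
            for j in range(i + 1, len(child_sets)):
                if child_sets[i] & child_sets[j]:
                    overlap = True
        support = getattr(node, "support", None)
        node.duplication = overlap and (support is None or support > support_min)
    return tree


# ---------------------------------------------------------------------------
# newick I/O (supports as internal-node labels, 6-decimal lengths)
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            body = node.name or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            support = getattr(node, "support", None)
            label = "" if support is None else format(support, "g")
            body = f"({inner}){label}"
        if node.length is not None:
            body += f":{node.length:.6f}"
        return body

    return fmt(tree) + ";"


def read_newick(text: str) -> TreeNode:
    tree = TreeNode.read([text], convert_underscores=False)
    for node in tree.non_tips(include_self=True):
        if node.name is not None:
            try:
                node.support = float(node.name)
                node.name = None
            except ValueError:
                pass
    return tree
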