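"""Transcriptome pruning: retention categories, chimera exclusion, and
one-representative-allele-per-gene selection.

A de novo (Trinity-style) assembly carries multiple alleles/isoforms per gene
plus misassembled and non-coding transcripts.  Given tabular BLAST hits of the
transcripts against a curated protein database (and the reverse search),
per-library TPM expression, and a list of structural-RNA transcript ids, each
transcript is assigned one of five categories:

* ``BEST``    — reciprocal best hit (RBH) with a database gene;
* ``2BEST``   — top-scoring match of some database gene while a sibling isoform
  of the same Trinity gene holds an RBH;
* ``GOOD``    — a significant hit with subject coverage >= 20% and expression
  >= 1 TPM in at least one library;
* ``LONGORF`` — no hit at all, but an ORF of >= 50 aa and >= 1 TPM;
* ``DISCARD`` — everything else (with a machine-readable reason).

Chimeric transcripts (two database genes matched side-by-side) and structural
RNAs are excluded up front, and finally exactly one non-discarded isoform per
Trinity gene is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seq_io import SequenceRecord, find_orfs, parse_trinity_id

CATEGORY_RANK = {"BEST": 0, "2BEST": 1, "GOOD": 2, "LONGORF": 3, "DISCARD": 4}

DISCARD_REASONS = {
    "chimeric",
    "structural_rna",
    "low_coverage",
    "low_expression",
    "no_orf",
    "not_representative",
}


@dataclass(frozen=True)
class BlastHit:
    """One row of a 12-column tabular hit file, 0-based half-open coordinates."""

    query_id: str
    subject_id: str
    pct_identity: float  # fraction in [0, 1]
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    subject_len: int


@dataclass
class HitTable:
    hits: list[BlastHit]
    by_query: dict[str, list[BlastHit]] = field(default_factory=dict)
    by_subject: dict[str, list[BlastHit]] = field(default_factory=dict)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not self.by_query:
            for h in self.hits:
                self.by_query.setdefault(h.query_id, []).append(h)
                self.by_subject.setdefault(h.subject_id, []).append(h)


@dataclass
class CurationParams:
    cov_min: float = 0.20
    min_aa: int = 50
    tpm_min: float = 1.0
    evalue_max: float = 1e-10
    chimera_cov_min: float = 0.20
    chimera_ovl_max: float = 0.20
    support_min: float = 50.0  # unused here; kept for CLI symmetry


def read_subject_lengths(path: str | Path) -> dict[str, int]:
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, slen = line.split("\t")[:2]
            lengths[sid] = int(slen)
    return lengths


def parse_hit_rows(
    lines: Iterable[str],
    subject_lengths: Mapping[str, int],
    evalue_max: float = 1e-10,
    source: str = "<rows>",
) -> HitTable:
    """Parse 12-column tabular hit rows already in memory.

    Coordinates are converted from the 1-based inclusive file convention to
    0-based half-open; rows with e-value above ``evalue_max`` are dropped and
    counted.  Every subject must appear in the subject-lengths table.
    """
    hits: list[BlastHit] = []
    dropped = 0
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\r\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ValueError(f"{source}:{lineno}: expected 12 columns, got {len(fields)}")
        try:
            (q, s, pid, alen, mm, go, qs, qe, ss, se, ev, bs) = fields
            hit = BlastHit(
                query_id=q,
                subject_id=s,
                pct_identity=float(pid) / 100.0,
                aln_len=int(alen),
                mismatches=int(mm),
                gap_opens=int(go),
                q_start=min(int(qs), int(qe)) - 1,
                q_end=max(int(qs), int(qe)),
                s_start=min(int(ss), int(se)) - 1,
                s_end=max(int(ss), int(se)),
                evalue=float(ev),
                bitscore=float(bs),
                subject_len=0,
            )
        except ValueError as exc:
            raise ValueError(f"{source}:{lineno}: malformed row ({exc})") from None
        if hit.subject_id not in subject_lengths:
            raise ValueError(f"{source}:{lineno}: unknown subject id {hit.subject_id!r}")
        if hit.evalue > evalue_max:
            dropped += 1
            continue
        hits.append(replace(hit, subject_len=subject_lengths[hit.subject_id]))
    return HitTable(hits=hits, n_dropped=dropped)


def parse_hit_table(
    path: str | Path,
    subject_lengths: str | Path | Mapping[str, int],
    evalue_max: float = 1e-10,
) -> HitTable:
    """Parse a 12-column tabular hit file (see :func:`parse_hit_rows`)."""
    if not isinstance(subject_lengths, Mapping):
        subject_lengths = read_subject_lengths(subject_lengths)
    with open(path) as fh:
        table = parse_hit_rows(fh, subject_lengths, evalue_max, source=str(path))
    if not table.hits:
        warnings.warn(f"no hits retained from {path}", stacklevel=2)
    return table


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for start, end in sorted(intervals):
        start = max(start, last_end)
        if end > start:
            total += end - start
            last_end = end
        last_end = max(last_end, end)
    return total


def subject_coverage(hits: Sequence[BlastHit]) -> float:
    """Union of subject intervals across HSPs of one (query, subject) pair,
    divided by subject length."""
    if not hits:
        raise ValueError("subject_coverage of an empty hit list")
    if len({(h.query_id, h.subject_id) for h in hits}) != 1:
        raise ValueError("all HSPs must share query and subject")
    return _union_length((h.s_start, h.s_end) for h in hits) / hits[0].subject_len


def best_subject_coverage(hits: Sequence[BlastHit]) -> tuple[str | None, float]:
    """Best-covered subject of a query: (subject_id, coverage)."""
    per_subject: dict[str, list[BlastHit]] = {}
    for h in hits:
        per_subject.setdefault(h.subject_id, []).append(h)
    best: tuple[str | None, float] = (None, 0.0)
    for sid in sorted(per_subject):
        cov = subject_coverage(per_subject[sid])
        if cov > best[1]:
            best = (sid, cov)
    return best


def _hit_sort_key(h: BlastHit) -> tuple[float, float, str, str]:
    return (-h.bitscore, h.evalue, h.subject_id, h.query_id)


def _best_target(hits: Sequence[BlastHit]) -> str:
    """Top subject of a query's hits: highest bitscore, then lower e-value,
    then lexicographic subject id (deterministic)."""
    return min(hits, key=_hit_sort_key).subject_id


def reciprocal_best_hits(forward: HitTable, reverse: HitTable) -> set[tuple[str, str]]:
    """(transcript, database gene) pairs where each is the other's top hit.

    ``forward`` is the transcripts->database search; ``reverse`` the
    database->transcripts search (its queries are database genes).
    """
    fwd_best = {q: _best_target(hs) for q, hs in forward.by_query.items()}
    rev_best = {s: _best_target(hs) for s, hs in reverse.by_query.items()}
    return {
        (q, s)
        for q, s in fwd_best.items()
        if rev_best.get(s) == q
    }


def detect_chimeras(
    table: HitTable, cov_min: float = 0.20, ovl_max: float = 0.20
) -> set[str]:
    """Transcripts matching two database genes side-by-side.

    A transcript is flagged iff it has hits to >= 2 distinct subjects, each with
    subject coverage >= ``cov_min``, whose query intervals overlap by less than
    ``ovl_max`` of the shorter interval.
    """
    flagged: set[str] = set()
    for q, hits in table.by_query.items():
        per_subject: dict[str, list[BlastHit]] = {}
        for h in hits:
            per_subject.setdefault(h.subject_id, []).append(h)
        spans: list[tuple[int, int]] = []
        for sid, hs in per_subject.items():
            if subject_coverage(hs) < cov_min:
                continue
            spans.append((min(h.q_start for h in hs), max(h.q_end for h in hs)))
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                (a0, a1), (b0, b1) = spans[i], spans[j]
                overlap = max(0, min(a1, b1) - max(a0, b0))
                shorter = min(a1 - a0, b1 - b0)
                if shorter > 0 and overlap < ovl_max * shorter:
                    flagged.add(q)
        # (fully overlapping subjects are alternative homologs, not chimeras)
    return flagged


@dataclass
class TranscriptCall:
    transcript_id: str
    category: str
    reason: str
    best_subject: str | None = None
    coverage: float = 0.0
    max_tpm: float = 0.0
    bitscore: float = 0.0
    longest_orf: int = 0

    def __post_init__(self) -> None:
        if self.category == "BEST" and self.reason != "rbh":
            raise ValueError("BEST implies reason rbh")
        if self.category == "DISCARD" and self.reason not in DISCARD_REASONS:
            raise ValueError(f"invalid discard reason {self.reason!r}")


def load_expression(path: str | Path) -> pd.DataFrame:
    """Load an expression table as transcripts x libraries (TPM).

    Accepts either long format (transcript_id, library_id, tpm) or a wide
    matrix with transcripts as the first column.
    """
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if len(df.columns) == 3 and "tpm" in cols:
        df.columns = ["transcript_id", "library_id", "tpm"]
        wide = df.pivot(index="transcript_id", columns="library_id", values="tpm")
    else:
        wide = df.set_index(df.columns[0])
    if (wide < 0).any().any():
        raise ValueError("negative TPM value in expression table")
    if wide.isna().any().any():
        raise ValueError("expression table must cover every library for every transcript")
    return wide


def classify_transcripts(
    hits: HitTable,
    rbh_pairs: set[tuple[str, str]],
    expression: pd.DataFrame,
    orf_lengths: Mapping[str, int],
    rna_ids: set[str],
    transcript_ids: Sequence[str],
    params: CurationParams | None = None,
    reverse_hits: HitTable | None = None,
    chimeric: set[str] | None = None,
) -> list[TranscriptCall]:
    """Assign every transcript a retention category.

    Precedence: structural_rna -> chimeric -> BEST -> 2BEST -> GOOD -> LONGORF
    -> DISCARD (first failing reason, coverage before expression).  BEST/2BEST
    are exempt from the coverage and expression filters: they are the best hits
    to the database genes.
    """
    params = params or CurationParams()
    if chimeric is None:
        chimeric = detect_chimeras(hits, params.chimera_cov_min, params.chimera_ovl_max)
    missing = [t for t in hits.by_query if t not in expression.index]
    if missing:
        raise ValueError(f"transcripts with hits but no expression: {missing[:5]}")

    rbh_queries = {q for q, _ in rbh_pairs}
    rbh_by_gene: dict[str, set[str]] = {}
    for q in rbh_queries:
        rbh_by_gene.setdefault(parse_trinity_id(q).gene, set()).add(q)

    # transcripts that are the top-scoring match of some database gene
    # (evaluated on the reverse, database->transcript, search)
    top_of_some_subject: set[str] = set()
    if reverse_hits is not None:
        for s, hs in reverse_hits.by_query.items():
            top_of_some_subject.add(_best_target(hs))

    max_tpm = expression.max(axis=1)
    calls: list[TranscriptCall] = []
    for t in transcript_ids:
        t_hits = hits.by_query.get(t, [])
        best_subject, coverage = best_subject_coverage(t_hits) if t_hits else (None, 0.0)
        bitscore = max((h.bitscore for h in t_hits), default=0.0)
        tpm = float(max_tpm.get(t, 0.0))
        orf = int(orf_lengths.get(t, 0))
        common = dict(
            transcript_id=t,
            best_subject=best_subject,
            coverage=coverage,
            max_tpm=tpm,
            bitscore=bitscore,
            longest_orf=orf,
        )
        gene = parse_trinity_id(t).gene
        if t in rna_ids:
            calls.append(TranscriptCall(category="DISCARD", reason="structural_rna", **common))
        elif t in chimeric:
            calls.append(TranscriptCall(category="DISCARD", reason="chimeric", **common))
        elif t in rbh_queries:
            calls.append(TranscriptCall(category="BEST", reason="rbh", **common))
        elif t in top_of_some_subject and (rbh_by_gene.get(gene, set()) - {t}):
            calls.append(TranscriptCall(category="2BEST", reason="best_to_gene", **common))
        elif t_hits:
            if coverage >= params.cov_min and tpm >= params.tpm_min:
                calls.append(TranscriptCall(category="GOOD", reason="coverage_expression", **common))
            elif coverage < params.cov_min:
                calls.append(TranscriptCall(category="DISCARD", reason="low_coverage", **common))
            else:
                calls.append(TranscriptCall(category="DISCARD", reason="low_expression", **common))
        else:
            if orf >= params.min_aa and tpm >= params.tpm_min:
                calls.append(TranscriptCall(category="LONGORF", reason="longorf", **common))
            elif orf < params.min_aa:
                calls.append(TranscriptCall(category="DISCARD", reason="no_orf", **common))
            else:
                calls.append(TranscriptCall(category="DISCARD", reason="low_expression", **common))
    return calls


def select_representatives(calls: list[TranscriptCall]) -> list[TranscriptCall]:
    """Keep exactly one non-DISCARD isoform per Trinity gene.

    Chosen by category rank (BEST > 2BEST > GOOD > LONGORF), then higher best
    bitscore, then longer longest ORF, then lexicographic id.  All other
    isoforms are re-marked DISCARD/not_representative.
    """
    by_gene: dict[str, list[TranscriptCall]] = {}
    for c in calls:
        by_gene.setdefault(parse_trinity_id(c.transcript_id).gene, []).append(c)
    out: list[TranscriptCall] = []
    winners: set[str] = set()
    for gene, group in by_gene.items():
        candidates = [c for c in group if c.category != "DISCARD"]
        if candidates:
            best = min(
                candidates,
                key=lambda c: (
                    CATEGORY_RANK[c.category],
                    -c.bitscore,
                    -c.longest_orf,
                    c.transcript_id,
                ),
            )
            winners.add(best.transcript_id)
    for c in calls:
        if c.category != "DISCARD" and c.transcript_id not in winners:
            out.append(replace(c, category="DISCARD", reason="not_representative"))
        else:
            out.append(c)
    return out


@dataclass
class CurationReport:
    category_counts: dict[str, int]
    gene_counts: dict[str, int]
    retained_ids: list[str]

    @property
    def total(self) -> int:
        return sum(self.category_counts.values())


@dataclass
class CurationResult:
    calls: list[TranscriptCall]
    retained: list[SequenceRecord]
    report: CurationReport

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript_id": c.transcript_id,
                    "trinity_gene": parse_trinity_id(c.transcript_id).gene,
                    "category": c.category,
                    "reason": c.reason,
                    "best_subject": c.best_subject or "",
                    "coverage": round(c.coverage, 6),
                    "max_tpm": round(c.max_tpm, 6),
                }
                for c in self.calls
            ],
            columns=[
                "transcript_id",
                "trinity_gene",
                "category",
                "reason",
                "best_subject",
                "coverage",
                "max_tpm",
            ],
        )


def run_curation(
    records: list[SequenceRecord],
    hits: HitTable,
    reverse_hits: HitTable,
    expression: pd.DataFrame,
    rna_ids: set[str],
    params: CurationParams | None = None,
) -> CurationResult:
    """Full pruning pipeline: classify, then select one allele per gene."""
    params = params or CurationParams()
    orf_lengths = {
        r.id: (orfs[0].aa_len if (orfs := find_orfs(r, min_aa=1)) else 0) for r in records
    }
    rbh = reciprocal_best_hits(hits, reverse_hits)
    calls = classify_transcripts(
        hits,
        rbh,
        expression,
        orf_lengths,
        rna_ids,
        transcript_ids=[r.id for r in records],
        params=params,
        reverse_hits=reverse_hits,
    )
    calls = select_representatives(calls)
    retained_ids = {c.transcript_id for c in calls if c.category != "DISCARD"}
    retained = [r for r in records if r.id in retained_ids]
    cat_counts: dict[str, int] = {}
    gene_counts: dict[str, set[str]] = {}
    for c in calls:
        cat_counts[c.category] = cat_counts.get(c.category, 0) + 1
        gene_counts.setdefault(c.category, set()).add(parse_trinity_id(c.transcript_id).gene)
    report = CurationReport(
        category_counts=cat_counts,
        gene_counts={k: len(v) for k, v in gene_counts.items()},
        retained_ids=sorted(retained_ids),
    )
    return CurationResult(calls=calls, retained=retained, report=report)
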