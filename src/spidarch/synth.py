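"""Seeded generators for spidroin proteins and Trinity-style transcriptome
fixtures, each with complete ground-truth annotations.

The generators emulate the study conditions the analysis modules are built
for: tandem-repeat silk proteins with conserved terminal domains (aciniform-
like single-type architectures of ten ~357-aa units; pseudoflagelliform-like
architectures of 48 short units in four types recurring with period 4, each
unit opening with a conserved glycine-poor spacer), and a de novo
transcriptome whose transcripts carry planted retention categories.  Hit
tables are synthesized directly from the planted homology rather than by
running an aligner, so tests need no search tool.  All outputs are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .repeat_arch import (
    ArchitectureString,
    ConsensusModel,
    DomainPartition,
    RepeatAnnotation,
    RepeatUnit,
)
from .seq_io import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Spidroin-like residue bias for repeat templates: serine/alanine/glycine
# enriched, as in aciniform repeats (S 25%, A 14%, G 8%), remainder spread
# over the other seventeen residues.
SPIDROIN_BIAS = {"S": 0.25, "A": 0.14, "G": 0.08}

#: Synthetic 100-aa terminal-domain exemplars (generated from a fixed seed;
#: not copied from any database).  They play the role of the conserved
#: spidroin N/C-terminal references in domain partitioning.
_rng_templates = np.random.default_rng(20220709)
NTERM_TEMPLATE = "".join(_rng_templates.choice(list(AA20), size=100))
CTERM_TEMPLATE = "".join(_rng_templates.choice(list(AA20), size=100))


def _biased_residues(rng: np.random.Generator, n: int, bias: dict[str, float] | None) -> str:
    if not bias:
        return "".join(rng.choice(list(AA20), size=n))
    rest = [a for a in AA20 if a not in bias]
    p_rest = (1.0 - sum(bias.values())) / len(rest)
    letters = list(bias) + rest
    probs = list(bias.values()) + [p_rest] * len(rest)
    return "".join(rng.choice(letters, size=n, p=np.array(probs) / sum(probs)))


def mutate_sequence(
    seq: str, subst_rate: float, indel_rate: float, rng: int | np.random.Generator
) -> str:
    """Per-site substitutions (uniform over the 19 alternatives) and geometric
    indels (p = 2/3, mean length 1.5), insertion/deletion equiprobable."""
    if not (0 <= subst_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        ch = seq[i]
        if indel_rate > 0 and rng.random() < indel_rate:
            length = int(rng.geometric(2 / 3))
            if rng.random() < 0.5:  # insertion before this residue
                out.append("".join(rng.choice(list(AA20), size=length)))
            else:  # deletion of `length` residues starting here
                i += length
                continue
        if subst_rate > 0 and rng.random() < subst_rate:
            out.append(rng.choice([a for a in AA20 if a != ch]))
        else:
            out.append(ch)
        i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# spidroin generator
# ---------------------------------------------------------------------------

@dataclass
class SpidroinSpec:
    seed: int = 1
    n_units: int = 10
    unit_len: int = 357
    n_types: int = 1
    arrangement: str | int | None = None  # explicit label string, or a period
    subst_rate: float = 0.0
    indel_rate: float = 0.0
    nterm: str = NTERM_TEMPLATE
    cterm: str = CTERM_TEMPLATE
    spacer: str | None = None  # conserved block prepended to every unit
    composition_bias: dict[str, float] | None = field(
        default_factory=lambda: dict(SPIDROIN_BIAS)
    )

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if not (0 <= self.subst_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("rates must lie in [0, 1)")


def _arrangement_labels(spec: SpidroinSpec) -> list[str]:
    if isinstance(spec.arrangement, str):
        labels = list(spec.arrangement)
        if len(labels) != spec.n_units:
            raise ValueError("arrangement length must equal n_units")
        if len(set(labels)) > spec.n_types:
            raise ValueError("arrangement uses more labels than n_types")
        return labels
    if isinstance(spec.arrangement, int):
        period = spec.arrangement
        if period != spec.n_types:
            raise ValueError("period arrangement requires period == n_types")
        if spec.n_units % period != 0:
            raise ValueError("period does not divide n_units for exact tiling")
        base = [str(i + 1) for i in range(period)]
        return base * (spec.n_units // period)
    # default: cycle through the types
    return [str(i % spec.n_types + 1) for i in range(spec.n_units)]


def make_spidroin(spec: SpidroinSpec) -> tuple[SequenceRecord, RepeatAnnotation]:
    """Build a synthetic spidroin and its ground-truth repeat annotation.

    Protein = nterm + mutated unit copies per arrangement + cterm.  Each unit
    template is a (shared) spacer block followed by a type-specific block;
    every copy is independently mutated at the spec's substitution/indel
    rates.  Truth records the exact post-mutation unit boundaries, type
    labels, and the higher-order period implied by the arrangement.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _arrangement_labels(spec)
    spacer = spec.spacer or ""
    var_len = spec.unit_len - len(spacer)
    if var_len <= 0:
        raise ValueError("spacer longer than unit_len")
    templates = {
        str(t + 1): spacer + _biased_residues(rng, var_len, spec.composition_bias)
        for t in range(spec.n_types)
    }
    parts: list[str] = [spec.nterm]
    pos = len(spec.nterm)
    units: list[RepeatUnit] = []
    for label in labels:
        copy = mutate_sequence(templates[label], spec.subst_rate, spec.indel_rate, rng)
        units.append(RepeatUnit(start=pos, end=pos + len(copy), seq=copy, type_label=label))
        parts.append(copy)
        pos += len(copy)
    parts.append(spec.cterm)
    protein = "".join(parts)
    record = SequenceRecord(
        id=f"synthetic_spidroin_seed{spec.seed}", residues=protein, moltype="aa"
    )
    partition = DomainPartition(a=len(spec.nterm), b=pos, length=len(protein))
    arch = ArchitectureString(labels=labels)
    if isinstance(spec.arrangement, int):
        arch.period = spec.arrangement
        arch.period_mismatch = 0.0
    consensus = ConsensusModel(
        consensus=dict(templates),
        profiles={l: [{r: 1.0} for r in t] for l, t in templates.items()},
    )
    truth = RepeatAnnotation(
        partition=partition, units=units, consensus=consensus, architecture=arch
    )
    return record, truth


def acsp1_like_spec(seed: int) -> SpidroinSpec:
    """Aciniform-like architecture: ten ~357-aa units of a single type at 5%
    substitutions and 1% indels — the repeat-recovery study condition."""
    return SpidroinSpec(
        seed=seed, n_units=10, unit_len=357, n_types=1, subst_rate=0.05, indel_rate=0.01
    )


#: Conserved glycine-poor spacer template (12 aa) used by the
#: pseudoflagelliform-like architecture; the variable block is glycine-rich.
PFLAG_SPACER = "ASTAKLQNVSTE"
PFLAG_BIAS = {"G": 0.38, "P": 0.11, "S": 0.15, "A": 0.08, "Q": 0.06, "E": 0.06}


def pflag_like_spec(seed: int) -> SpidroinSpec:
    """Pseudoflagelliform-like architecture: 48 ensemble repeats of ~50 aa in
    four types recurring with period 4, each opening with a conserved spacer,
    at 5% substitutions."""
    return SpidroinSpec(
        seed=seed,
        n_units=48,
        unit_len=50,
        n_types=4,
        arrangement=4,
        subst_rate=0.05,
        indel_rate=0.0,
        spacer=PFLAG_SPACER,
        composition_bias=dict(PFLAG_BIAS),
    )


# ---------------------------------------------------------------------------
# transcriptome generator
# ---------------------------------------------------------------------------

@dataclass
class TranscriptomeSpec:
    seed: int = 1
    n_genes: int = 60
    n_transcripts: int = 200
    chimera_rate: float = 0.05
    rna_rate: float = 0.05
    n_libraries: int = 4
    tpm_sigma: float = 1.0  # log-normal spread of expressed TPM values

    def __post_init__(self) -> None:
        for r in (self.chimera_rate, self.rna_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_transcripts < self.n_genes:
            raise ValueError("need at least one transcript per gene")


@dataclass
class TranscriptomeFixture:
    records: list[SequenceRecord]
    forward_rows: list[str]  # 12-column tabular rows, transcripts -> database
    reverse_rows: list[str]  # database -> transcripts
    subject_lengths: dict[str, int]
    expression: pd.DataFrame  # transcripts x libraries (TPM)
    rna_ids: set[str]
    truth: pd.DataFrame  # transcript_id, category, reason

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .seq_io import write_fasta

        write_fasta(self.records, outdir / "transcripts.fasta")
        (outdir / "hits_fwd.tsv").write_text("\n".join(self.forward_rows) + "\n")
        (outdir / "hits_rev.tsv").write_text("\n".join(self.reverse_rows) + "\n")
        (outdir / "subject_lengths.tsv").write_text(
            "\n".join(f"{s}\t{l}" for s, l in sorted(self.subject_lengths.items())) + "\n"
        )
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        (outdir / "rna_ids.txt").write_text("\n".join(sorted(self.rna_ids)) + "\n")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


_STOPS = ("TAA", "TAG", "TGA")

_CODONS_BY_AA: dict[str, list[str]] = {}


def _codons_for(aa: str) -> list[str]:
    if not _CODONS_BY_AA:
        from .seq_io import CODON_TABLE

        for codon, res in sorted(CODON_TABLE.items()):
            _CODONS_BY_AA.setdefault(res, []).append(codon)
    return _CODONS_BY_AA[aa]


def _coding_nt(rng: np.random.Generator, n_aa: int) -> str:
    """A stop-free coding stretch of ``n_aa`` codons (random synonymous
    codon usage, so the other five frames accumulate stops by chance)."""
    aas = rng.choice(list(AA20), size=n_aa)
    return "".join(rng.choice(_codons_for(a)) for a in aas)


def _orfless_nt(rng: np.random.Generator, n: int = 120) -> str:
    """A transcript too short to contain any >= 50 aa ORF in any frame."""
    return "".join(rng.choice(list("ACGT"), size=n))


def _long_orf_nt(rng: np.random.Generator, n_aa: int = 80) -> str:
    return _STOPS[0] + _coding_nt(rng, n_aa) + _STOPS[0]


def _exact_orf_nt(rng: np.random.Generator, n_aa: int) -> str:
    """A transcript whose longest six-frame ORF is exactly ``n_aa`` residues
    (rejection-sampled against spurious long runs on the other frames)."""
    from .seq_io import find_orfs

    while True:
        nt = _STOPS[0] + _coding_nt(rng, n_aa) + _STOPS[0]
        orfs = find_orfs(nt, min_aa=1)
        if orfs and orfs[0].aa_len == n_aa:
            return nt


def _tabrow(
    q: str,
    s: str,
    bitscore: float,
    q_iv: tuple[int, int],
    s_iv: tuple[int, int],
    evalue: float = 1e-50,
    pid: float = 90.0,
) -> str:
    qs, qe = q_iv
    ss, se = s_iv
    alen = max(qe - qs, se - ss)
    return "\t".join(
        str(x)
        for x in (
            q, s, pid, alen, int(alen * 0.1), 0,
            qs + 1, qe, ss + 1, se, evalue, bitscore,
        )
    )


def make_transcriptome(spec: TranscriptomeSpec) -> TranscriptomeFixture:
    """Build a Trinity-style transcriptome fixture with planted truth.

    Gene scenarios (cycled deterministically across genes, rates honoured for
    chimera/structural-RNA transcripts): RBH genes whose extra isoforms are
    GOOD alternates; RBH + second-best sibling genes; GOOD genes; LONGORF
    genes; discard genes (low coverage / low expression / no ORF).  The truth
    table holds the final expected call per transcript, including
    ``not_representative`` for losing isoforms, computed from the planted
    attributes by the same documented ranking rule — never by running the
    pipeline itself.
    """
    rng = np.random.default_rng(spec.seed)
    # allocate isoform counts 1..4 summing to n_transcripts
    counts = [1 + int(rng.integers(0, 4)) for _ in range(spec.n_genes)]
    while sum(counts) != spec.n_transcripts:
        i = int(rng.integers(0, spec.n_genes))
        if sum(counts) > spec.n_transcripts and counts[i] > 1:
            counts[i] -= 1
        elif sum(counts) < spec.n_transcripts and counts[i] < 4:
            counts[i] += 1

    n_chim = int(round(spec.chimera_rate * spec.n_transcripts))
    n_rna = int(round(spec.rna_rate * spec.n_transcripts))

    records: list[SequenceRecord] = []
    fwd: list[str] = []
    rev: list[str] = []
    subject_lengths: dict[str, int] = {}
    rna_ids: set[str] = set()
    expr_rows: dict[str, np.ndarray] = {}
    truth_rows: list[dict] = []
    libraries = [f"lib{k + 1}" for k in range(spec.n_libraries)]

    def expressed_tpm() -> np.ndarray:
        v = rng.lognormal(mean=1.0, sigma=spec.tpm_sigma, size=spec.n_libraries)
        v[int(rng.integers(0, spec.n_libraries))] = max(v.max(), 2.0)
        return np.round(v, 3)

    def silent_tpm() -> np.ndarray:
        return np.round(rng.uniform(0.0, 0.5, size=spec.n_libraries), 3)

    def new_subject(prefix: str, gi: int, k: int = 0, length: int = 400) -> str:
        sid = f"db_{prefix}_{gi}_{k}"
        subject_lengths[sid] = length
        return sid

    scenarios = ["best", "best2", "good", "longorf", "low_cov", "low_expr", "no_orf"]
    # queue of per-transcript overrides for chimera / structural RNA
    special = ["chimeric"] * n_chim + ["rna"] * n_rna
    best_ids: list[str] = []  # RBH transcripts, reused as reverse-best decoys

    # track per-gene planted calls for representative selection
    for gi in range(spec.n_genes):
        gene = f"DN{gi}_c0_g1"
        n_iso = counts[gi]
        scen = scenarios[gi % len(scenarios)]
        planted: list[dict] = []  # per isoform: category, reason, bitscore, orf
        sid_main = new_subject(scen, gi)
        for iso in range(n_iso):
            tid = f"TRINITY_{gene}_i{iso + 1}"
            if special and iso == n_iso - 1 and n_iso > 1:
                kind = special.pop()
                if kind == "rna":
                    records.append(SequenceRecord(tid, _orfless_nt(rng), "nt"))
                    rna_ids.add(tid)
                    expr_rows[tid] = expressed_tpm()
                    planted.append(
                        dict(tid=tid, category="DISCARD", reason="structural_rna",
                             rank=99, bitscore=0.0, orf=0)
                    )
                else:  # chimeric: two subjects matched side by side, both covered
                    records.append(SequenceRecord(tid, _long_orf_nt(rng, 220), "nt"))
                    s1 = new_subject("chimA", gi)
                    s2 = new_subject("chimB", gi)
                    fwd.append(_tabrow(tid, s1, 150.0, (0, 300), (0, 200)))
                    fwd.append(_tabrow(tid, s2, 140.0, (350, 650), (0, 200)))
                    expr_rows[tid] = expressed_tpm()
                    planted.append(
                        dict(tid=tid, category="DISCARD", reason="chimeric",
                             rank=99, bitscore=150.0, orf=220)
                    )
                continue
            if scen == "best":
                records.append(SequenceRecord(tid, _long_orf_nt(rng, 150), "nt"))
                expr_rows[tid] = expressed_tpm()
                if iso == 0:
                    bits = 400.0
                    fwd.append(_tabrow(tid, sid_main, bits, (0, 450), (0, 150)))
                    rev.append(_tabrow(sid_main, tid, bits, (0, 150), (0, 450)))
                    best_ids.append(tid)
                    planted.append(dict(tid=tid, category="BEST", reason="rbh",
                                        rank=0, bitscore=bits, orf=150))
                else:
                    bits = 200.0 - iso
                    fwd.append(_tabrow(tid, sid_main, bits, (0, 450), (0, 150)))
                    planted.append(dict(tid=tid, category="GOOD",
                                        reason="coverage_expression",
                                        rank=2, bitscore=bits, orf=150))
            elif scen == "best2":
                records.append(SequenceRecord(tid, _long_orf_nt(rng, 150), "nt"))
                expr_rows[tid] = expressed_tpm()
                if iso == 0:
                    bits = 400.0
                    fwd.append(_tabrow(tid, sid_main, bits, (0, 450), (0, 150)))
                    rev.append(_tabrow(sid_main, tid, bits, (0, 150), (0, 450)))
                    planted.append(dict(tid=tid, category="BEST", reason="rbh",
                                        rank=0, bitscore=bits, orf=150))
                elif iso == 1:
                    # top query of a second database gene, but its own best
                    # subject is the sibling's RBH partner -> not reciprocal
                    s2 = new_subject("best2", gi, 1)
                    fwd.append(_tabrow(tid, sid_main, 300.0, (0, 450), (0, 150)))
                    fwd.append(_tabrow(tid, s2, 250.0, (0, 450), (0, 150)))
                    rev.append(_tabrow(s2, tid, 250.0, (0, 150), (0, 450)))
                    planted.append(dict(tid=tid, category="2BEST",
                                        reason="best_to_gene",
                                        rank=1, bitscore=300.0, orf=150))
                else:
                    bits = 100.0 - iso
                    fwd.append(_tabrow(tid, sid_main, bits, (0, 450), (0, 150)))
                    planted.append(dict(tid=tid, category="GOOD",
                                        reason="coverage_expression",
                                        rank=2, bitscore=bits, orf=150))
            elif scen == "good":
                # hit with ample coverage; reciprocity broken because the
                # database gene's reverse-best is an RBH transcript of an
                # earlier gene (whose own best subject lies elsewhere)
                records.append(SequenceRecord(tid, _long_orf_nt(rng, 150), "nt"))
                expr_rows[tid] = expressed_tpm()
                bits = 180.0 - iso
                if iso == 0 and best_ids:
                    rev.append(_tabrow(sid_main, best_ids[0], 500.0, (0, 200), (0, 450)))
                fwd.append(_tabrow(tid, sid_main, bits, (0, 450), (0, 200)))
                planted.append(dict(tid=tid, category="GOOD",
                                    reason="coverage_expression",
                                    rank=2, bitscore=bits, orf=150))
            elif scen == "longorf":
                n_aa = 60 + 30 * iso  # widely spaced so the actual longest
                # ORF (which can exceed the planted frame by a couple of
                # residues on another frame) preserves the planted ranking
                records.append(SequenceRecord(tid, _long_orf_nt(rng, n_aa), "nt"))
                expr_rows[tid] = expressed_tpm()
                planted.append(dict(tid=tid, category="LONGORF", reason="longorf",
                                    rank=3, bitscore=0.0, orf=n_aa))
            elif scen == "low_cov":
                records.append(SequenceRecord(tid, _long_orf_nt(rng, 80), "nt"))
                expr_rows[tid] = expressed_tpm()
                bits = 90.0 - iso
                fwd.append(_tabrow(tid, sid_main, bits, (0, 120), (0, 40)))  # cov 0.1
                planted.append(dict(tid=tid, category="DISCARD", reason="low_coverage",
                                    rank=99, bitscore=bits, orf=80))
            elif scen == "low_expr":
                records.append(SequenceRecord(tid, _long_orf_nt(rng, 80), "nt"))
                expr_rows[tid] = silent_tpm()
                bits = 90.0 - iso
                fwd.append(_tabrow(tid, sid_main, bits, (0, 450), (0, 200)))  # cov 0.5
                planted.append(dict(tid=tid, category="DISCARD", reason="low_expression",
                                    rank=99, bitscore=bits, orf=80))
            else:  # no_orf: no hits, no ORF >= 50 aa
                records.append(SequenceRecord(tid, _orfless_nt(rng), "nt"))
                expr_rows[tid] = expressed_tpm()
                planted.append(dict(tid=tid, category="DISCARD", reason="no_orf",
                                    rank=99, bitscore=0.0, orf=0))
        # representative selection among the planted non-discard isoforms
        keep = [p for p in planted if p["category"] != "DISCARD"]
        winner = None
        if keep:
            winner = min(keep, key=lambda p: (p["rank"], -p["bitscore"], -p["orf"], p["tid"]))
        for p in planted:
            cat, reason = p["category"], p["reason"]
            if winner is not None and cat != "DISCARD" and p["tid"] != winner["tid"]:
                cat, reason = "DISCARD", "not_representative"
            truth_rows.append(dict(transcript_id=p["tid"], category=cat, reason=reason))

    expression = pd.DataFrame.from_dict(expr_rows, orient="index", columns=libraries)
    expression.index.name = "transcript_id"
    truth = pd.DataFrame(truth_rows, columns=["transcript_id", "category", "reason"])
    return TranscriptomeFixture(
        records=records,
        forward_rows=fwd,
        reverse_rows=rev,
        subject_lengths=subject_lengths,
        expression=expression,
        rna_ids=rna_ids,
        truth=truth,
    )


def boundary_fixture(seed: int = 0) -> TranscriptomeFixture:
    """Six single-isoform transcripts planted exactly at the decision cutoffs.

    Coverage 0.19 / 0.21 around the 20% coverage cutoff, maximum TPM 0.9 / 1.1
    around the 1-TPM cutoff, and longest ORF 49 / 51 aa around the 50-aa
    cutoff; the truth table records the documented side of each boundary.
    """
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    fwd: list[str] = []
    subject_lengths: dict[str, int] = {}
    expr_rows: dict[str, np.ndarray] = {}
    truth_rows: list[dict] = []

    def add(tid: str, nt: str, tpm_max: float, category: str, reason: str,
            s_cov_len: int | None = None) -> None:
        records.append(SequenceRecord(tid, nt, "nt"))
        expr_rows[tid] = np.array([tpm_max, 0.1, 0.1, 0.1])
        if s_cov_len is not None:
            sid = f"db_{tid}"
            subject_lengths[sid] = 400
            fwd.append(_tabrow(tid, sid, 120.0, (0, 3 * s_cov_len), (0, s_cov_len)))
        truth_rows.append(dict(transcript_id=tid, category=category, reason=reason))

    add("DN900_c0_g1_i1", _long_orf_nt(rng, 100), 5.0, "DISCARD", "low_coverage",
        s_cov_len=76)   # coverage 76/400 = 0.19
    add("DN901_c0_g1_i1", _long_orf_nt(rng, 100), 5.0, "GOOD", "coverage_expression",
        s_cov_len=84)   # coverage 84/400 = 0.21
    add("DN902_c0_g1_i1", _long_orf_nt(rng, 100), 0.9, "DISCARD", "low_expression",
        s_cov_len=200)  # coverage 0.5, max TPM 0.9
    add("DN903_c0_g1_i1", _long_orf_nt(rng, 100), 1.1, "GOOD", "coverage_expression",
        s_cov_len=200)  # coverage 0.5, max TPM 1.1
    add("DN904_c0_g1_i1", _exact_orf_nt(rng, 49), 5.0,
        "DISCARD", "no_orf")   # longest ORF 49 aa, no hits
    add("DN905_c0_g1_i1", _exact_orf_nt(rng, 51), 5.0,
        "LONGORF", "longorf")  # longest ORF 51 aa, no hits

    expression = pd.DataFrame.from_dict(
        expr_rows, orient="index", columns=[f"lib{k + 1}" for k in range(4)]
    )
    expression.index.name = "transcript_id"
    truth = pd.DataFrame(truth_rows, columns=["transcript_id", "category", "reason"])
    return TranscriptomeFixture(
        records=records,
        forward_rows=fwd,
        reverse_rows=[],
        subject_lengths=subject_lengths,
        expression=expression,
        rna_ids=set(),
        truth=truth,
    )
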