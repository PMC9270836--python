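"""Sequence I/O, Trinity identifier decomposition, and open-reading-frame scanning.

All internal coordinates are 0-based half-open on the forward strand; 1-based
inclusive conventions (BLAST, GFF) are converted at I/O boundaries.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

NT_ALPHABET = set("ACGTUN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, stops as "*"; any codon containing a non-ACGT base is "X"
CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TABLE.update({c: "*" for c in _STANDARD.stop_codons})

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

Moltype = Literal["nt", "aa"]


@dataclass
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    residues: str
    moltype: Moltype = "aa"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TrinityId:
    """Decomposition of a Trinity-style identifier.

    ``TRINITY_DN1000_c1_g2_i3`` -> cluster ``DN1000_c1``, gene ``DN1000_c1_g2``,
    isoform ``i3``.  Non-conforming ids degrade to a singleton gene equal to the
    full id so that arbitrary FASTA still groups one-transcript-per-gene.
    """

    cluster: str
    gene: str
    isoform: str

    def format(self) -> str:
        if not self.isoform:
            return self.gene
        return f"{self.gene}_{self.isoform}"


_TRINITY_RE = re.compile(r"^(?:TRINITY_)?(DN\d+_c\d+)_(g\d+)_(i\d+)$")


def parse_trinity_id(identifier: str) -> TrinityId:
    """Split a Trinity transcript id into cluster / gene / isoform.

    The ``TRINITY_`` prefix is optional.  Unparsable ids fall back to a
    singleton gene (gene == full id, empty isoform); this is the contract, not
    an error.
    """
    m = _TRINITY_RE.match(identifier)
    if m is None:
        return TrinityId(cluster=identifier, gene=identifier, isoform="")
    cluster, gene_part, isoform = m.groups()
    return TrinityId(cluster=cluster, gene=f"{cluster}_{gene_part}", isoform=isoform)


@dataclass(frozen=True)
class OpenReadingFrame:
    """A stop-to-stop open segment in one of the six reading frames.

    ``nt_start``/``nt_end`` are forward-strand coordinates covering the coding
    codons plus the terminal stop codon when one is present.  ``aa_seq`` never
    contains the stop symbol.
    """

    frame: int  # one of +1,+2,+3,-1,-2,-3
    nt_start: int
    nt_end: int
    aa_seq: str

    @property
    def aa_len(self) -> int:
        return len(self.aa_seq)


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def translate(nt: str, frame: int = 1) -> str:
    """Translate one reading frame with the standard codon table.

    Stops render ``*``; the trailing partial codon is dropped; any codon
    containing ``N`` (or another non-ACGT symbol) renders ``X``.
    """
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError(f"invalid frame {frame}")
    seq = nt.upper().replace("U", "T")
    if frame < 0:
        seq = reverse_complement(seq)
    seq = seq[abs(frame) - 1 :]
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def find_orfs(rec: SequenceRecord | str, min_aa: int = 50) -> list[OpenReadingFrame]:
    """Six-frame stop-to-stop ORF scan.

    A start codon is *not* required: every maximal stop-free translated segment
    of length >= ``min_aa`` is reported, sorted by decreasing amino-acid length
    (ties broken by frame then forward-strand start).
    """
    nt = (rec.residues if isinstance(rec, SequenceRecord) else rec).upper().replace("U", "T")
    L = len(nt)
    if L < 3:
        return []
    orfs: list[OpenReadingFrame] = []
    for frame in (1, 2, 3, -1, -2, -3):
        aa = translate(nt, frame)
        off = abs(frame) - 1
        # segment boundaries in aa coordinates of this frame
        start = 0
        for pos, ch in enumerate(aa + "*"):
            if ch == "*":
                seg = aa[start:pos]
                if len(seg) >= min_aa:
                    has_stop = pos < len(aa)
                    n_codons = (pos - start) + (1 if has_stop else 0)
                    if frame > 0:
                        nt_start = off + 3 * start
                        nt_end = nt_start + 3 * n_codons
                    else:
                        # aa coordinates run along the reverse strand
                        rev_start = off + 3 * start
                        nt_end = L - rev_start
                        nt_start = nt_end - 3 * n_codons
                    orfs.append(OpenReadingFrame(frame, nt_start, nt_end, seg))
                start = pos + 1
    orfs.sort(key=lambda o: (-o.aa_len, o.frame, o.nt_start))
    return orfs


def _check_alphabet(rec: SequenceRecord) -> None:
    allowed = NT_ALPHABET if rec.moltype == "nt" else AA_ALPHABET | {"-"}
    for i, ch in enumerate(rec.residues):
        if ch not in allowed:
            raise ValueError(
                f"record {rec.id!r}: illegal {rec.moltype} residue {ch!r} at position {i}"
            )


def read_fasta(path: str | Path, moltype: Moltype = "aa") -> list[SequenceRecord]:
    """Read a (possibly line-wrapped, CR/LF) FASTA file.

    Residues are uppercased and validated against the declared alphabet;
    duplicate ids raise.  An empty file returns an empty list with a warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for sr in SeqIO.parse(str(path), "fasta"):
        if sr.id in seen:
            raise ValueError(f"duplicate sequence id {sr.id!r} in {path}")
        seen.add(sr.id)
        desc = sr.description[len(sr.id) :].strip() if sr.description.startswith(sr.id) else sr.description
        rec = SequenceRecord(id=sr.id, residues=str(sr.seq).upper(), moltype=moltype, description=desc)
        _check_alphabet(rec)
        records.append(rec)
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")
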