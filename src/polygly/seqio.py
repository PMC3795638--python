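"""Protein sequence and alignment I/O with a single coordinate convention.

Every module in :mod:`polygly` numbers residues 1-based and inclusive, so
that e.g. the phosphoacceptor threonine written Thr214 in the literature is
``residue_at(record, 214)``.  This module owns that convention: it reads and
writes FASTA sequences and precomputed multiple alignments (aligned FASTA or
Clustal), validates the amino-acid alphabet, and exposes the little
coordinate helpers everything else builds on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "STANDARD_AA",
    "ProteinRecord",
    "AlignmentBlock",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "residue_at",
]

#: The 20 standard one-letter amino-acid codes.  Ambiguity codes (B, Z, J, X)
#: and the rare translated residues (U, O) are rejected unless a record is
#: built with ``allow_extended=True``.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

GAP = "-"

_ALIGNMENT_DIALECTS = {"aligned-fasta": "fasta", "fasta": "fasta", "clustal": "clustal"}


def _validate_sequence(seq: str, record_id: str, allow_extended: bool) -> str:
    seq = seq.upper()
    if seq.endswith("*"):
        warnings.warn(f"stripping terminal stop '*' from record {record_id!r}")
        seq = seq.rstrip("*")
    if not seq:
        raise ValueError(f"record {record_id!r} has an empty sequence")
    if not allow_extended:
        for i, aa in enumerate(seq, start=1):
            if aa not in STANDARD_AA:
                raise ValueError(
                    f"record {record_id!r}: illegal residue {aa!r} at position {i}"
                )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence with 1-based residue numbering."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _validate_sequence(self.sequence, self.id, False)
        )

    @classmethod
    def unchecked(cls, id: str, sequence: str, description: str = "") -> "ProteinRecord":
        """Build a record without alphabet validation (uppercasing only)."""
        out = cls.__new__(cls)
        object.__setattr__(out, "id", id)
        object.__setattr__(out, "sequence", sequence.upper().rstrip("*"))
        object.__setattr__(out, "description", description)
        return out

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, n: int) -> str:
        """Residue letter at 1-based position *n*."""
        return residue_at(self, n)

    def subsequence(self, start: int, end: int) -> str:
        """Subsequence over the 1-based inclusive range [start, end]."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise IndexError(
                f"range [{start}, {end}] invalid for {self.id!r} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class AlignmentBlock:
    """Rows of equal-length gapped sequences; columns are numbered 1-based."""

    records: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment block must contain at least one row")
        lengths = {len(row) for _, row in self.records}
        if len(lengths) != 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def row(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(f"no row with id {rid!r}")

    def column(self, n: int) -> tuple[str, ...]:
        """Residues (and gaps) in 1-based column *n*."""
        if not (1 <= n <= self.length):
            raise IndexError(f"column {n} out of range 1..{self.length}")
        return tuple(s[n - 1] for _, s in self.records)

    def degap(self) -> list[ProteinRecord]:
        """Drop gaps from every row, returning validated protein records."""
        return [
            ProteinRecord(id=rid, sequence=s.replace(GAP, "")) for rid, s in self.records
        ]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)


def read_fasta(path: str | Path, allow_extended: bool = False) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are uppercased, internal line breaks joined, and residues
    validated against the 20-letter alphabet (``allow_extended`` passes
    B/Z/J/U/O/X through unvalidated).  An empty file is an error.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _validate_sequence(str(rec.seq), rec.id, allow_extended)
        if allow_extended:
            records.append(ProteinRecord.unchecked(rec.id, seq, rec.description))
        else:
            records.append(
                ProteinRecord(id=rec.id, sequence=seq, description=rec.description)
            )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(seqrecords, str(Path(path)), "fasta")


def read_alignment(path: str | Path, dialect: str = "aligned-fasta") -> AlignmentBlock:
    """Read a precomputed multiple alignment.

    ``dialect`` is ``"aligned-fasta"`` or ``"clustal"``.  Clustal conservation
    lines (asterisks/colons) are ignored.  Rows of unequal length are an
    error.
    """
    fmt = _ALIGNMENT_DIALECTS.get(dialect)
    if fmt is None:
        raise ValueError(
            f"unknown alignment dialect {dialect!r}; "
            f"expected one of {sorted(set(_ALIGNMENT_DIALECTS))}"
        )
    try:
        aln = AlignIO.read(str(Path(path)), fmt)
    except ValueError as exc:
        raise ValueError(f"failed to parse {path} as {dialect}: {exc}") from exc
    return AlignmentBlock(
        records=tuple((rec.id, str(rec.seq).upper()) for rec in aln)
    )


def residue_at(record: ProteinRecord, n: int) -> str:
    """Amino-acid letter at 1-based position *n* of *record*."""
    if not (1 <= n <= len(record.sequence)):
        raise IndexError(
            f"position {n} out of range 1..{len(record.sequence)} for {record.id!r}"
        )
    return record.sequence[n - 1]
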