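"""In-silico trypsin digestion producing coordinate-carrying peptides.

Trypsin cleaves C-terminal to lysine or arginine, but is suppressed when the
next residue is proline ("trypsin strict").  Peptides keep their 1-based
inclusive coordinates on the parent protein so that a product can be written
the way mass-spectrometry results are reported, e.g. residues 202-219 of a
parent carrying one internal missed cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .masscalc import mh_plus, neutral_mass
from .seqio import ProteinRecord

__all__ = ["Peptide", "digest", "peptide_by_coords", "cut_sites", "digest_table"]


@dataclass(frozen=True)
class Peptide:
    """A digestion product with parent coordinates (1-based inclusive)."""

    parent_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    tryptic: bool = True
    c_terminal: bool = False

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def neutral_mass(self) -> float:
        return neutral_mass(self.sequence)

    @property
    def mh_plus(self) -> float:
        return mh_plus(self.sequence)


def cut_sites(sequence: str) -> list[int]:
    """Positions *i* (1-based) after which trypsin cuts: K/R not before P."""
    sites = []
    for i in range(1, len(sequence)):  # no cut after the final residue
        if sequence[i - 1] in "KR" and sequence[i] != "P":
            sites.append(i)
    return sites


def _count_missed(sequence: str, parent: str, start: int, end: int) -> int:
    # internal K/R (not before P) strictly before the peptide's last residue
    n = 0
    for i in range(start, end):  # parent positions start..end-1
        if parent[i - 1] in "KR" and (i == len(parent) or parent[i] != "P"):
            n += 1
    return n


def digest(
    record: ProteinRecord,
    max_missed: int = 2,
    min_len: int = 1,
    max_len: int | None = None,
) -> list[Peptide]:
    """All tryptic peptides of *record* with up to *max_missed* missed
    cleavages and length within [min_len, max_len], sorted by (start, end)."""
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if min_len < 1 or (max_len is not None and max_len < min_len):
        raise ValueError(f"invalid length bounds [{min_len}, {max_len}]")
    seq = record.sequence
    if not seq:
        raise ValueError(f"record {record.id!r} has an empty sequence")

    boundaries = [0] + cut_sites(seq) + [len(seq)]
    peptides = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 1 + max_missed + 1, len(boundaries))):
            start, end = boundaries[i] + 1, boundaries[j]
            length = end - start + 1
            if length < min_len or (max_len is not None and length > max_len):
                continue
            peptides.append(
                Peptide(
                    parent_id=record.id,
                    start=start,
                    end=end,
                    sequence=seq[start - 1 : end],
                    missed_cleavages=j - i - 1,
                    tryptic=True,
                    c_terminal=(end == len(seq)),
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def peptide_by_coords(record: ProteinRecord, start: int, end: int) -> Peptide:
    """The subsequence [start, end] as a Peptide, tryptic or not.

    The ``tryptic`` flag records whether both termini are genuine tryptic
    boundaries (protein terminus or a K/R-not-P cut); ``missed_cleavages``
    counts internal uncleaved sites either way.
    """
    seq = record.sequence
    if not (1 <= start <= end <= len(seq)):
        raise IndexError(
            f"range [{start}, {end}] invalid for {record.id!r} of length {len(seq)}"
        )
    cuts = set(cut_sites(seq))
    n_term_ok = start == 1 or (start - 1) in cuts
    c_term_ok = end == len(seq) or end in cuts
    return Peptide(
        parent_id=record.id,
        start=start,
        end=end,
        sequence=seq[start - 1 : end],
        missed_cleavages=_count_missed(seq, seq, start, end),
        tryptic=n_term_ok and c_term_ok,
        c_terminal=(end == len(seq)),
    )


def digest_table(record: ProteinRecord, **kwargs) -> pd.DataFrame:
    """Digest and tabulate with monoisotopic masses (TSV-ready)."""
    rows = [
        {
            "parent_id": p.parent_id,
            "start": p.start,
            "end": p.end,
            "sequence": p.sequence,
            "missed_cleavages": p.missed_cleavages,
            "neutral_mass": round(p.neutral_mass, 5),
            "mh_plus": round(p.mh_plus, 5),
        }
        for p in digest(record, **kwargs)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "parent_id",
            "start",
            "end",
            "sequence",
            "missed_cleavages",
            "neutral_mass",
            "mh_plus",
        ],
    )
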