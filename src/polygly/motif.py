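"""Scanner for the polyglycylation signature motif.

Polyglycylation sites on tubulins and on Giardia 14-3-3 sit in an acidic
C-terminal context summarized by the discrete pattern

    [T/G] X{0,1} [D/E] X{1,3} G [D/E] X{1,2} E{2,4}

where X is a polar or negatively charged residue and the terminal glutamate
run carries the candidate glycylation sites.  Element lengths are variable,
so a single start position can admit several expansions; the scanner
explores all of them with backtracking and reports one canonical match per
start (fewest class violations, then longest, then earlier elements as long
as possible).

A bounded *fuzzy* mode admits matches in which up to ``max_violations``
residues fall outside their element's class, recording which residues
violated what.  This exists because naturally occurring sites drift from
the consensus: the pattern as written is strict enough to miss some
experimentally verified glycylation contexts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .seqio import STANDARD_AA, ProteinRecord

__all__ = [
    "DEFAULT_X_ALPHABET",
    "SignaturePattern",
    "MotifMatch",
    "Violation",
    "compile_pattern",
    "scan",
]

#: Default interpretation of X = "polar or negatively charged":
#: the polar-uncharged residues plus Asp/Glu.
DEFAULT_X_ALPHABET = frozenset("STNQCYDE")

_ELEMENT_NAMES = (
    "anchor",      # [T/G]
    "x1",          # X{0,1}
    "acidic1",     # [D/E]
    "x2",          # X{1,3}
    "glycine",     # G
    "acidic2",     # [D/E]
    "x3",          # X{1,2}
    "glu_run",     # E{2,4}  -- candidate glycylation sites
)


@dataclass(frozen=True)
class Violation:
    element: str
    position: int  # 1-based position in the scanned sequence
    residue: str


@dataclass(frozen=True)
class MotifMatch:
    """One signature-motif match with its per-element residue assignment."""

    record_id: str
    start: int  # 1-based inclusive
    end: int
    matched: str
    element_spans: tuple[tuple[str, int, int], ...]  # (name, start, end); empty: end<start
    glycyl_sites: tuple[int, ...]  # positions of the terminal glutamate run
    violations: tuple[Violation, ...] = ()

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class SignaturePattern:
    """Compiled signature pattern: (name, allowed residues, min, max) elements."""

    elements: tuple[tuple[str, frozenset[str], int, int], ...]
    max_violations: int = 0

    @property
    def min_length(self) -> int:
        return sum(lo for _, _, lo, _ in self.elements)

    @property
    def max_length(self) -> int:
        return sum(hi for _, _, _, hi in self.elements)


def compile_pattern(
    x_alphabet: Sequence[str] | frozenset[str] = DEFAULT_X_ALPHABET,
    strictness: str | int = "strict",
) -> SignaturePattern:
    """Compile the signature pattern for a given X alphabet and strictness.

    ``strictness`` is ``"strict"`` (no violations) or an integer >= 0, the
    maximum number of residue-level class violations a match may carry
    (``0`` is equivalent to strict).
    """
    x = frozenset(str(a).upper() for a in x_alphabet)
    if not x:
        raise ValueError("x_alphabet must be non-empty")
    bad = x - STANDARD_AA
    if bad:
        raise ValueError(f"x_alphabet contains non-standard letters: {sorted(bad)}")
    if strictness == "strict":
        max_violations = 0
    elif isinstance(strictness, int) and not isinstance(strictness, bool):
        if strictness < 0:
            raise ValueError("max_violations must be >= 0")
        max_violations = strictness
    else:
        raise ValueError(f"invalid strictness {strictness!r}")
    de = frozenset("DE")
    elements = (
        ("anchor", frozenset("TG"), 1, 1),
        ("x1", x, 0, 1),
        ("acidic1", de, 1, 1),
        ("x2", x, 1, 3),
        ("glycine", frozenset("G"), 1, 1),
        ("acidic2", de, 1, 1),
        ("x3", x, 1, 2),
        ("glu_run", frozenset("E"), 2, 4),
    )
    return SignaturePattern(elements=elements, max_violations=max_violations)


def _match_from(
    seq: str,
    start0: int,  # 0-based start in seq
    pattern: SignaturePattern,
) -> tuple[tuple[int, ...], list[Violation]] | None:
    """Best assignment of element lengths at one start position, or None.

    Preference order: fewest violations, then longest total match, then
    lexicographically longest element lengths (earlier elements greedy).
    Implemented as depth-first backtracking over per-element lengths, longest
    first, with violation-budget pruning.
    """
    elements = pattern.elements
    budget = pattern.max_violations
    best: list[tuple[tuple[int, int, tuple[int, ...]], list[Violation]]] = []

    def recurse(pos: int, elem_i: int, lengths: tuple[int, ...], viol: list[Violation]):
        if elem_i == len(elements):
            # rank key minimized: (violations, -total length, negated lengths)
            best.append(((len(viol), -(pos - start0), tuple(-l for l in lengths)), viol))
            return
        name, allowed, lo, hi = elements[elem_i]
        for length in range(hi, lo - 1, -1):
            if pos + length > len(seq):
                continue
            new_viol = list(viol)
            ok = True
            for k in range(length):
                aa = seq[pos + k]
                if aa not in allowed:
                    new_viol.append(Violation(name, pos + k + 1, aa))
                    if len(new_viol) > budget:
                        ok = False
                        break
            if ok:
                recurse(pos + length, elem_i + 1, lengths + (length,), new_viol)

    recurse(start0, 0, (), [])
    if not best:
        return None
    best.sort(key=lambda item: item[0])
    key, viol = best[0]
    lengths = tuple(-l for l in key[2])
    return lengths, viol


def scan(record: ProteinRecord | str, pattern: SignaturePattern) -> list[MotifMatch]:
    """All signature-motif matches in *record*, left to right.

    Overlapping matches at different start positions are all reported; at
    each start the canonical expansion is returned (see
    :func:`_match_from`).  Each match lists the positions of its terminal
    glutamate run — the candidate glycylation sites.
    """
    if isinstance(record, str):
        record = ProteinRecord(id="query", sequence=record)
    seq = record.sequence
    matches = []
    for start0 in range(len(seq) - pattern.min_length + 1):
        hit = _match_from(seq, start0, pattern)
        if hit is None:
            continue
        lengths, viol = hit
        spans = []
        pos = start0 + 1
        for (name, _, _, _), length in zip(pattern.elements, lengths):
            spans.append((name, pos, pos + length - 1))
            pos += length
        end = pos - 1
        glu_span = spans[-1]
        matches.append(
            MotifMatch(
                record_id=record.id,
                start=start0 + 1,
                end=end,
                matched=seq[start0:end],
                element_spans=tuple(spans),
                glycyl_sites=tuple(range(glu_span[1], glu_span[2] + 1)),
                violations=tuple(viol),
            )
        )
    return matches


def matches_table(matches: Sequence[MotifMatch]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "record_id": m.record_id,
                "start": m.start,
                "end": m.end,
                "matched": m.matched,
                "glycyl_sites": ",".join(map(str, m.glycyl_sites)),
                "n_violations": len(m.violations),
                "violations": ";".join(
                    f"{v.element}:{v.position}{v.residue}" for v in m.violations
                ),
            }
            for m in matches
        ],
        columns=[
            "record_id",
            "start",
            "end",
            "matched",
            "glycyl_sites",
            "n_violations",
            "violations",
        ],
    )
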