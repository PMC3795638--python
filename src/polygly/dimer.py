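"""Salt-bridge based dimerization-compatibility scoring for 14-3-3 proteins.

14-3-3 dimers are held together by a small number of N-terminal salt
bridges between an acidic (Asp/Glu) and a basic (Lys/Arg) residue of the
two monomers.  When the corresponding positions in another family member
carry different residues, a bridge may be lost (neutral) or even become a
like-charge repulsion.  Classifying each reference bridge position pair on
a candidate dimer and counting intact minus repulsive pairs gives a crude
but informative compatibility score, enough to rank which homo- and
heterodimers are electrostatically favoured.

Classification is purely residue-identity based; no geometry is modelled.
A packaged table (``data/bridges.tsv``) carries the residue pairs at the
homologous bridge positions of human 14-3-3zeta, Drosophila LeoII and
14-3-3epsilon, and Giardia 14-3-3, for the homodimers and the two
Giardia/Drosophila heterodimers.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .seqio import STANDARD_AA, ProteinRecord, residue_at

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "Bridge",
    "BridgeCall",
    "DimerReport",
    "classify_pair",
    "score_bridges",
    "score_dimer",
    "rank_partners",
    "load_bridge_table",
    "reference_bridges",
]

#: Default charge sets at physiological pH; histidine is excluded from the
#: positive set (mostly uncharged at pH 7.4) but both sets are parameters.
POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")

INTACT = "intact"
NEUTRAL = "neutral"
REPULSIVE = "repulsive"


def classify_pair(
    res_a: str,
    res_b: str,
    positive: frozenset[str] = POSITIVE,
    negative: frozenset[str] = NEGATIVE,
) -> str:
    """Classify a residue pair: ``intact`` when one is basic and the other
    acidic, ``repulsive`` when both sit in the same charged set, ``neutral``
    otherwise."""
    a, b = res_a.upper(), res_b.upper()
    for r in (a, b):
        if r not in STANDARD_AA:
            raise ValueError(f"invalid residue letter {r!r}")
    if (a in positive and b in negative) or (a in negative and b in positive):
        return INTACT
    if (a in positive and b in positive) or (a in negative and b in negative):
        return REPULSIVE
    return NEUTRAL


@dataclass(frozen=True)
class Bridge:
    """One interface residue pair (chain A residue vs chain B residue)."""

    label: str
    res_a: str
    pos_a: int
    res_b: str
    pos_b: int
    chain_a: str = "A"
    chain_b: str = "B"


@dataclass(frozen=True)
class BridgeCall:
    bridge: Bridge
    classification: str


@dataclass(frozen=True)
class DimerReport:
    """Per-bridge classification for one partner pair, with the aggregate
    compatibility score = intact count - repulsive count."""

    partner_a: str
    partner_b: str
    calls: tuple[BridgeCall, ...]
    unresolved: tuple[str, ...] = ()  # bridge labels that mapped onto a gap

    @property
    def n_intact(self) -> int:
        return sum(c.classification == INTACT for c in self.calls)

    @property
    def n_neutral(self) -> int:
        return sum(c.classification == NEUTRAL for c in self.calls)

    @property
    def n_repulsive(self) -> int:
        return sum(c.classification == REPULSIVE for c in self.calls)

    @property
    def score(self) -> int:
        return self.n_intact - self.n_repulsive

    def to_dict(self) -> dict:
        return {
            "partner_a": self.partner_a,
            "partner_b": self.partner_b,
            "score": self.score,
            "intact": self.n_intact,
            "neutral": self.n_neutral,
            "repulsive": self.n_repulsive,
            "bridges": [
                {
                    "label": c.bridge.label,
                    "res_a": c.bridge.res_a,
                    "pos_a": c.bridge.pos_a,
                    "res_b": c.bridge.res_b,
                    "pos_b": c.bridge.pos_b,
                    "class": c.classification,
                }
                for c in self.calls
            ],
            "unresolved": list(self.unresolved),
        }


def score_bridges(
    partner_a: str,
    partner_b: str,
    bridges: Iterable[Bridge],
    positive: frozenset[str] = POSITIVE,
    negative: frozenset[str] = NEGATIVE,
) -> DimerReport:
    """Classify an explicit bridge list into a DimerReport."""
    calls = tuple(
        BridgeCall(b, classify_pair(b.res_a, b.res_b, positive, negative))
        for b in bridges
    )
    return DimerReport(partner_a=partner_a, partner_b=partner_b, calls=calls)


def score_dimer(
    partner_a: ProteinRecord,
    partner_b: ProteinRecord,
    reference_bridges: Sequence[Bridge],
    map_a: Callable[[int], int | None],
    map_b: Callable[[int], int | None],
    positive: frozenset[str] = POSITIVE,
    negative: frozenset[str] = NEGATIVE,
) -> DimerReport:
    """Carry reference bridge positions onto two partners and classify them.

    ``map_a``/``map_b`` translate a reference-sequence position into a
    position on the respective partner (returning ``None`` for positions
    aligned to a gap; such bridges are reported unresolved and excluded from
    the counts, with a warning).
    """
    calls = []
    unresolved = []
    for bridge in reference_bridges:
        pa, pb = map_a(bridge.pos_a), map_b(bridge.pos_b)
        if pa is None or pb is None:
            warnings.warn(
                f"bridge {bridge.label!r} unresolvable on "
                f"{partner_a.id}/{partner_b.id} (position maps to a gap)"
            )
            unresolved.append(bridge.label)
            continue
        ra, rb = residue_at(partner_a, pa), residue_at(partner_b, pb)
        mapped = Bridge(
            label=bridge.label,
            res_a=ra,
            pos_a=pa,
            res_b=rb,
            pos_b=pb,
            chain_a=partner_a.id,
            chain_b=partner_b.id,
        )
        calls.append(BridgeCall(mapped, classify_pair(ra, rb, positive, negative)))
    return DimerReport(
        partner_a=partner_a.id,
        partner_b=partner_b.id,
        calls=tuple(calls),
        unresolved=tuple(unresolved),
    )


def rank_partners(
    subject: str,
    candidates: Mapping[str, Sequence[Bridge]],
    positive: frozenset[str] = POSITIVE,
    negative: frozenset[str] = NEGATIVE,
) -> list[DimerReport]:
    """Rank candidate partners of *subject* by compatibility score.

    Ties are broken by intact count (descending) and then partner id."""
    if not candidates:
        raise ValueError("need at least one candidate")
    reports = [
        score_bridges(subject, partner, bridges, positive, negative)
        for partner, bridges in candidates.items()
    ]
    reports.sort(key=lambda r: (-r.score, -r.n_intact, r.partner_b))
    return reports


def load_bridge_table(path: str | Path) -> dict[tuple[str, str], list[Bridge]]:
    """Read a bridge table TSV keyed by (partner_a, partner_b).

    Columns: pair_id, partner_a, partner_b, label, res_a, pos_a, res_b,
    pos_b[, note]."""
    table: dict[tuple[str, str], list[Bridge]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = (row["partner_a"], row["partner_b"])
            table.setdefault(key, []).append(
                Bridge(
                    label=row["label"],
                    res_a=row["res_a"],
                    pos_a=int(row["pos_a"]),
                    res_b=row["res_b"],
                    pos_b=int(row["pos_b"]),
                    chain_a=row["partner_a"],
                    chain_b=row["partner_b"],
                )
            )
    if not table:
        raise ValueError(f"no bridges found in {path}")
    return table


def reference_bridges() -> dict[tuple[str, str], list[Bridge]]:
    """The packaged reference table of 14-3-3 interface residue pairs."""
    ref = resources.files("polygly").joinpath("data/bridges.tsv")
    with resources.as_file(ref) as path:
        return load_bridge_table(path)
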