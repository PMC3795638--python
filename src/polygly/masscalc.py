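"""Monoisotopic mass arithmetic for tryptic peptides and their PTM variants.

MALDI reflector instruments report singly protonated monoisotopic masses
(MH+), so the arithmetic here is deliberately minimal: residue masses are
summed, water is added for the intact peptide, one proton for the observed
ion, and modification deltas on top.  Two modifications are modelled, the
two that matter for 14-3-3 proteins in Giardia:

* phosphorylation, +79.96633 Da on Ser/Thr/Tyr, at most one event per site;
* polyglycylation, +57.02146 Da per glycine appended to a glutamate side
  chain, so a chain of n glycines shifts the peptide by exactly
  n x 57.02146 Da and a modified peptide appears as a peak ladder with a
  57-Da rung spacing.

Average masses and charge states beyond +1 are out of scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "MONOISOTOPIC",
    "WATER",
    "PROTON",
    "GLYCINE",
    "PHOSPHO_DELTA",
    "Modification",
    "PHOSPHO",
    "GLYCYL",
    "ModSite",
    "ModVariant",
    "ModSpace",
    "neutral_mass",
    "mh_plus",
    "enumerate_variants",
]

#: Monoisotopic residue masses in Da (the mass each amino acid contributes
#: inside a peptide chain, i.e. the free amino acid minus water).
MONOISOTOPIC: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER = 18.010565
PROTON = 1.007276
GLYCINE = 57.02146
PHOSPHO_DELTA = 79.96633


@dataclass(frozen=True)
class Modification:
    """A named mass modification restricted to a set of target residues.

    ``max_per_site`` is the largest multiplicity a single site may carry
    (``None`` = unbounded, as for a polyglycine chain).
    """

    name: str
    delta: float
    targets: frozenset[str]
    max_per_site: int | None = 1

    def total_delta(self, multiplicity: int) -> float:
        if multiplicity < 0:
            raise ValueError(f"negative multiplicity {multiplicity}")
        if self.max_per_site is not None and multiplicity > self.max_per_site:
            raise ValueError(
                f"{self.name} multiplicity {multiplicity} exceeds "
                f"max {self.max_per_site} per site"
            )
        return self.delta * multiplicity


PHOSPHO = Modification("phospho", PHOSPHO_DELTA, frozenset("STY"), max_per_site=1)
GLYCYL = Modification("glycyl", GLYCINE, frozenset("E"), max_per_site=None)


@dataclass(frozen=True, order=True)
class ModSite:
    """One modified site: 1-based position within the peptide + multiplicity."""

    position: int
    modification: Modification = field(compare=False)
    multiplicity: int = 1


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty peptide sequence")
    sequence = sequence.upper()
    for i, aa in enumerate(sequence, start=1):
        if aa not in MONOISOTOPIC:
            raise ValueError(f"invalid residue {aa!r} at position {i}")
    return sequence


def _check_mods(sequence: str, mods: Iterable[ModSite]) -> tuple[ModSite, ...]:
    checked = []
    for site in mods:
        if not (1 <= site.position <= len(sequence)):
            raise ValueError(
                f"modification site {site.position} outside peptide 1..{len(sequence)}"
            )
        aa = sequence[site.position - 1]
        if aa not in site.modification.targets:
            raise ValueError(
                f"{site.modification.name} not permitted on {aa!r} "
                f"at peptide position {site.position} "
                f"(targets: {''.join(sorted(site.modification.targets))})"
            )
        site.modification.total_delta(site.multiplicity)  # validates multiplicity
        checked.append(site)
    return tuple(sorted(checked))


def neutral_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of a peptide: residue masses + water."""
    sequence = _check_sequence(sequence)
    return sum(MONOISOTOPIC[aa] for aa in sequence) + WATER


def mh_plus(sequence: str, mods: Iterable[ModSite] = ()) -> float:
    """Singly protonated monoisotopic mass, with optional modifications.

    Raises ``ValueError`` if a modification site is not one of its permitted
    target residues.
    """
    sequence = _check_sequence(sequence)
    mods = _check_mods(sequence, mods)
    delta = sum(m.modification.total_delta(m.multiplicity) for m in mods)
    return neutral_mass(sequence) + delta + PROTON


@dataclass(frozen=True)
class ModVariant:
    """A peptide together with a concrete assignment of modifications."""

    sequence: str
    mods: tuple[ModSite, ...] = ()

    def __post_init__(self) -> None:
        seq = _check_sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "mods", _check_mods(seq, self.mods))

    @property
    def neutral(self) -> float:
        delta = sum(m.modification.total_delta(m.multiplicity) for m in self.mods)
        return neutral_mass(self.sequence) + delta

    @property
    def mh_plus(self) -> float:
        return self.neutral + PROTON

    @property
    def n_glycines(self) -> int:
        return sum(m.multiplicity for m in self.mods if m.modification.name == "glycyl")

    @property
    def n_phospho(self) -> int:
        return sum(m.multiplicity for m in self.mods if m.modification.name == "phospho")

    def label(self) -> str:
        if not self.mods:
            return self.sequence
        parts = [
            f"{m.modification.name}x{m.multiplicity}@{m.position}" for m in self.mods
        ]
        return f"{self.sequence}[{'+'.join(parts)}]"


@dataclass(frozen=True)
class ModSpace:
    """The combinatorial space of modifications to enumerate over a peptide.

    ``phospho_sites`` / ``glycyl_sites``: explicit 1-based positions, or
    ``"auto"`` to use every permitted target residue in the peptide, or
    ``None`` to disable the modification.  ``glycyl_range`` bounds the chain
    length (inclusive); by default at most one glutamate carries the chain,
    mirroring single-site polyglycylation, unless ``allow_multi_glycyl``.
    """

    phospho_sites: Sequence[int] | str | None = "auto"
    glycyl_sites: Sequence[int] | str | None = "auto"
    glycyl_range: tuple[int, int] = (0, 30)
    allow_multi_glycyl: bool = False

    def resolve_sites(self, sequence: str, which: str) -> list[int]:
        spec = self.phospho_sites if which == "phospho" else self.glycyl_sites
        mod = PHOSPHO if which == "phospho" else GLYCYL
        if spec is None:
            return []
        if spec == "auto":
            return [i for i, aa in enumerate(sequence, start=1) if aa in mod.targets]
        return sorted(int(p) for p in spec)


def enumerate_variants(peptide: str, space: ModSpace = ModSpace()) -> list[ModVariant]:
    """All modification variants of *peptide* under *space*, sorted by MH+.

    Every subset of phospho sites is combined with every admissible
    polyglycine placement; variants identical in (site, multiplicity)
    content are deduplicated (e.g. a zero-length chain on different
    glutamates is the one unmodified variant).
    """
    peptide = _check_sequence(peptide)
    lo, hi = space.glycyl_range
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid glycyl multiplicity range [{lo}, {hi}]")

    phospho_sites = space.resolve_sites(peptide, "phospho")
    glycyl_sites = space.resolve_sites(peptide, "glycyl")

    glycyl_choices: list[tuple[ModSite, ...]]
    if not glycyl_sites:
        glycyl_choices = [()]
    elif space.allow_multi_glycyl:
        per_site = [
            [None] + [ModSite(p, GLYCYL, n) for n in range(max(lo, 1), hi + 1)]
            for p in glycyl_sites
        ]
        glycyl_choices = [
            tuple(s for s in combo if s is not None)
            for combo in itertools.product(*per_site)
        ]
        if lo > 0:
            glycyl_choices = [c for c in glycyl_choices if c]
    else:
        glycyl_choices = []
        if lo == 0:
            glycyl_choices.append(())
        for p in glycyl_sites:
            for n in range(max(lo, 1), hi + 1):
                glycyl_choices.append((ModSite(p, GLYCYL, n),))

    seen: dict[tuple, ModVariant] = {}
    for k in range(len(phospho_sites) + 1):
        for psubset in itertools.combinations(phospho_sites, k):
            pmods = tuple(ModSite(p, PHOSPHO, 1) for p in psubset)
            for gmods in glycyl_choices:
                variant = ModVariant(peptide, pmods + gmods)
                key = tuple(
                    (m.position, m.modification.name, m.multiplicity)
                    for m in variant.mods
                )
                seen.setdefault(key, variant)
    return sorted(seen.values(), key=lambda v: (v.mh_plus, v.label()))
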