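"""Synthetic proteins and MALDI peak lists with ground truth.

Every generator is fully deterministic under its seed and returns the data
together with the planted truth, so detection code is always evaluated
against (data, truth) pairs rather than against generator internals.

Spectra emulate centroided MALDI reflector peak lists: one singly
protonated monoisotopic peak per declared peptide variant, perturbed by a
small Gaussian calibration jitter (default sd 0.02 Da, well inside the
0.1 Da matching tolerance), plus uniformly placed decoy peaks.  Decoys are
excluded from a +/- 2 x 0.1 Da neighbourhood of every position of the
declared ladder comb so that sensitivity (recovering planted rungs) and
specificity (ignoring unrelated peaks) remain separately measurable; a
*hostile* mode instead parks decoys at half-rung offsets to stress
tie-breaking.  No isotopic envelopes or detector-noise physics are
modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .masscalc import GLYCINE, GLYCYL, ModSite, ModVariant
from .motif import DEFAULT_X_ALPHABET, compile_pattern
from .seqio import ProteinRecord
from .spectra import DEFAULT_TOLERANCE, DEFAULT_WINDOW, PeakList

__all__ = [
    "ProteinConfig",
    "SpectrumConfig",
    "gen_protein",
    "gen_spectrum",
    "ladder_variants",
    "write_truth",
]

#: Background residues that cannot participate in the signature pattern
#: (no T/G/D/E anchor residues and outside the default X alphabet), so a
#: background-only sequence is guaranteed motif-free.
MOTIF_FREE_ALPHABET = "AVLIMFWKRHP"


@dataclass(frozen=True)
class ProteinConfig:
    """Parameters for synthetic protein generation."""

    seed: int
    length: int = 60
    n_motifs: int = 1
    x_alphabet: frozenset[str] = DEFAULT_X_ALPHABET
    background_alphabet: str = MOTIF_FREE_ALPHABET


def _sample_motif_instance(rng: np.random.Generator, x_alphabet: frozenset[str]) -> str:
    """One concrete expansion of the signature pattern.

    X positions are drawn from the polar-uncharged subset of the X alphabet
    (no D/E/T/G), so the planted instance cannot seed a second overlapping
    match.
    """
    safe_x = sorted(set(x_alphabet) - set("DETG")) or sorted(x_alphabet)
    pattern = compile_pattern(x_alphabet)
    parts = []
    for name, allowed, lo, hi in pattern.elements:
        length = int(rng.integers(lo, hi + 1))
        pool = safe_x if name in ("x1", "x2", "x3") else sorted(allowed)
        parts.append("".join(rng.choice(pool) for _ in range(length)))
    return "".join(parts)


def gen_protein(config: ProteinConfig) -> tuple[ProteinRecord, list[tuple[int, int]]]:
    """A random protein with planted signature motifs and their true spans.

    The background alphabet excludes all pattern-critical residues, so the
    only matches a scanner should find are the planted ones.
    """
    rng = np.random.default_rng(config.seed)
    background = list(config.background_alphabet)
    seq = [str(rng.choice(background)) for _ in range(config.length)]
    spans: list[tuple[int, int]] = []
    for _ in range(config.n_motifs):
        instance = _sample_motif_instance(rng, config.x_alphabet)
        if len(instance) > config.length:
            raise ValueError(
                f"motif of length {len(instance)} does not fit protein "
                f"of length {config.length}"
            )
        # place without overlapping previously planted spans
        for _attempt in range(1000):
            start0 = int(rng.integers(0, config.length - len(instance) + 1))
            span = (start0 + 1, start0 + len(instance))
            if all(span[1] < s or span[0] > e for s, e in spans):
                break
        else:
            raise ValueError("could not place motif without overlap")
        seq[start0 : start0 + len(instance)] = list(instance)
        spans.append(span)
    record = ProteinRecord(
        id=f"synthetic_{config.seed}", sequence="".join(seq),
        description="synthetic protein with planted polyglycylation motifs",
    )
    return record, sorted(spans)


def ladder_variants(
    peptide: str, site: int, multiplicities: Sequence[int]
) -> list[ModVariant]:
    """Polyglycylated variants of *peptide* at glutamate *site* (1-based),
    one per chain length in *multiplicities* (0 = unmodified)."""
    variants = []
    for n in multiplicities:
        mods = () if n == 0 else (ModSite(site, GLYCYL, n),)
        variants.append(ModVariant(peptide, mods))
    return variants


@dataclass(frozen=True)
class SpectrumConfig:
    """Parameters for synthetic peak-list generation."""

    seed: int
    variants: tuple[ModVariant, ...]
    jitter_sd: float = 0.02
    n_decoys: int = 0
    window: tuple[float, float] = DEFAULT_WINDOW
    decoy_exclusion: float = 2 * DEFAULT_TOLERANCE
    #: exclude decoys around base + n*step for n = 0..comb_n_max, where base
    #: is the lightest declared variant's MH+ (protects ladder calling from
    #: spurious rungs above the planted ones)
    comb_n_max: int = 30
    comb_step: float = GLYCINE
    hostile: bool = False
    intensity_mean: float = 4.0  # lognormal parameters, arbitrary units
    intensity_sigma: float = 0.5


def gen_spectrum(config: SpectrumConfig) -> tuple[PeakList, dict]:
    """A synthetic peak list for the declared variants, plus ground truth.

    True peaks sit at each variant's MH+ plus Gaussian jitter; decoys are
    uniform over the acquisition window outside the exclusion comb (or at
    half-rung offsets in hostile mode).  Raises when a declared variant
    falls outside the window.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.window
    true_mhs = [v.mh_plus for v in config.variants]
    for v, mh in zip(config.variants, true_mhs):
        if not (lo <= mh <= hi):
            raise ValueError(
                f"variant {v.label()} MH+ {mh:.3f} outside window [{lo}, {hi}]"
            )

    pairs: list[tuple[float, float]] = []
    observed = []
    for mh in true_mhs:
        mz = mh + rng.normal(0.0, config.jitter_sd)
        inten = float(rng.lognormal(config.intensity_mean, config.intensity_sigma))
        pairs.append((mz, inten))
        observed.append(mz)

    comb: list[float] = []
    if true_mhs:
        base = min(true_mhs)
        comb = [base + n * config.comb_step for n in range(config.comb_n_max + 1)]

    decoys = []
    n_placed = 0
    while n_placed < config.n_decoys:
        if config.hostile and comb:
            n = int(rng.integers(0, config.comb_n_max))
            mz = min(true_mhs) + (n + 0.5) * config.comb_step
            if not (lo <= mz <= hi):
                continue
        else:
            mz = float(rng.uniform(lo, hi))
            if any(abs(mz - c) <= config.decoy_exclusion for c in comb):
                continue
        inten = float(rng.lognormal(config.intensity_mean, config.intensity_sigma))
        pairs.append((mz, inten))
        decoys.append(mz)
        n_placed += 1

    peaks = PeakList.from_pairs(pairs, source=f"synthetic seed={config.seed}",
                                window=config.window)
    truth = {
        "seed": config.seed,
        "variants": [v.label() for v in config.variants],
        "true_mh": true_mhs,
        "observed_mz": observed,
        "n_glycines": [v.n_glycines for v in config.variants],
        "decoys": decoys,
    }
    return peaks, truth


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))
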