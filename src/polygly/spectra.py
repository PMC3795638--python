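"""Peak-list handling, theoretical-mass matching, and PTM-shift detection.

Inputs are centroided MALDI reflector peak lists (singly protonated ions in
a 750-4000 Da acquisition window).  Three questions are answered here:

* which predicted peptide variants are present, within a mass tolerance
  (:func:`match_variants`);
* does a peptide show the +79.96633 Da phosphorylation shift, including the
  "exclusively phosphorylated" case where the unmodified peak is absent
  (:func:`detect_phospho_pair`);
* does a peptide carry a polyglycine ladder — a series of peaks spaced
  57.02146 Da apart above its MH+ (:func:`call_ladder`).

Intensity is carried but ignored by default: published assignments of this
kind rest on peak presence/absence, not abundance.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .masscalc import GLYCINE, PHOSPHO_DELTA, ModVariant

__all__ = [
    "DEFAULT_WINDOW",
    "DEFAULT_TOLERANCE",
    "PeakList",
    "MatchResult",
    "PhosphoCall",
    "LadderCall",
    "read_peaks",
    "match_variants",
    "detect_phospho_pair",
    "call_ladder",
]

DEFAULT_WINDOW = (750.0, 4000.0)
DEFAULT_TOLERANCE = 0.1
_MERGE_EPS = 1e-6


@dataclass(frozen=True)
class PeakList:
    """Ordered (m/z, intensity) pairs with acquisition metadata.

    Construction normalizes: peaks are sorted by m/z, duplicates within
    1e-6 Da merged (intensities summed), and every m/z must fall inside the
    acquisition ``window`` (pass ``window=None`` to disable the check).
    """

    mz: np.ndarray
    intensity: np.ndarray
    source: str = ""
    window: tuple[float, float] | None = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(inten < 0):
            raise ValueError("negative intensity")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if mz.size:
            keep_mz, keep_int = [mz[0]], [inten[0]]
            for m, h in zip(mz[1:], inten[1:]):
                if m - keep_mz[-1] <= _MERGE_EPS:
                    keep_int[-1] += h
                else:
                    keep_mz.append(m)
                    keep_int.append(h)
            mz, inten = np.array(keep_mz), np.array(keep_int)
        if self.window is not None and mz.size:
            lo, hi = self.window
            if mz[0] < lo or mz[-1] > hi:
                bad = mz[(mz < lo) | (mz > hi)][0]
                raise ValueError(
                    f"peak at m/z {bad:.4f} outside acquisition window [{lo}, {hi}]"
                )
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[float, float]],
        source: str = "",
        window: tuple[float, float] | None = DEFAULT_WINDOW,
    ) -> "PeakList":
        pairs = list(pairs)
        mz = np.array([p[0] for p in pairs], dtype=float)
        inten = np.array([p[1] for p in pairs], dtype=float)
        return cls(mz=mz, intensity=inten, source=source, window=window)

    def __len__(self) -> int:
        return int(self.mz.size)

    def nearest(self, target: float) -> tuple[float, float] | None:
        """(m/z, |error|) of the peak nearest *target*, or None if empty."""
        if not len(self):
            return None
        i = int(np.searchsorted(self.mz, target))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(self):
                err = abs(self.mz[j] - target)
                if best is None or err < best[1]:
                    best = (float(self.mz[j]), err)
        return best

    def has_peak(self, target: float, tolerance: float) -> float | None:
        """m/z of the nearest peak within *tolerance* of *target*, else None."""
        hit = self.nearest(target)
        if hit is not None and hit[1] <= tolerance:
            return hit[0]
        return None

    def min_intensity_filter(self, threshold: float) -> "PeakList":
        keep = self.intensity >= threshold
        return replace(self, mz=self.mz[keep], intensity=self.intensity[keep])


def _read_delimited(path: Path, delimiter: str) -> list[tuple[float, float]]:
    pairs = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            row = [c.strip() for c in row if c.strip()]
            if not row:
                continue
            try:
                mz = float(row[0])
            except ValueError:
                if lineno == 1:  # optional header
                    continue
                raise ValueError(
                    f"{path}:{lineno}: non-numeric m/z {row[0]!r}"
                ) from None
            inten = 1.0
            if len(row) > 1:
                try:
                    inten = float(row[1])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric intensity {row[1]!r}"
                    ) from None
            if inten < 0:
                raise ValueError(f"{path}:{lineno}: negative intensity {inten}")
            pairs.append((mz, inten))
    return pairs


def read_peaks(
    path: str | Path,
    dialect: str = "tsv",
    window: tuple[float, float] | None = DEFAULT_WINDOW,
) -> PeakList:
    """Read a peak list from TSV/CSV (mz, intensity columns; header optional)
    or MGF.  Output is sorted and deduplicated."""
    path = Path(path)
    if dialect in ("tsv", "csv"):
        pairs = _read_delimited(path, "\t" if dialect == "tsv" else ",")
    elif dialect == "mgf":
        pairs = []
        with _mgf.read(str(path)) as reader:
            for block in reader:
                pairs.extend(
                    zip(
                        block["m/z array"].tolist(),
                        block["intensity array"].tolist(),
                    )
                )
    else:
        raise ValueError(f"unknown peak-list dialect {dialect!r}")
    return PeakList.from_pairs(pairs, source=str(path), window=window)


@dataclass(frozen=True)
class MatchResult:
    """A predicted variant matched (or not) against the observed peaks."""

    variant: ModVariant
    matched_mz: float | None
    mass_error: float | None  # observed - theoretical MH+
    ambiguous: bool = False

    @property
    def present(self) -> bool:
        return self.matched_mz is not None


def match_variants(
    peaks: PeakList,
    variants: Sequence[ModVariant],
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[MatchResult]:
    """Match each variant to its nearest peak within *tolerance*.

    One peak may satisfy several variants; such matches are flagged
    ``ambiguous``.  Variants with no peak within tolerance are reported
    absent rather than dropped.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not variants:
        raise ValueError("empty variant list")
    raw = []
    for v in variants:
        target = v.mh_plus
        hit = peaks.has_peak(target, tolerance)
        raw.append((v, hit))
    peak_use: dict[float, int] = {}
    for _, hit in raw:
        if hit is not None:
            peak_use[hit] = peak_use.get(hit, 0) + 1
    return [
        MatchResult(
            variant=v,
            matched_mz=hit,
            mass_error=None if hit is None else hit - v.mh_plus,
            ambiguous=hit is not None and peak_use[hit] > 1,
        )
        for v, hit in raw
    ]


@dataclass(frozen=True)
class PhosphoCall:
    """Outcome of looking for the +80 Da phosphorylation shift."""

    detected: bool
    exclusive: bool  # phospho peak present while the unmodified peak is absent
    base_mz: float | None
    phospho_mz: float | None


def detect_phospho_pair(
    peaks: PeakList, base_mh: float, tolerance: float = DEFAULT_TOLERANCE
) -> PhosphoCall:
    """Detect phosphorylation of a peptide with unmodified MH+ *base_mh*.

    Positive when both the unmodified and the +79.96633 Da peak are present,
    or when only the shifted peak is present (the peptide observed
    exclusively in phosphorylated form, flagged ``exclusive``).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    base = peaks.has_peak(base_mh, tolerance)
    shifted = peaks.has_peak(base_mh + PHOSPHO_DELTA, tolerance)
    detected = shifted is not None
    return PhosphoCall(
        detected=detected,
        exclusive=detected and base is None,
        base_mz=base,
        phospho_mz=shifted,
    )


@dataclass(frozen=True)
class LadderCall:
    """A called polyglycine ladder anchored at a peptide's unmodified MH+."""

    base_mh: float
    rungs: tuple[int, ...]  # glycine multiplicities with an observed peak
    rung_mz: tuple[float, ...]
    gaps: tuple[int, ...]  # multiplicities <= k_max without a peak
    step: float = GLYCINE

    @property
    def k_max(self) -> int:
        return max(self.rungs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "base_mh": self.base_mh,
                "step": self.step,
                "k_max": self.k_max,
                "rungs": list(self.rungs),
                "rung_mz": [round(m, 5) for m in self.rung_mz],
                "gaps": list(self.gaps),
            }
        )


def call_ladder(
    peaks: PeakList,
    base_mh: float,
    tolerance: float = DEFAULT_TOLERANCE,
    max_gap: int = 1,
    min_rungs: int = 3,
    n_max: int = 30,
    step: float = GLYCINE,
) -> LadderCall | None:
    """Call a modification ladder: peaks near ``base_mh + n*step``.

    The ladder is anchored at the unmodified MH+ even when that rung is
    absent (a fully modified peptide shows no n=0 peak): extension starts at
    the smallest observed rung and proceeds upward, tolerating up to
    *max_gap* consecutive missing rungs.  Rungs below the anchor are
    reported in ``gaps``.  Returns ``None`` unless at least *min_rungs*
    rungs are observed.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if max_gap < 0 or min_rungs < 2 or n_max < 1:
        raise ValueError("require max_gap >= 0, min_rungs >= 2, n_max >= 1")
    present: dict[int, float] = {}
    for n in range(n_max + 1):
        hit = peaks.has_peak(base_mh + n * step, tolerance)
        if hit is not None:
            present[n] = hit
    if not present:
        return None
    anchor = min(present)
    rungs = [anchor]
    gap_run = 0
    for n in range(anchor + 1, n_max + 1):
        if n in present:
            rungs.append(n)
            gap_run = 0
        else:
            gap_run += 1
            if gap_run > max_gap:
                break
    if len(rungs) < min_rungs:
        return None
    k_max = rungs[-1]
    rung_set = set(rungs)
    return LadderCall(
        base_mh=base_mh,
        rungs=tuple(rungs),
        rung_mz=tuple(present[n] for n in rungs),
        gaps=tuple(n for n in range(k_max + 1) if n not in rung_set),
        step=step,
    )


def matches_table(results: Sequence[MatchResult]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "variant": r.variant.label(),
                "theoretical_mh": round(r.variant.mh_plus, 5),
                "matched_mz": None if r.matched_mz is None else round(r.matched_mz, 5),
                "mass_error": None if r.mass_error is None else round(r.mass_error, 5),
                "present": r.present,
                "ambiguous": r.ambiguous,
            }
            for r in results
        ]
    )
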