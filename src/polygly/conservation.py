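"""Pairwise global alignment statistics and alignment-column conservation.

Percent identity and similarity between 14-3-3 family members are computed
from an optimal end-to-end (Needleman-Wunsch) alignment under affine gap
penalties; *similarity* additionally counts substitutions with a positive
substitution-matrix score.  Multiple-alignment columns are classified into
the conservation classes used in family alignment figures (invariant /
conserved in at least k rows / divergent), and aligned positions can be
mapped across sequences to carry residue annotations (e.g. salt-bridge
positions) from one family member onto another.

Alignment itself is delegated to Bio.Align.PairwiseAligner; this module owns
the parameter presets, the statistics conventions, and the coordinate
bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import GAP, AlignmentBlock, ProteinRecord

__all__ = [
    "PRESETS",
    "PairwiseAlignment",
    "global_align",
    "identity_similarity",
    "classify_columns",
    "map_position",
]

#: Named parameter presets: (matrix, gap_open, gap_extend).  "blosum" is the
#: default; "gonnet" approximates classic ClustalW pairwise parameters.
PRESETS: dict[str, tuple[str, float, float]] = {
    "blosum": ("BLOSUM62", 10.0, 0.5),
    "gonnet": ("GONNET1992", 10.0, 0.2),
}


@lru_cache(maxsize=None)
def _load_matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except FileNotFoundError:
        raise ValueError(
            f"unknown substitution matrix {name!r}; "
            f"available: {substitution_matrices.load()}"
        ) from None


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment with its scoring parameters.

    ``a_gapped``/``b_gapped`` are equal-length rows over residues and '-'.
    """

    a_id: str
    b_id: str
    a_gapped: str
    b_gapped: str
    score: float
    matrix_name: str
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        if len(self.a_gapped) != len(self.b_gapped):
            raise ValueError("gapped rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.a_gapped)

    @property
    def identity(self) -> float:
        return identity_similarity(self)[0]

    @property
    def similarity(self) -> float:
        return identity_similarity(self)[1]

    def swapped(self) -> "PairwiseAlignment":
        return PairwiseAlignment(
            a_id=self.b_id,
            b_id=self.a_id,
            a_gapped=self.b_gapped,
            b_gapped=self.a_gapped,
            score=self.score,
            matrix_name=self.matrix_name,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )


def _as_record(x: ProteinRecord | str, default_id: str) -> ProteinRecord:
    if isinstance(x, ProteinRecord):
        return x
    return ProteinRecord(id=default_id, sequence=x)


def global_align(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    preset: str | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment of *a* and *b* under affine gap penalties.

    A gap of length L is penalized ``gap_open + (L - 1) * gap_extend``.
    ``preset`` ("blosum" or "gonnet") overrides the three parameters.  The
    aligner's first reported optimum is returned, which is deterministic for
    fixed inputs and parameters.
    """
    if preset is not None:
        try:
            matrix, gap_open, gap_extend = PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            ) from None
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    rec_a, rec_b = _as_record(a, "a"), _as_record(b, "b")
    if not rec_a.sequence or not rec_b.sequence:
        raise ValueError("cannot align empty sequences")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _load_matrix(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    result = aligner.align(rec_a.sequence, rec_b.sequence)
    best = result[0]
    a_gapped, b_gapped = best[0], best[1]
    return PairwiseAlignment(
        a_id=rec_a.id,
        b_id=rec_b.id,
        a_gapped=str(a_gapped),
        b_gapped=str(b_gapped),
        score=float(best.score),
        matrix_name=matrix,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def identity_similarity(
    alignment: PairwiseAlignment, denominator: str = "alignment"
) -> tuple[float, float]:
    """(identity %, similarity %) of a pairwise alignment, rounded to 1 dp.

    Identity counts identical residue columns; similarity additionally
    counts substitutions whose matrix score is positive.  The denominator is
    the full alignment length by default, or the shorter input sequence
    (``denominator="shorter"``).
    """
    if denominator not in ("alignment", "shorter"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    mat = _load_matrix(alignment.matrix_name)
    ident = positive = 0
    for x, y in zip(alignment.a_gapped, alignment.b_gapped):
        if x == GAP or y == GAP:
            continue
        if x == y:
            ident += 1
        elif mat[x, y] > 0:
            positive += 1
    if denominator == "alignment":
        denom = alignment.length
    else:
        denom = min(
            len(alignment.a_gapped.replace(GAP, "")),
            len(alignment.b_gapped.replace(GAP, "")),
        )
    if denom == 0:
        return (0.0, 0.0)
    return (
        round(100.0 * ident / denom, 1),
        round(100.0 * (ident + positive) / denom, 1),
    )


def classify_columns(block: AlignmentBlock, k: int = 2) -> list[str]:
    """Per-column conservation class for a multiple alignment.

    ``invariant``: all rows carry the same residue (no gaps);
    ``conserved_k``: some residue occurs in at least *k* rows;
    ``divergent`` otherwise.
    """
    if block.n_rows < 2:
        raise ValueError("need an alignment with at least 2 rows")
    if k < 2:
        raise ValueError("k must be >= 2")
    classes = []
    for col in range(1, block.length + 1):
        residues = [c for c in block.column(col) if c != GAP]
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        if len(residues) == block.n_rows and len(counts) == 1:
            classes.append("invariant")
        elif counts and max(counts.values()) >= k:
            classes.append(f"conserved_{k}")
        else:
            classes.append("divergent")
    return classes


def map_position(
    alignment: PairwiseAlignment, position: int, source: str = "a"
) -> int | None:
    """Map a 1-based residue position across a pairwise alignment.

    Returns the aligned 1-based position in the other sequence, or ``None``
    when the residue is aligned to a gap.
    """
    if source not in ("a", "b"):
        raise ValueError("source must be 'a' or 'b'")
    src = alignment.a_gapped if source == "a" else alignment.b_gapped
    dst = alignment.b_gapped if source == "a" else alignment.a_gapped
    n_src = len(src.replace(GAP, ""))
    if not (1 <= position <= n_src):
        raise IndexError(f"position {position} out of range 1..{n_src}")
    seen = 0
    for col, c in enumerate(src):
        if c != GAP:
            seen += 1
            if seen == position:
                if dst[col] == GAP:
                    return None
                return len(dst[: col + 1].replace(GAP, ""))
    raise AssertionError("unreachable")
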