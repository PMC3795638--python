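"""Independent oracles used by the test suite.

These deliberately take different algorithmic routes from the package:
exhaustive enumeration for the motif scanner, a 3-state affine-gap DP for
alignment scores, and closed-form counting for variant enumeration.
"""

from __future__ import annotations

import itertools

# ---------------------------------------------------------------- motif ----

ELEMENTS = (
    ("anchor", "TG", 1, 1),
    ("x1", "X", 0, 1),
    ("acidic1", "DE", 1, 1),
    ("x2", "X", 1, 3),
    ("glycine", "G", 1, 1),
    ("acidic2", "DE", 1, 1),
    ("x3", "X", 1, 2),
    ("glu_run", "E", 2, 4),
)

LENGTH_COMBOS = list(
    itertools.product(*[range(lo, hi + 1) for _, _, lo, hi in ELEMENTS])
)


def oracle_scan(
    seq: str, x_alphabet: frozenset[str], max_violations: int = 0
) -> list[tuple[int, int, tuple[int, ...], int]]:
    """All canonical matches by exhaustive expansion of every element-length
    combination at every offset.

    Returns (start, end, element lengths, n_violations) tuples, 1-based
    inclusive, one per matching start position, selected by fewest
    violations, then longest match, then lexicographically longest element
    lengths.
    """
    classes = {"X": set(x_alphabet)}
    for _, cls, _, _ in ELEMENTS:
        if cls != "X":
            classes[cls] = set(cls)
    # prefix[c][i] = members of class c among seq[:i]
    prefix = {
        c: [0] * (len(seq) + 1) for c in classes
    }
    for c, members in classes.items():
        acc = prefix[c]
        for i, aa in enumerate(seq):
            acc[i + 1] = acc[i] + (aa in members)

    results = []
    for start in range(len(seq)):
        candidates = []
        for lengths in LENGTH_COMBOS:
            end = start + sum(lengths)
            if end > len(seq):
                continue
            pos = start
            viol = 0
            for (name, cls, _, _), length in zip(ELEMENTS, lengths):
                acc = prefix[cls]
                viol += length - (acc[pos + length] - acc[pos])
                pos += length
            if viol <= max_violations:
                candidates.append((viol, -(end - start), tuple(-l for l in lengths)))
        if candidates:
            viol, neg_total, neg_lengths = min(candidates)
            lengths = tuple(-l for l in neg_lengths)
            results.append((start + 1, start + sum(lengths), lengths, viol))
    return results


# ------------------------------------------------------------ alignment ----

def gotoh_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap alignment score by the standard 3-state DP.

    Gap of length L costs gap_open + (L-1)*gap_extend.  Independent of the
    package's aligner (which delegates to biopython).
    """
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0:
                X[i][j] = max(
                    M[i - 1][j] - gap_open,
                    X[i - 1][j] - gap_extend,
                    Y[i - 1][j] - gap_open,
                )
            if j > 0:
                Y[i][j] = max(
                    M[i][j - 1] - gap_open,
                    X[i][j - 1] - gap_open,
                    Y[i][j - 1] - gap_extend,
                )
            if i > 0 and j > 0:
                s = matrix[a[i - 1], b[j - 1]]
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
    return max(M[n][m], X[n][m], Y[n][m])


# ------------------------------------------------------------- variants ----

def variant_count(n_phospho_sites: int, n_glycyl_sites: int,
                  glycyl_lo: int, glycyl_hi: int) -> int:
    """Closed-form count of modification variants (single-chain glycylation):
    phospho subsets x (one unmodified choice if lo==0, plus one chain per
    site and per admissible length >= max(lo, 1))."""
    chain_lengths = max(0, glycyl_hi - max(glycyl_lo, 1) + 1)
    glycyl_options = (1 if glycyl_lo == 0 else 0) + n_glycyl_sites * chain_lengths
    if n_glycyl_sites == 0:
        glycyl_options = 1
    return (2 ** n_phospho_sites) * glycyl_options
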