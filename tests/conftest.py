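"""Shared fixtures: peptides printed in MALDI figure legends, tiny FASTA
writers, and random-sequence helpers."""

from __future__ import annotations

import random
from pathlib import Path

import pytest

from polygly.seqio import ProteinRecord

# Tryptic peptides of the three 14-3-3 proteins as reported alongside the
# MALDI spectra (parent coordinates in the comments), with the printed
# observed masses.  DNLNLWVTDSAGDDNAEEK's printed 2104.92 is the neutral
# monoisotopic mass; all others are MH+.
PRINTED_MASSES = [
    # (sequence, n_phospho, printed value, value kind)
    ("AFDAAITDLDKLTEESYK", 1, 2109.96, "mh"),      # g14-3-3 202-219, pThr214
    ("DNLNLWVTDSAGDDNAEEK", 0, 2104.92, "neutral"),  # g14-3-3 230-248
    ("AAFDDAIAELDTLSEESYK", 0, 2087.9, "mh"),      # D14-3-3e 197-216
    ("AAFDDAIAELDTLSEESYK", 1, 2167.9, "mh"),
    ("EQIQDVEDQDVS", 0, 1404.6, "mh"),             # D14-3-3e 249-260
    ("EQIQDVEDQDVS", 1, 1484.6, "mh"),             # pSer260
    ("QAFDDAIAELDTLNEDSYK", 0, 2157.98, "mh"),     # LeoII 197-215
    ("DNLTLWTSDTQGDEAEPQEGGDN", 0, 2492.03, "mh"),  # LeoII 226-248
]

LEOII_CTERM_PEPTIDE = "DNLTLWTSDTQGDEAEPQEGGDN"

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def write_fasta_file(tmp_path: Path):
    def _write(records: dict[str, str], name: str = "input.fasta") -> Path:
        path = tmp_path / name
        path.write_text(
            "".join(f">{rid}\n{seq}\n" for rid, seq in records.items())
        )
        return path

    return _write


@pytest.fixture
def write_text(tmp_path: Path):
    def _write(content: str, name: str) -> Path:
        path = tmp_path / name
        path.write_text(content)
        return path

    return _write


def random_protein(rng: random.Random, min_len: int = 1, max_len: int = 50) -> str:
    n = rng.randint(min_len, max_len)
    return "".join(rng.choice(AA20) for _ in range(n))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20130)
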