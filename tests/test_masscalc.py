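"""Monoisotopic mass arithmetic and modification-variant enumeration."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pt_mass

from conftest import PRINTED_MASSES
from oracles import variant_count
from polygly.masscalc import (
    GLYCINE,
    GLYCYL,
    MONOISOTOPIC,
    PHOSPHO,
    PROTON,
    WATER,
    ModSite,
    ModSpace,
    ModVariant,
    enumerate_variants,
    mh_plus,
    neutral_mass,
)

peptide_seq = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30)


class TestResidueTable:
    def test_leucine_isoleucine_isobaric(self):
        assert MONOISOTOPIC["I"] == MONOISOTOPIC["L"]

    def test_glycine_neutral_mass(self):
        assert neutral_mass("G") == pytest.approx(75.03203, abs=1e-5)

    @settings(max_examples=50, derandomize=True)
    @given(seq=peptide_seq)
    def test_agrees_with_pyteomics(self, seq):
        # independent elemental-composition computation of the same quantity
        assert neutral_mass(seq) == pytest.approx(
            pt_mass.calculate_mass(sequence=seq), abs=1e-4
        )


class TestNeutralMassAndMhPlus:
    def test_composition_invariance(self):
        assert neutral_mass("AG") == neutral_mass("GA")

    def test_invalid_residue(self):
        with pytest.raises(ValueError, match="invalid residue"):
            neutral_mass("AXB")

    def test_empty_sequence(self):
        with pytest.raises(ValueError):
            neutral_mass("")

    @pytest.mark.parametrize("seq,n_phospho,printed,kind", PRINTED_MASSES)
    def test_printed_masses_within_tenth_dalton(self, seq, n_phospho, printed, kind):
        """Every peptide mass printed alongside the MALDI spectra is
        reproduced within the 0.1 Da reporting precision."""
        mods = ()
        if n_phospho:
            site = max(i for i, aa in enumerate(seq, 1) if aa in "STY")
            mods = (ModSite(site, PHOSPHO),)
        value = (
            mh_plus(seq, mods)
            if kind == "mh"
            else neutral_mass(seq) + n_phospho * PHOSPHO.delta
        )
        assert value == pytest.approx(printed, abs=0.1)

    def test_phospho_on_thr13_of_202_219(self):
        assert mh_plus(
            "AFDAAITDLDKLTEESYK", [ModSite(13, PHOSPHO)]
        ) == pytest.approx(2109.96, abs=0.1)

    def test_mh_minus_neutral_is_one_proton(self):
        v = ModVariant("AEK", (ModSite(2, GLYCYL, 3),))
        assert v.mh_plus - v.neutral == pytest.approx(PROTON, abs=1e-9)

    def test_mod_on_forbidden_residue(self):
        with pytest.raises(ValueError, match="not permitted"):
            mh_plus("AAK", [ModSite(1, PHOSPHO)])
        with pytest.raises(ValueError, match="not permitted"):
            mh_plus("ASK", [ModSite(2, GLYCYL, 2)])

    def test_second_phospho_on_same_site_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            mh_plus("ASK", [ModSite(2, PHOSPHO, 2)])

    @settings(max_examples=50, derandomize=True)
    @given(a=peptide_seq, b=peptide_seq)
    def test_concatenation_additivity(self, a, b):
        assert neutral_mass(a + b) == pytest.approx(
            neutral_mass(a) + neutral_mass(b) - WATER, abs=1e-9
        )


class TestEnumerateVariants:
    def test_glycyl_ladder_on_single_glutamate(self):
        variants = enumerate_variants(
            "AEK", ModSpace(phospho_sites=None, glycyl_range=(0, 2))
        )
        masses = [v.mh_plus for v in variants]
        assert len(variants) == 3
        assert masses[1] - masses[0] == pytest.approx(GLYCINE, abs=1e-9)
        assert masses[2] - masses[0] == pytest.approx(2 * GLYCINE, abs=1e-9)

    def test_no_target_residues_single_unmodified_variant(self):
        variants = enumerate_variants("AVLK", ModSpace())
        assert len(variants) == 1
        assert variants[0].mods == ()

    def test_cterm_phosphopeptide_249_260(self):
        variants = enumerate_variants(
            "EQIQDVEDQDVS", ModSpace(glycyl_range=(0, 0))
        )
        phospho_terminal = [
            v
            for v in variants
            if v.n_phospho == 1 and v.mods[0].position == 12
        ]
        assert phospho_terminal
        assert phospho_terminal[0].mh_plus == pytest.approx(1484.6, abs=0.1)

    def test_sorted_by_mh(self):
        variants = enumerate_variants("SEK", ModSpace(glycyl_range=(0, 3)))
        masses = [v.mh_plus for v in variants]
        assert masses == sorted(masses)

    def test_empty_multiplicity_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            enumerate_variants("AEK", ModSpace(glycyl_range=(3, 1)))
        with pytest.raises(ValueError, match="range"):
            enumerate_variants("AEK", ModSpace(glycyl_range=(-1, 2)))

    @pytest.mark.parametrize(
        "peptide,glycyl_range",
        [("STYEEK", (0, 4)), ("AEK", (0, 2)), ("SSEEK", (1, 3)), ("TK", (0, 5))],
    )
    def test_count_matches_closed_form(self, peptide, glycyl_range):
        n_p = sum(aa in "STY" for aa in peptide)
        n_g = sum(aa == "E" for aa in peptide)
        variants = enumerate_variants(peptide, ModSpace(glycyl_range=glycyl_range))
        assert len(variants) == variant_count(n_p, n_g, *glycyl_range)

    def test_glycyl_step_monotone(self):
        variants = enumerate_variants(
            "AEK", ModSpace(phospho_sites=None, glycyl_range=(0, 10))
        )
        masses = [v.mh_plus for v in variants]
        steps = [b - a for a, b in zip(masses, masses[1:])]
        assert all(s == pytest.approx(GLYCINE, abs=1e-9) for s in steps)
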