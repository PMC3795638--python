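"""Peak lists, variant matching, phospho-shift detection, ladder calling."""

import numpy as np
import pytest

from polygly.masscalc import GLYCINE, PHOSPHO, ModSite, ModVariant, mh_plus
from polygly.spectra import (
    PeakList,
    call_ladder,
    detect_phospho_pair,
    match_variants,
    read_peaks,
)


def peaklist(*mzs, window=(750.0, 4000.0)):
    return PeakList.from_pairs([(m, 100.0) for m in mzs], window=window)


class TestPeakList:
    def test_sorted_and_deduplicated(self):
        pl = PeakList.from_pairs([(1500.0, 5.0), (900.0, 1.0), (1500.0, 2.0)])
        assert list(pl.mz) == [900.0, 1500.0]
        assert list(pl.intensity) == [1.0, 7.0]  # merged intensities summed

    def test_window_enforced(self):
        with pytest.raises(ValueError, match="window"):
            peaklist(500.0)
        assert len(peaklist(500.0, window=None)) == 1

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            PeakList.from_pairs([(900.0, -1.0)])

    def test_min_intensity_filter(self):
        pl = PeakList.from_pairs([(900.0, 1.0), (901.0, 10.0)])
        assert list(pl.min_intensity_filter(5.0).mz) == [901.0]


class TestReadPeaks:
    def test_tsv_single_peak(self, write_text):
        pl = read_peaks(write_text("1404.61\t100\n", "p.tsv"), "tsv")
        assert len(pl) == 1
        assert pl.mz[0] == pytest.approx(1404.61)

    def test_header_and_csv(self, write_text):
        pl = read_peaks(write_text("mz,intensity\n900.5,3\n800.1,2\n", "p.csv"), "csv")
        assert list(pl.mz) == [800.1, 900.5]  # normalized to sorted order

    def test_mgf(self, write_text):
        content = (
            "BEGIN IONS\nTITLE=synthetic\nPEPMASS=1000\n"
            "900.1 10\n1200.2 5\n850.0 2\nEND IONS\n"
        )
        pl = read_peaks(write_text(content, "p.mgf"), "mgf")
        assert list(pl.mz) == [850.0, 900.1, 1200.2]

    def test_non_numeric_mz_reports_line(self, write_text):
        with pytest.raises(ValueError, match=":2:"):
            read_peaks(write_text("900.0\t1\nxyz\t1\n", "bad.tsv"), "tsv")

    def test_unknown_dialect(self, write_text):
        with pytest.raises(ValueError, match="dialect"):
            read_peaks(write_text("900\t1\n", "p.tsv"), "xml")


class TestMatchVariants:
    PEPTIDE = "AAFDDAIAELDTLSEESYK"

    def variants(self):
        return [
            ModVariant(self.PEPTIDE),
            ModVariant(self.PEPTIDE, (ModSite(14, PHOSPHO),)),
        ]

    def test_phospho_pair_both_matched(self):
        peaks = peaklist(2087.96, 2167.93)
        results = match_variants(peaks, self.variants(), tolerance=0.1)
        assert all(r.present for r in results)
        gap = results[1].matched_mz - results[0].matched_mz
        assert gap == pytest.approx(79.97, abs=0.01)

    def test_empty_peaklist_all_absent(self):
        results = match_variants(peaklist(), self.variants(), tolerance=0.1)
        assert all(not r.present for r in results)

    def test_tolerance_boundary(self):
        target = ModVariant(self.PEPTIDE).mh_plus
        results = match_variants(
            peaklist(target + 0.25), [ModVariant(self.PEPTIDE)], tolerance=0.1
        )
        assert not results[0].present

    def test_shared_peak_flagged_ambiguous(self):
        # two isobaric variants (phospho on either serine) hit the same peak
        variants = [
            ModVariant(self.PEPTIDE, (ModSite(14, PHOSPHO),)),
            ModVariant(self.PEPTIDE, (ModSite(17, PHOSPHO),)),
        ]
        results = match_variants(peaklist(variants[0].mh_plus), variants, 0.1)
        assert all(r.present and r.ambiguous for r in results)

    def test_empty_variant_list_error(self):
        with pytest.raises(ValueError):
            match_variants(peaklist(900.0), [], 0.1)

    def test_match_monotone_in_tolerance(self):
        base = ModVariant(self.PEPTIDE)
        offsets = [0.01, 0.05, 0.09, 0.15, 0.3]
        peaks = peaklist(*[base.mh_plus + o for o in offsets])
        counts = []
        for tol in (0.3, 0.15, 0.09, 0.05, 0.01):
            res = match_variants(peaks, [base], tol)
            counts.append(sum(r.present for r in res))
        assert counts == sorted(counts, reverse=True)


class TestDetectPhosphoPair:
    def test_exclusively_phosphorylated(self):
        base = mh_plus("AFDAAITDLDKLTEESYK")  # ~2030.0, absent from the peaks
        call = detect_phospho_pair(peaklist(2109.96), base, tolerance=0.1)
        assert call.detected and call.exclusive
        assert call.base_mz is None

    def test_pair_detected(self):
        call = detect_phospho_pair(peaklist(1404.61, 1484.58), 1404.61, 0.1)
        assert call.detected and not call.exclusive
        assert call.phospho_mz == pytest.approx(1484.58)

    def test_no_phospho(self):
        call = detect_phospho_pair(peaklist(1404.61, 1450.00), 1404.61, 0.1)
        assert not call.detected


class TestCallLadder:
    BASE = 2105.93  # MH+ of the fully glycylatable 19-mer

    def ladder_peaks(self, rungs, jitter=0.0, extra=()):
        rng = np.random.default_rng(7)
        mzs = [
            self.BASE + n * GLYCINE + (rng.uniform(-jitter, jitter) if jitter else 0.0)
            for n in rungs
        ]
        return peaklist(*(list(mzs) + list(extra)))

    def test_full_ladder_to_24(self):
        call = call_ladder(self.ladder_peaks(range(25)), self.BASE)
        assert call.k_max == 24
        assert call.gaps == ()

    def test_anchor_gap_when_unmodified_absent(self):
        call = call_ladder(self.ladder_peaks(range(1, 25)), self.BASE)
        assert call.k_max == 24
        assert call.gaps == (0,)

    def test_internal_gap_reported(self):
        call = call_ladder(
            self.ladder_peaks([0, 1, 3, 4]), self.BASE, max_gap=1, min_rungs=3
        )
        assert call.k_max == 4
        assert call.gaps == (2,)
        assert call.rungs == (0, 1, 3, 4)

    def test_gap_run_terminates_ladder(self):
        call = call_ladder(
            self.ladder_peaks([0, 1, 2, 5, 6]), self.BASE, max_gap=1, min_rungs=3
        )
        assert call.k_max == 2  # rungs 3 and 4 missing: two consecutive gaps

    def test_min_rungs_unmet_returns_none(self):
        assert call_ladder(self.ladder_peaks([0]), self.BASE) is None
        assert call_ladder(peaklist(900.0), self.BASE) is None

    def test_jittered_rungs_recovered(self):
        call = call_ladder(self.ladder_peaks(range(10), jitter=0.1 / 3), self.BASE)
        assert call.k_max == 9
        assert call.gaps == ()

    def test_decoys_far_from_rungs_do_not_change_call(self):
        rng = np.random.default_rng(11)
        reference = call_ladder(self.ladder_peaks(range(1, 25)), self.BASE)
        rung_positions = [self.BASE + n * GLYCINE for n in range(31)]
        decoys = []
        while len(decoys) < 60:
            mz = float(rng.uniform(750, 4000))
            if all(abs(mz - r) > 0.2 for r in rung_positions):
                decoys.append(mz)
        noisy = call_ladder(
            self.ladder_peaks(range(1, 25), extra=decoys), self.BASE
        )
        assert noisy.rungs == reference.rungs
        assert noisy.gaps == reference.gaps

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            call_ladder(peaklist(900.0), self.BASE, tolerance=0)
        with pytest.raises(ValueError):
            call_ladder(peaklist(900.0), self.BASE, min_rungs=1)
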