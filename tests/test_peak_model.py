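"""Score conversion, filtering, ranking, quantile selection, and peak I/O."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from chiptarget.peak_model import (
    Peak,
    PeakError,
    PeakParseError,
    PeakSet,
    filter_peaks,
    p_from_score,
    rank_and_index,
    read_peaks,
    score_from_p,
    select_top_fraction,
    write_peak_table,
    write_peaks,
)
from chiptarget.target_assignment import Assignment
from .conftest import random_peaks


def mk(peak_id, score, fold=5.0, chrom="c", start=0, end=100):
    return Peak(peak_id, chrom, start, end, score, fold)


class TestScoreConversion:
    def test_p_1e5_maps_to_score_50(self):
        assert score_from_p(1e-5) == pytest.approx(50.0, abs=1e-12)
        assert score_from_p(1.0) == 0.0
        assert score_from_p(1e-64) == pytest.approx(640.0, abs=1e-9)

    def test_score_50_maps_back_to_p_1e5(self):
        assert p_from_score(50.0) == pytest.approx(1e-5, rel=1e-12)
        assert p_from_score(0.0) == 1.0
        assert p_from_score(642.39) <= 1e-64

    @pytest.mark.parametrize("bad_p", [0.0, -1.0, 1.5])
    def test_p_domain(self, bad_p):
        with pytest.raises(ValueError):
            score_from_p(bad_p)

    def test_score_domain(self):
        with pytest.raises(ValueError):
            p_from_score(-1.0)

    @given(st.floats(min_value=1e-300, max_value=1.0))
    def test_round_trip(self, p):
        assert p_from_score(score_from_p(p)) == pytest.approx(p, rel=1e-12)


class TestFilterPeaks:
    def test_boundary_values_are_kept(self):
        ps = PeakSet([mk("a", 50.0, 3.0), mk("b", 49.9, 10.0), mk("c", 80.0, 2.99)])
        kept = filter_peaks(ps)
        assert [p.peak_id for p in kept] == ["a"]

    def test_matches_predicate_comprehension(self, rng):
        ps = random_peaks(rng, n_peaks=100)
        kept = filter_peaks(ps, min_score=120.0, min_fold=4.0)
        expected = [p for p in ps if p.score >= 120.0 and p.fold >= 4.0]
        assert kept.peaks == expected
        assert len(ps) == 100  # input unmodified

    @given(
        s1=st.floats(0, 600), s2=st.floats(0, 600),
        f1=st.floats(0.5, 50), f2=st.floats(0.5, 50),
    )
    def test_monotone_in_thresholds(self, s1, s2, f1, f2):
        import numpy as np

        ps = random_peaks(np.random.default_rng(7), n_peaks=50)
        lo = filter_peaks(ps, min_score=min(s1, s2), min_fold=min(f1, f2))
        hi = filter_peaks(ps, min_score=max(s1, s2), min_fold=max(f1, f2))
        assert {p.peak_id for p in hi} <= {p.peak_id for p in lo}


class TestRankAndIndex:
    def test_indices_follow_score_order(self):
        ps = PeakSet([mk("a", 10), mk("b", 99, start=200, end=300), mk("c", 50, start=400, end=500)])
        ranked = {p.peak_id: p.index for p in rank_and_index(ps)}
        assert ranked == {"a": 3, "b": 1, "c": 2}

    def test_score_tie_broken_by_start(self):
        ps = PeakSet([
            Peak("x", "chr2L", 100, 150, 80.0, 5.0),
            Peak("y", "chr2L", 50, 90, 80.0, 5.0),
        ])
        ranked = {p.peak_id: p.index for p in rank_and_index(ps)}
        assert ranked == {"y": 1, "x": 2}

    def test_idempotent(self, rng):
        ps = random_peaks(rng, n_peaks=40)
        once = rank_and_index(ps)
        twice = rank_and_index(once)
        assert once.peaks == twice.peaks

    def test_index_is_permutation_and_score_non_increasing(self, rng):
        ranked = rank_and_index(random_peaks(rng, n_peaks=200))
        ordered = sorted(ranked, key=lambda p: p.index)
        assert sorted(p.index for p in ordered) == list(range(1, 201))
        scores = [p.score for p in ordered]
        assert all(a >= b for a, b in zip(scores, scores[1:]))


class TestSelectTopFraction:
    @pytest.mark.parametrize(
        "n,fraction,expected",
        [(7_566, 0.10, 757), (10, 1.0, 10), (10, 0.05, 1), (3, 0.5, 2)],
    )
    def test_ceiling_rule(self, n, fraction, expected):
        ps = rank_and_index(PeakSet([mk(f"p{i}", float(i % 650), start=i, end=i + 10) for i in range(n)]))
        assert len(select_top_fraction(ps, fraction)) == expected

    @pytest.mark.parametrize("fraction", [0.0, -0.2, 1.5])
    def test_fraction_domain(self, fraction):
        ps = rank_and_index(PeakSet([mk("a", 10.0)]))
        with pytest.raises(ValueError):
            select_top_fraction(ps, fraction)

    def test_requires_indexed_peaks(self):
        with pytest.raises(PeakError):
            select_top_fraction(PeakSet([mk("a", 10.0)]), 0.5)

    def test_selection_dominates_remainder(self, rng):
        ps = rank_and_index(random_peaks(rng, n_peaks=97))
        top = select_top_fraction(ps, 0.25)
        assert len(top) == math.ceil(0.25 * 97)
        inside = {p.peak_id for p in top}
        min_in = min(p.score for p in top)
        out_scores = [p.score for p in ps if p.peak_id not in inside]
        assert min_in >= max(out_scores)


class TestPeakIO:
    def test_narrowpeak_pvalue_scaled_by_ten(self, tmp_path):
        path = tmp_path / "x.narrowPeak"
        path.write_text("chr1\t100\t600\tpk1\t100\t.\t8.5\t5.0\t-1\t-1\n")
        ps = read_peaks(path, dialect="narrowpeak")
        p = ps.peaks[0]
        assert (p.start, p.end, p.score, p.fold) == (100, 600, 50.0, 8.5)

    def test_narrowpeak_missing_fold(self, tmp_path):
        path = tmp_path / "x.narrowPeak"
        path.write_text("chr1\t100\t600\tpk1\t100\t.\t-1\t5.0\t-1\t-1\n")
        with pytest.raises(PeakParseError, match="fold"):
            read_peaks(path, dialect="narrowpeak")
        ps = read_peaks(path, dialect="narrowpeak", default_fold=4.0)
        assert ps.peaks[0].fold == 4.0

    def test_macs_tab_start_is_one_based(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("chrom\tstart\tend\tscore\tfold\nchr1\t101\t600\t75.5\t6.2\n")
        p = read_peaks(path, dialect="macs_tab").peaks[0]
        assert (p.start, p.end, p.score, p.fold) == (100, 600, 75.5, 6.2)

    def test_non_numeric_score_names_line(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("chr1\t101\t600\toops\t6.2\n")
        with pytest.raises(PeakParseError, match=r":1:"):
            read_peaks(path, dialect="macs_tab")

    @pytest.mark.parametrize("dialect", ["narrowpeak", "macs_tab"])
    def test_round_trip_preserves_fields(self, tmp_path, rng, dialect):
        ps = random_peaks(rng, n_peaks=50)
        path = tmp_path / "rt"
        write_peaks(ps, path, dialect=dialect)
        back = read_peaks(path, dialect=dialect)
        for orig, new in zip(ps, back):
            assert (orig.peak_id, orig.chrom, orig.start, orig.end) == (
                new.peak_id, new.chrom, new.start, new.end)
            assert new.score == pytest.approx(orig.score, rel=1e-12)
            assert new.fold == pytest.approx(orig.fold, rel=1e-12)


class TestPeakTable:
    def test_table_layout_and_conventions(self, tmp_path):
        peaks = rank_and_index(PeakSet([
            Peak("pkA", "2L", 150, 250, 500.0, 8.0),
            Peak("pkB", "2L", 5_000, 5_400, 100.0, 4.0),
        ]))
        assignments = [
            Assignment("pkA", "gX", "GENE_OVERLAP", 0, "gY", 30),
            Assignment("pkB", "gZ", "GENE_CLOSE", 500, "gZ", 700),
        ]
        out = tmp_path / "table.tsv"
        write_peak_table(peaks, assignments, out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == [
            "INDEX", "PVALUE", "CHR", "START", "END", "GENE",
            "GENE_STATUS", "GENE_DIS", "TSS_GENE", "TSS_DIS",
        ]
        # rows sorted by index; START written 1-based inclusive
        assert lines[1].split("\t") == [
            "1", "500", "2L", "151", "250", "gX", "GENE_OVERLAP", "0", "gY", "30"]
        assert lines[2].split("\t") == [
            "2", "100", "2L", "5001", "5400", "gZ", "GENE_CLOSE", "500", "gZ", "700"]

    def test_unindexed_peaks_rejected(self, tmp_path):
        peaks = PeakSet([Peak("pkA", "2L", 150, 250, 500.0, 8.0)])
        with pytest.raises(PeakError):
            write_peak_table(peaks, [], tmp_path / "t.tsv")
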