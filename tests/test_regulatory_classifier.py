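"""Probe collapsing, POS/NEG/AMB calls, enrichment, and candidate selection."""

import itertools
import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chiptarget.peak_model import Peak, PeakSet
from chiptarget.regulatory_classifier import (
    AMB,
    NEG,
    POS,
    ProbeResponse,
    RegulatoryCall,
    ResponseRecord,
    classify,
    classify_records,
    cluster_enrichment_score,
    collapse_probes,
    hypergeom_enrichment,
    intersect_with_peaks,
    read_probe_table,
    round_pct,
    select_screen_candidates,
    summarize,
    write_probe_table,
)
from chiptarget.target_assignment import Assignment


def record(gene="g", loss=(), gain=()):
    return ResponseRecord(gene, frozenset(loss), frozenset(gain))


class TestCollapseProbes:
    def test_union_is_idempotent(self):
        probes = [
            ProbeResponse("p1", "geneA", "loss", "down", True),
            ProbeResponse("p2", "geneA", "loss", "down", True),
        ]
        (rec,) = collapse_probes(probes)
        assert rec.loss_signs == {"down"} and rec.gain_signs == frozenset()

    def test_dual_direction_probes_kept(self):
        probes = [
            ProbeResponse("p1", "nonA-like", "loss", "up", True),
            ProbeResponse("p2", "nonA-like", "loss", "down", True),
        ]
        (rec,) = collapse_probes(probes)
        assert rec.loss_signs == {"up", "down"}

    def test_insignificant_probes_dropped(self):
        probes = [ProbeResponse("p1", "geneA", "gain", "up", False)]
        assert collapse_probes(probes) == []


class TestClassify:
    @pytest.mark.parametrize(
        "loss,gain,expected",
        [
            ({"down"}, set(), POS),  # lower without the factor => activated
            (set(), {"up"}, POS),
            ({"down"}, {"up"}, POS),
            ({"up"}, set(), NEG),
            (set(), {"down"}, NEG),
            ({"up"}, {"down"}, NEG),
            ({"up"}, {"up"}, AMB),  # loss-up infers repression, gain-up activation
            ({"down"}, {"down"}, AMB),
            ({"up", "down"}, set(), AMB),  # within-contrast conflict
        ],
    )
    def test_sign_union_rule(self, loss, gain, expected):
        assert classify(record(loss=loss, gain=gain)).category == expected

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            classify(record())

    def test_contrast_swap_symmetry(self):
        # loss-down and gain-up infer the same (positive) regulation
        assert (
            classify(record(loss={"down"})).category
            == classify(record(gain={"up"})).category
        )
        assert (
            classify(record(loss={"up"})).category
            == classify(record(gain={"down"})).category
        )


class TestIntersection:
    def test_has_peak_set_from_any_assignment_status(self):
        calls = [RegulatoryCall("g1", POS), RegulatoryCall("g2", NEG)]
        assignments = [Assignment("p1", "g1", "GENE_CLOSE", 40, "g1", 40)]
        out = intersect_with_peaks(calls, assignments)
        assert [(c.gene_id, c.has_peak) for c in out] == [("g1", True), ("g2", False)]

    def test_peakless_genes_excluded_from_summary(self):
        records = [record("g1", loss={"down"}), record("g2", loss={"down"})]
        calls = intersect_with_peaks(
            classify_records(records),
            [Assignment("p1", "g1", "GENE_OVERLAP", 0, "g1", 0)],
        )
        assert summarize(calls, records).total == 1


class TestSummarize:
    def test_percentages_use_half_away_rounding(self):
        assert round_pct(468, 810) == 57.8
        assert round_pct(290, 810) == 35.8
        assert round_pct(52, 810) == 6.4
        assert round_pct(33, 468) == 7.1
        assert round_pct(10, 290) == 3.4
        assert round_pct(94, 810) == 11.6
        assert round_pct(143, 2000) == 7.2  # exactly 7.15 rounds away from zero

    def test_small_example_counts(self):
        records = [
            record("a", loss={"down"}),               # POS, loss only
            record("b", gain={"up"}),                 # POS, gain only
            record("c", loss={"down"}, gain={"up"}),  # POS, both
            record("d", loss={"up"}),                 # NEG, loss only
            record("e", loss={"down"}, gain={"down"}),  # AMB, both
        ]
        calls = [
            RegulatoryCall(r.gene_id, classify(r).category, has_peak=True)
            for r in records
        ]
        s = summarize(calls, records)
        assert (s.total, s.n_pos, s.n_neg, s.n_amb) == (5, 3, 1, 1)
        assert (s.n_loss, s.n_gain, s.n_both) == (4, 3, 2)
        assert s.n_loss + s.n_gain - s.n_both == s.total
        assert (s.pos_breakdown.n_loss, s.pos_breakdown.n_gain, s.pos_breakdown.n_both) == (2, 2, 1)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sets(st.sampled_from(["up", "down"])),
                st.sets(st.sampled_from(["up", "down"])),
            ).filter(lambda t: t[0] or t[1]),
            min_size=1,
            max_size=40,
        )
    )
    def test_partition_and_inclusion_exclusion(self, sign_sets):
        records = [
            record(f"g{i}", loss=loss, gain=gain)
            for i, (loss, gain) in enumerate(sign_sets)
        ]
        calls = [
            RegulatoryCall(r.gene_id, classify(r).category, has_peak=True)
            for r in records
        ]
        s = summarize(calls, records)
        assert s.n_pos + s.n_neg + s.n_amb == s.total
        assert s.n_loss + s.n_gain - s.n_both == s.total
        for br, n_cat in ((s.pos_breakdown, s.n_pos), (s.neg_breakdown, s.n_neg)):
            assert br.n_loss + br.n_gain - br.n_both == n_cat

    def test_empty_summary_rejected(self):
        with pytest.raises(ValueError):
            summarize([], [])


def brute_hypergeom_upper(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    population = [1] * K + [0] * (N - K)
    total = hits = 0
    for combo in itertools.combinations(range(N), n):
        total += 1
        hits += sum(population[i] for i in combo) >= k
    return hits / total


class TestHypergeom:
    def test_term_equals_background(self):
        df = hypergeom_enrichment({"a", "b"}, {"a", "b", "c"}, {"T": {"a", "b", "c"}})
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_small_case_matches_enumeration(self):
        fg = {f"g{i}" for i in range(4)}
        bg = {f"g{i}" for i in range(10)}
        term = {f"g{i}" for i in [0, 1, 2, 3, 9]}  # K=5, k=4
        df = hypergeom_enrichment(fg, bg, {"T": term})
        assert df.loc[0, "p_value"] == pytest.approx(5 / 210)

    def test_zero_overlap_gives_p_one(self):
        df = hypergeom_enrichment({"a"}, {"a", "b", "c", "d"}, {"T": {"b", "c"}})
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_foreground_must_be_subset(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment({"zzz"}, {"a"}, {})

    def test_matches_enumeration_for_small_populations(self, rng):
        for _ in range(40):
            N = int(rng.integers(2, 13))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            bg = [f"g{i}" for i in range(N)]
            fg = [bg[i] for i in rng.choice(N, size=n, replace=False)]
            term = {bg[i] for i in rng.choice(N, size=K, replace=False)}
            df = hypergeom_enrichment(fg, bg, {"T": term})
            k = len(term & set(fg))
            assert df.loc[0, "p_value"] == pytest.approx(
                brute_hypergeom_upper(N, K, n, k), rel=1e-9
            )

    def test_bh_correction_is_monotone(self):
        term_map = {f"T{i}": {f"g{j}" for j in range(i + 1)} for i in range(5)}
        bg = {f"g{i}" for i in range(30)}
        df = hypergeom_enrichment({"g0", "g1", "g2"}, bg, term_map)
        assert (df["q_value"] >= df["p_value"] - 1e-12).all()


class TestClusterScore:
    def test_convention_values(self):
        assert cluster_enrichment_score([0.05, 0.05, 0.05]) == pytest.approx(
            -math.log10(0.05), abs=1e-9
        )
        assert cluster_enrichment_score([1.0, 1.0]) == 0.0
        assert cluster_enrichment_score([0.1, 0.001]) == pytest.approx(2.0)

    def test_domain(self):
        with pytest.raises(ValueError):
            cluster_enrichment_score([0.0, 0.5])
        with pytest.raises(ValueError):
            cluster_enrichment_score([])


class TestScreenCandidates:
    def _setup(self):
        peaks = PeakSet(
            [
                Peak("p1", "c", 0, 100, 250.0, 5.0),
                Peak("p2", "c", 500, 600, 200.0, 5.0),
                Peak("p3", "c", 900, 950, 300.0, 5.0),
            ]
        )
        assignments = [
            Assignment("p1", "novel_hi", "GENE_OVERLAP", 0, "novel_hi", 0),
            Assignment("p2", "novel_boundary", "GENE_OVERLAP", 0, "novel_boundary", 0),
            Assignment("p3", "known", "GENE_OVERLAP", 0, "known", 0),
            Assignment("p3", "novel_unexpressed", "GENE_OVERLAP", 0, "known", 0),
        ]
        return peaks, assignments

    def test_three_criteria(self, caplog):
        peaks, assignments = self._setup()
        expression = {"novel_hi": 12.0, "novel_boundary": 50.0, "known": 99.0}
        novel = {
            "novel_hi": True,
            "novel_boundary": True,
            "known": False,
            "novel_unexpressed": True,
        }
        with caplog.at_level(logging.WARNING):
            out = select_screen_candidates(assignments, peaks, expression, novel)
        # peak score exactly 200 fails the strict P < 1e-20 bound;
        # missing expression counts as not expressed (and is logged)
        assert out == ["novel_hi"]
        assert "novel_unexpressed" in caplog.text

    def test_expression_boundary_kept(self):
        peaks, assignments = self._setup()
        out = select_screen_candidates(
            assignments, peaks, {"novel_hi": 10.0}, {"novel_hi": True}
        )
        assert out == ["novel_hi"]


class TestProbeIO:
    def test_round_trip(self, tmp_path):
        probes = [
            ProbeResponse("p1", "g1", "loss", "down", True),
            ProbeResponse("p2", "g1", "gain", "up", False),
        ]
        path = tmp_path / "probes.tsv"
        write_probe_table(probes, path)
        assert read_probe_table(path) == probes
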