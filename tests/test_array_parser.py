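"""Array-parser correctness: trimming, expansion detection, aggregation."""

import numpy as np
import pytest
from scipy import stats

from adaptrace import (
    SimulationConfig,
    aggregate_calls,
    detect_expansion,
    orient_and_trim,
    parse_read,
    simulate_amplicon_reads,
)
from adaptrace._seq import revcomp
from adaptrace.array_parser import (
    NO_ANCHOR,
    NO_REPEAT_AT_START,
    ParsedRead,
    reject_summary,
)

from conftest import small_config


def _mutate_positions(seq: str, positions: list[int]) -> str:
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestOrientAndTrim:
    def test_adapter_random_bases_anchor_stripped(self, design):
        read = design.adapter + "GT" + design.forward_anchor + "ACGTACGTAC"
        trimmed, orientation, reason = orient_and_trim(read, design)
        assert (trimmed, orientation, reason) == ("ACGTACGTAC", "forward", None)

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_all_random_prefix_lengths(self, design, k):
        tail = "TTTTGGGGCCCCAAAA"
        read = design.adapter + "A" * k + design.forward_anchor + tail
        trimmed, _, _ = orient_and_trim(read, design)
        assert trimmed == tail

    def test_reverse_complement_read(self, design):
        tail = "ACGTACGTACGTACGT"
        read = revcomp(design.adapter + design.forward_anchor + tail)
        trimmed, orientation, _ = orient_and_trim(read, design)
        assert trimmed == tail
        assert orientation == "reverse"

    def test_anchor_within_budget_accepted(self, design):
        mm = design.anchor_max_mismatches
        anchor = _mutate_positions(design.forward_anchor, list(range(mm)))
        read = design.adapter + anchor + "ACGTACGTAC"
        trimmed, _, reason = orient_and_trim(read, design)
        assert trimmed == "ACGTACGTAC" and reason is None

    def test_anchor_over_budget_rejected(self, design):
        mm = design.anchor_max_mismatches
        anchor = _mutate_positions(design.forward_anchor, list(range(mm + 1)))
        read = design.adapter + anchor + "ACGTACGTAC"
        trimmed, _, reason = orient_and_trim(read, design)
        assert trimmed is None
        assert reason == NO_ANCHOR


class TestDetectExpansion:
    def test_unexpanded_array(self, locus, design):
        trimmed = locus.repeat + design.reverse_anchor
        status, spacers, reason = detect_expansion(trimmed, locus, design)
        assert (status, spacers, reason) == ("unexpanded", [], None)

    def test_one_planted_unit(self, locus, design):
        spacer = "ACGATTGCCGTAGCATTACGGATCAGGCTAAGCATG"  # 36 nt
        trimmed = locus.repeat + spacer + locus.repeat + design.reverse_anchor
        status, spacers, _ = detect_expansion(trimmed, locus, design)
        assert status == "expanded"
        assert spacers == [spacer]

    def test_two_planted_units_leader_proximal_order(self, locus, design):
        s1 = "ACGATTGCCGTAGCATTACGGATCAGGCTAAGCATG"
        s2 = "TTGACCATGGAACGTCCTAGAATTCAGGACCATGCA"
        trimmed = (
            locus.repeat + s1 + locus.repeat + s2 + locus.repeat
            + design.reverse_anchor
        )
        status, spacers, _ = detect_expansion(trimmed, locus, design)
        assert status == "expanded"
        assert spacers == [s1, s2]

    def test_no_repeat_at_start_rejected(self, locus, design):
        trimmed = "A" * len(locus.repeat) + design.reverse_anchor
        status, _, reason = detect_expansion(trimmed, locus, design)
        # degenerate case: if the random repeat were A-rich this could match
        assert status == "reject"
        assert reason == NO_REPEAT_AT_START

    def test_errored_repeat_within_budget(self, locus, design):
        spacer = "ACGATTGCCGTAGCATTACGGATCAGGCTAAGCATG"
        rep = _mutate_positions(locus.repeat, [0, 10, 20])  # 3 = default budget
        trimmed = rep + spacer + locus.repeat + design.reverse_anchor
        status, spacers, _ = detect_expansion(trimmed, locus, design)
        assert status == "expanded" and spacers == [spacer]


class TestEndToEndParsing:
    def test_completeness_and_conservation_at_zero_error(self, library, locus, design):
        """Error-free library: every read parses, support is conserved."""
        reads, truth = library
        parses = [parse_read(r.read_id, r.seq, locus, design) for r in reads]
        assert all(p.status == "expanded" for p in parses)
        calls = aggregate_calls(parses, locus.locus_id)
        assert sum(c.support for c in calls) == len(reads)
        planted = {r.seq for r in truth if r.reads > 0}
        called = {c.seq for c in calls}
        assert planted == called
        # per-sequence support: identical planted sequences pool their reads
        support_by_seq = {c.seq: c.support for c in calls}
        truth_by_seq: dict[str, int] = {}
        for r in truth:
            truth_by_seq[r.seq] = truth_by_seq.get(r.seq, 0) + r.reads
        for seq, n in truth_by_seq.items():
            if n > 0:
                assert support_by_seq[seq] == n

    def test_orientation_invariance(self, library, locus, design):
        reads, _ = library
        for r in reads[:50]:
            fwd = parse_read(r.read_id, r.seq, locus, design)
            rev = parse_read(r.read_id, revcomp(r.seq), locus, design)
            assert fwd.status == rev.status
            assert fwd.spacers == rev.spacers

    def test_no_chimeras(self, library, locus, design):
        """Every reported spacer is a contiguous substring of its read."""
        reads, _ = library
        for r in reads[:200]:
            p = parse_read(r.read_id, r.seq, locus, design)
            for s in p.spacers:
                assert s in r.seq or s in revcomp(r.seq)

    def test_recovery_rate_meets_analytic_bound(self, locus, truth, design):
        """At error rate e, acceptance must beat the closed-form lower bound.

        A read certainly parses if the adapter, both anchors, and every
        repeat copy stay within their mismatch budgets; those regions
        mutate independently, so the product of binomial tails bounds the
        acceptance rate from below.
        """
        e = 0.02
        n = 2_000
        cfg = small_config(seed=31, n_reads=n, error_rate=e, orientation="forward")
        reads, _ = simulate_amplicon_reads(locus, truth, design, cfg)
        parses = [parse_read(r.read_id, r.seq, locus, design) for r in reads]
        accepted = sum(p.status == "expanded" for p in parses) / n

        mm_a = design.anchor_max_mismatches
        mm_r = design.repeat_max_mismatches
        p_ok = (
            stats.binom.cdf(mm_a, len(design.adapter), e)
            * stats.binom.cdf(mm_a, len(design.forward_anchor), e)
            * stats.binom.cdf(mm_r, len(locus.repeat), e) ** 2
            * stats.binom.cdf(mm_a, len(design.reverse_anchor), e)
        )
        se = np.sqrt(p_ok * (1 - p_ok) / n)
        assert accepted >= p_ok - 4 * se


class TestAggregateCalls:
    def test_empty_input(self):
        assert aggregate_calls([], "P1") == []

    def test_tie_broken_lexicographically(self):
        parses = [
            ParsedRead("r1", "expanded", ["TTTT" * 9]),
            ParsedRead("r2", "expanded", ["AAAA" * 9]),
        ]
        calls = aggregate_calls(parses, "P1")
        assert [c.seq for c in calls] == ["AAAA" * 9, "TTTT" * 9]

    def test_sorted_by_support_descending(self):
        parses = [ParsedRead(f"r{i}", "expanded", ["GGGG" * 9]) for i in range(3)]
        parses.append(ParsedRead("r9", "expanded", ["AAAA" * 9]))
        calls = aggregate_calls(parses, "P1")
        assert [(c.seq, c.support) for c in calls] == [
            ("GGGG" * 9, 3),
            ("AAAA" * 9, 1),
        ]

    def test_min_reads_filter(self):
        parses = [ParsedRead(f"r{i}", "expanded", ["GGGG" * 9]) for i in range(3)]
        parses.append(ParsedRead("r9", "expanded", ["AAAA" * 9]))
        calls = aggregate_calls(parses, "P1", min_reads=2)
        assert len(calls) == 1

    def test_insertion_index_modal(self):
        s1, s2 = "ACGT" * 9, "TGCA" * 9
        parses = [
            ParsedRead("r1", "expanded", [s1, s2]),
            ParsedRead("r2", "expanded", [s1]),
        ]
        calls = {c.seq: c for c in aggregate_calls(parses, "P1")}
        assert calls[s1].insertion_index == 1
        assert calls[s2].insertion_index == 2

    def test_reject_summary_counts(self, locus, design):
        parses = [
            parse_read("r1", "GATTACA" * 10, locus, design),
            ParsedRead("r2", "expanded", ["ACGT" * 9]),
        ]
        summary = reject_summary(parses)
        assert sum(summary.values()) == 1
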