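"""Parsimonious event reconstruction: partitions, donors, extents, spacer."""

import numpy as np
import pytest

from rrnconv.alignment import OperonAlignment, encode_sequence
from rrnconv.inference import (
    GeneConversionEvent,
    NovelAlleleError,
    SpacerAllele,
    SpacerUnclassifiedError,
    apply_event_min_extent,
    classify_spacer_allele,
    events_from_frame,
    events_to_frame,
    greedy_event_partition,
    infer_event_extents,
    infer_events_for_recipient,
    min_events_oracle,
)
from rrnconv.simulator import LineageState, apply_conversions, sample_conversion
from rrnconv.synthetic import simulate_ma_lineages
from rrnconv.rates import MAExperimentConfig


def aln_from_rows(rows, region="g", kind="gene"):
    return OperonAlignment.from_sequences(region, rows, kind=kind)


class TestInferEventsForRecipient:
    def test_unchanged_row_gives_no_events(self, toy_family):
        assert infer_events_for_recipient(toy_family, toy_family.data[0], "op0") == []

    def test_single_change_donors_and_extents(self):
        # recipient 'r' changes column 5 C->A, matching donors d1 and d2;
        # all donors disagree with r at column 9, blocking rightward growth
        anc = aln_from_rows(
            [
                ("r",  "AAAACAAAGAAA"),
                ("d1", "AAAAAAAATAAA"),
                ("d2", "AAAAAAAATAAA"),
            ]
        )
        evolved = "AAAAAAAAGAAA"
        (event,) = infer_events_for_recipient(anc, evolved, "r")
        assert event.changed_positions == (5,)
        assert event.donor_candidates == frozenset({"d1", "d2"})
        assert event.min_extent == (5, 5)
        assert event.max_extent == (1, 8)

    def test_incompatible_changes_split_into_two_events(self):
        # column 3 matches only d1, column 9 only d2: no single donor works
        anc = aln_from_rows(
            [
                ("r",  "AACAAAAAGAAA"),
                ("d1", "AATAAAAAGAAA"),
                ("d2", "AACAAAAACAAA"),
            ]
        )
        evolved = "AATAAAAACAAA"
        events = infer_events_for_recipient(anc, evolved, "r")
        assert len(events) == 2
        assert events[0].donor_candidates == frozenset({"d1"})
        assert events[1].donor_candidates == frozenset({"d2"})
        # brute-force agreement
        anc_cols = anc.data
        assert min_events_oracle(anc_cols, encode_sequence(evolved), 0) == 2

    def test_shared_donor_spanning_two_runs_gives_one_event(self):
        # both changed columns (and the intervening heterologous column)
        # match donor d1, so one conversion suffices
        anc = aln_from_rows(
            [
                ("r",  "AACAGACAAAAA"),
                ("d1", "AATAGATAAAAA"),
                ("d2", "AACAGACAAAAA"),
            ]
        )
        evolved = "AATAGATAAAAA"
        events = infer_events_for_recipient(anc, evolved, "r")
        assert len(events) == 1
        assert events[0].changed_positions == (3, 7)

    def test_intervening_mismatch_blocks_merging(self):
        # changed columns 3 and 9 both match d1, but at column 6 d1 differs
        # from the (unchanged) recipient, so one event cannot span both
        anc = aln_from_rows(
            [
                ("r",  "AACAAGAAGAAA"),
                ("d1", "AATAACAATAAA"),
            ]
        )
        evolved = "AATAAGAATAAA"
        events = infer_events_for_recipient(anc, evolved, "r")
        assert len(events) == 2

    def test_novel_allele_raises(self):
        anc = aln_from_rows([("r", "AAAA"), ("d", "AAAA")])
        with pytest.raises(NovelAlleleError):
            infer_events_for_recipient(anc, "ACAA", "r")

    def test_gap_state_participates_like_a_base(self):
        # small deletions are alignment characters; converting them works
        anc = aln_from_rows([("r", "AACGTA"), ("d", "AA--TA")])
        (event,) = infer_events_for_recipient(anc, "AA--TA", "r")
        assert event.changed_positions == (3, 4)
        assert event.donor_candidates == frozenset({"d"})


class TestExtents:
    def test_unblocked_extension_spans_whole_region(self):
        anc = aln_from_rows([("r", "AACAAAAA"), ("d", "AATAAAAA")])
        min_ext, max_ext = infer_event_extents(anc, "AATAAAAA", [3], ["d"])
        assert min_ext == (3, 3)
        assert max_ext == (1, 8)

    def test_blocking_column_stops_growth(self):
        # all donors differ from the evolved recipient at column 6
        anc = aln_from_rows([("r", "AACAAGAA"), ("d", "AATAACAA")])
        _, max_ext = infer_event_extents(anc, "AATAAGAA", [3], ["d"])
        assert max_ext == (1, 5)

    def test_surviving_donor_carries_extension(self):
        # d1 blocks at column 7 but d2 still matches, so growth continues
        anc = aln_from_rows(
            [
                ("r",  "AACAAATAA"),
                ("d1", "AATAAACAA"),
                ("d2", "AATAAATAA"),
            ]
        )
        _, max_ext = infer_event_extents(anc, "AATAAATAA", [3], ["d1", "d2"])
        assert max_ext == (1, 9)

    def test_empty_run_rejected(self):
        anc = aln_from_rows([("r", "AAAA"), ("d", "AAAA")])
        with pytest.raises(ValueError):
            infer_event_extents(anc, "AAAA", [], ["d"])


class TestSpacer:
    LONG = SpacerAllele("long", "ACGTACGTAC")
    SHORT = SpacerAllele("short", "TTGCA")

    def test_classify_exact_alleles(self):
        assert classify_spacer_allele("ACGTACGTAC", (self.LONG, self.SHORT)) == "long"
        assert classify_spacer_allele("TTGCA", (self.LONG, self.SHORT)) == "short"

    def test_gaps_ignored_on_classification(self):
        assert classify_spacer_allele("TTGCA-----", (self.LONG, self.SHORT)) == "short"

    def test_near_miss_is_unclassified(self):
        with pytest.raises(SpacerUnclassifiedError):
            classify_spacer_allele("ACGTACGTAT", (self.LONG, self.SHORT))

    def test_spacer_conversion_spans_whole_region(self):
        rows = [("a", "ACGTACGTAC"), ("b", "TTGCA-----"), ("c", "ACGTACGTAC")]
        anc = aln_from_rows(rows, region="spacer", kind="spacer")
        (event,) = infer_events_for_recipient(anc, "TTGCA-----", "a")
        assert event.donor_candidates == frozenset({"b"})
        assert event.min_extent == event.max_extent == (1, 10)

    def test_spacer_novel_sequence_rejected(self):
        rows = [("a", "ACGTACGTAC"), ("b", "TTGCA-----")]
        anc = aln_from_rows(rows, region="spacer", kind="spacer")
        with pytest.raises(NovelAlleleError):
            infer_events_for_recipient(anc, "ACGTACGTAT", "a")


class TestRoundTripAndMaximality:
    """Inferred events reproduce the evolved row and carry maximal donor sets."""

    def _simulated_cases(self, ecoli_family, ecoli_sampler, n=6):
        cfg = MAExperimentConfig(n_lineages=n, n_replicates=1, seed=11)
        evolved, _ = simulate_ma_lineages(ecoli_family, 4e-4, cfg, ecoli_sampler, seed=11)
        for fam in evolved.values():
            for rid, aln in fam.items():
                anc = ecoli_family.alignments[rid]
                for op in anc.operon_ids:
                    yield anc, aln.row(op), op

    def test_round_trip_reproduces_evolved_row(self, ecoli_family, ecoli_sampler):
        seen = 0
        for anc, ev_row, op in self._simulated_cases(ecoli_family, ecoli_sampler):
            events = infer_events_for_recipient(anc, ev_row, op)
            row = anc.row(op).copy()
            for e in events:
                row = apply_event_min_extent(anc, row, e)
            assert (row == ev_row).all()
            seen += len(events)
        assert seen > 0

    def test_donor_sets_are_maximal(self, ecoli_family, ecoli_sampler):
        for anc, ev_row, op in self._simulated_cases(ecoli_family, ecoli_sampler):
            if anc.kind == "spacer":
                continue
            for e in infer_events_for_recipient(anc, ev_row, op):
                lo, hi = e.min_extent
                span = slice(lo - 1, hi)
                excluded = set(anc.operon_ids) - e.donor_candidates - {op}
                for other in excluded:
                    d = anc.row_index(other)
                    assert not (anc.data[d, span] == ev_row[span]).all()


class TestGreedyEqualsOracle:
    def test_random_small_instances(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(200):
            n_copies = int(rng.integers(2, 5))
            m = int(rng.integers(1, 9))
            anc_cols = rng.integers(0, 3, size=(n_copies, m)).astype(np.uint8)
            recipient = 0
            # evolved states always copied from some row: no novel alleles
            ev = np.array(
                [anc_cols[rng.integers(n_copies), c] for c in range(m)], dtype=np.uint8
            )
            greedy = len(greedy_event_partition(anc_cols, ev, recipient))
            exact = min_events_oracle(anc_cols, ev, recipient)
            assert greedy == exact
            checked += 1
        assert checked == 200


class TestEventTsvRoundTrip:
    def test_frame_round_trip(self):
        e = GeneConversionEvent(
            "L01", "16S", "rrnD", (210,), frozenset({"rrnC", "rrnE", "rrnG"}), (210, 210), (1, 1001)
        )
        df = events_to_frame([e])
        (back,) = events_from_frame(df)
        assert back == e
        assert back.max_size == 1001
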