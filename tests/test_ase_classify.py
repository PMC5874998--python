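"""Event classification, frame prediction, and reported-junction annotation."""

from __future__ import annotations

import itertools

import pytest

from titinsplice.ase_classify import (
    SpliceEvent,
    annotate_reported,
    classify_all,
    classify_junction,
    frame_effect,
)
from titinsplice.gene_model import GeneModel, Isoform
from titinsplice.junction_io import Junction

from conftest import build_model


def junction_between(model: GeneModel, donor_exon: int, acceptor_exon: int,
                     donor_shift: int = 0, acceptor_shift: int = 0) -> Junction:
    """Junction joining two exons' boundaries, with transcript-orientation shifts."""
    sign = 1 if model.strand == "+" else -1
    donor = model.donor_pos(model.exon(donor_exon)) + sign * donor_shift
    acceptor = model.acceptor_pos(model.exon(acceptor_exon)) + sign * acceptor_shift
    start, end = min(donor, acceptor), max(donor, acceptor)
    return Junction(model.chromosome, start, end, model.strand)


class TestCategories:
    def test_consecutive_boundaries_are_canonical(self, either_strand_model):
        model = either_strand_model
        event = classify_junction(junction_between(model, 2, 3), model)
        assert event.category == "canonical_consecutive"
        assert (event.donor_exon, event.acceptor_exon) == (2, 3)
        assert event.skipped_exons == ()
        assert event.donor_offset_nt == 0 == event.acceptor_offset_nt

    def test_single_exon_skip(self, either_strand_model):
        model = either_strand_model
        event = classify_junction(junction_between(model, 2, 4), model)
        assert event.category == "exon_skipping"
        assert event.skipped_exons == (3,)

    def test_multi_exon_skip_lists_all_between(self, either_strand_model):
        model = either_strand_model
        event = classify_junction(junction_between(model, 1, 5), model)
        assert event.skipped_exons == (2, 3, 4)

    def test_alt_acceptor_inside_exon_positive_offset(self, either_strand_model):
        model = either_strand_model
        event = classify_junction(junction_between(model, 2, 3, acceptor_shift=4), model)
        assert event.category == "alt_acceptor"
        assert event.acceptor_offset_nt == 4
        assert event.donor_offset_nt == 0
        assert event.acceptor_exon == 3

    def test_alt_donor_into_intron_positive_offset(self, either_strand_model):
        model = either_strand_model
        event = classify_junction(junction_between(model, 2, 3, donor_shift=7), model)
        assert event.category == "alt_donor"
        assert event.donor_offset_nt == 7

    def test_alt_both_when_neither_end_canonical(self, plus_model):
        event = classify_junction(
            junction_between(plus_model, 2, 4, donor_shift=-6, acceptor_shift=9), plus_model
        )
        assert event.category == "alt_both"
        assert (event.donor_offset_nt, event.acceptor_offset_nt) == (-6, 9)

    def test_far_from_any_boundary_is_unassigned(self, plus_model):
        event = classify_junction(
            junction_between(plus_model, 2, 3, donor_shift=30), plus_model, max_offset=10
        )
        assert event.category == "unassigned"

    def test_outside_gene_span_is_unassigned_with_note(self, plus_model):
        event = classify_junction(Junction("chr2", 10, 50, "+"), plus_model)
        assert event.category == "unassigned"
        assert "span" in event.note
        other = classify_junction(Junction("chrX", 1100, 1300, "+"), plus_model)
        assert other.category == "unassigned"

    def test_meta_only_flag_set_by_skipped_exons(self):
        model = build_model([60] * 8, classes={4: "meta_only", 5: "meta_only"})
        event = classify_junction(junction_between(model, 3, 6), model)
        assert event.category == "exon_skipping"
        assert event.skipped_exons == (4, 5)
        assert event.involves_meta_only

    def test_repeat_region_flag_from_end_exons(self):
        model = build_model([60] * 6, repeat_blocks={3: "B1", 4: "B2"})
        assert classify_junction(junction_between(model, 3, 5), model).in_repeated_region
        assert not classify_junction(junction_between(model, 1, 2), model).in_repeated_region

    def test_exon11_skip_pattern(self):
        # junctions 10-12 / 10-13 / 10-14 skip exon 11 (and beyond)
        model = build_model([90] * 14)
        for acceptor, skipped in [(12, (11,)), (13, (11, 12)), (14, (11, 12, 13))]:
            event = classify_junction(junction_between(model, 10, acceptor), model)
            assert event.category == "exon_skipping"
            assert event.skipped_exons == skipped

    def test_consecutive_in_reference_isoform_is_canonical(self):
        # the 47-50 style junction: reference isoform lacks the two middle exons
        n2a_like = Isoform("N2A", (1, 2, 5))
        meta = Isoform("meta", (1, 2, 3, 4, 5))
        model = build_model([60] * 5, isoforms=[meta, n2a_like])
        model.reference_isoform = "N2A"
        event = classify_junction(junction_between(model, 2, 5), model)
        assert event.category == "canonical_consecutive"


class TestFrameEffect:
    def test_skip_delta_is_minus_summed_coding_length(self, either_strand_model):
        model = either_strand_model  # exon 3 length 60 -> delta -60, frame kept
        event = classify_junction(junction_between(model, 2, 4), model)
        assert event.frame_delta_nt == -60
        assert event.frame_preserving == "yes"

    def test_skip_deltas_match_coding_lengths(self, either_strand_model):
        model = either_strand_model
        event = classify_junction(junction_between(model, 3, 5), model)  # skips exon 4 (99 nt)
        assert event.frame_delta_nt == -99
        assert event.frame_preserving == "yes"
        both = classify_junction(junction_between(model, 2, 5), model)  # skips 3+4 = 159 nt
        assert both.frame_delta_nt == -159
        assert both.frame_preserving == "yes"

    def test_frameshifting_skip(self):
        model = build_model([90, 100, 90])  # middle exon 100 nt: 100 % 3 == 1
        event = classify_junction(junction_between(model, 1, 3), model)
        assert event.frame_preserving == "no"
        assert event.frame_delta_nt == -100

    def test_alt_acceptor_small_offsets(self, either_strand_model):
        model = either_strand_model
        downstream = classify_junction(junction_between(model, 2, 3, acceptor_shift=3), model)
        assert downstream.frame_delta_nt == -3
        assert downstream.frame_preserving == "yes"
        intronic = classify_junction(junction_between(model, 2, 3, acceptor_shift=-3), model)
        assert intronic.frame_delta_nt == 3
        assert intronic.frame_preserving == "yes"
        shifted = classify_junction(junction_between(model, 2, 3, acceptor_shift=4), model)
        assert shifted.frame_preserving == "no"

    def test_alt_site_spanning_skipped_exons_combines_terms(self, plus_model):
        # donor +2 into intron, acceptor +4 into exon 4, exon 3 (60 nt) skipped
        event = classify_junction(
            junction_between(plus_model, 2, 4, donor_shift=2, acceptor_shift=4), plus_model
        )
        assert event.frame_delta_nt == 2 - 4 - 60
        assert event.frame_preserving == "no"

    def test_events_touching_noncoding_exon_not_applicable(self):
        model = build_model([60] * 4, classes={1: "noncoding"})
        event = classify_junction(junction_between(model, 1, 3), model)
        assert event.frame_preserving == "not_applicable"
        assert event.frame_delta_nt is None

    def test_disjoint_skip_deltas_are_additive(self):
        model = build_model([90, 120, 60, 99, 150, 81, 33])
        skip_a = classify_junction(junction_between(model, 1, 3), model)  # skips 2
        skip_b = classify_junction(junction_between(model, 4, 7), model)  # skips 5,6
        combined_coding = sum(model.exon(i).coding_length for i in (2, 5, 6))
        assert skip_a.frame_delta_nt + skip_b.frame_delta_nt == -combined_coding


class TestAnnotateReported:
    def test_reference_isoform_junctions_are_reported(self):
        n2a_like = Isoform("N2A", (1, 2, 5))
        model = build_model([60] * 5, isoforms=[n2a_like])
        events = classify_all(
            [junction_between(model, 2, 5), junction_between(model, 1, 3)],
            model,
        )
        assert events[0].previously_reported  # 2-5 consecutive in the isoform
        assert not events[1].previously_reported

    def test_empty_isoform_set_reports_nothing(self, plus_model):
        events = annotate_reported(
            [classify_junction(junction_between(plus_model, 1, 2), plus_model)], plus_model
        )
        assert not events[0].previously_reported


class TestProperties:
    def test_classification_total_and_deterministic(self, either_strand_model):
        model = either_strand_model
        lo, hi = model.span
        junctions = [
            Junction(model.chromosome, s, e, model.strand)
            for s in range(lo - 40, hi + 40, 97)
            for e in (s + 50, s + 333)
        ]
        first = classify_all(junctions, model)
        second = classify_all(junctions, model)
        assert first == second
        assert all(e.category in (
            "canonical_consecutive", "exon_skipping", "alt_donor",
            "alt_acceptor", "alt_both", "unassigned",
        ) for e in first)

    def test_growing_max_offset_never_unassigns(self, plus_model):
        junction = junction_between(plus_model, 2, 3, donor_shift=25)
        small = classify_junction(junction, plus_model, max_offset=10)
        for max_offset in (25, 60, 500):
            bigger = classify_junction(junction, plus_model, max_offset=max_offset)
            assert bigger.category != "unassigned"
        assert small.category == "unassigned"

    def test_equidistant_tie_goes_to_upstream_exon(self):
        # a donor-side point equidistant (60 nt) from the donor boundaries of
        # exons 1 and 2 is assigned to the upstream exon
        model = build_model([60, 60, 60], intron=60)
        donor_mid = model.donor_pos(model.exon(1)) + 60
        acceptor = model.acceptor_pos(model.exon(3))
        event = classify_junction(
            Junction(model.chromosome, donor_mid, acceptor, "+"), model, max_offset=500
        )
        assert event.donor_exon == 1
        assert event.donor_offset_nt == 60
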