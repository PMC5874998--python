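"""Classify observed junctions against the gene model.

Every junction maps to exactly one category:

* ``canonical_consecutive`` — both ends hit annotated boundaries of exons that
  are consecutive in the reference isoform;
* ``exon_skipping`` — both ends hit annotated boundaries of non-consecutive
  exons, excluding everything between them;
* ``alt_donor`` / ``alt_acceptor`` / ``alt_both`` — one or both ends are
  offset from the nearest annotated boundary (within ``max_offset``);
* ``unassigned`` — an end falls farther than ``max_offset`` from any boundary
  of the appropriate side, or the junction lies outside the gene.

Offsets are signed in transcript orientation: positive means the splice site
moved 3'-ward of the canonical boundary (into the intron for a donor, into
the exon for an acceptor).  The reading-frame consequence of an event is the
net change in included coding sequence; an event is frame-preserving when that
delta is a multiple of 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .gene_model import GeneModel, genomic_to_cds
from .junction_io import Junction

__all__ = [
    "SpliceEvent",
    "classify_junction",
    "classify_all",
    "frame_effect",
    "annotate_reported",
    "known_junction_pairs",
    "event_table",
]

CATEGORIES = (
    "canonical_consecutive",
    "exon_skipping",
    "alt_donor",
    "alt_acceptor",
    "alt_both",
    "unassigned",
)


@dataclass(frozen=True)
class SpliceEvent:
    """A junction classified against the gene model."""

    junction: Junction
    category: str
    donor_exon: int | None = None
    acceptor_exon: int | None = None
    skipped_exons: tuple[int, ...] = ()
    donor_offset_nt: int = 0
    acceptor_offset_nt: int = 0
    frame_preserving: str = "not_applicable"  # yes | no | not_applicable
    frame_delta_nt: int | None = None
    involves_meta_only: bool = False
    in_repeated_region: bool = False
    previously_reported: bool = False
    note: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "exon_skipping":
            assert self.skipped_exons and self.donor_offset_nt == 0 == self.acceptor_offset_nt
        if self.category == "canonical_consecutive":
            assert not self.skipped_exons
            assert self.donor_offset_nt == 0 == self.acceptor_offset_nt
        if self.category in ("alt_donor", "alt_both"):
            assert self.donor_offset_nt != 0
        if self.category in ("alt_acceptor", "alt_both"):
            assert self.acceptor_offset_nt != 0

    def label(self) -> str:
        """Short event label in the field's exon-pair style, e.g. ``10-13``."""
        if self.category in ("canonical_consecutive", "exon_skipping"):
            return f"{self.donor_exon}-{self.acceptor_exon}"
        if self.donor_exon is not None and self.acceptor_exon is not None:
            d = f"{self.donor_exon}" + ("*" if self.donor_offset_nt else "")
            a = f"{self.acceptor_exon}" + ("*" if self.acceptor_offset_nt else "")
            return f"{d}-{a}"
        return "unassigned"


def _nearest_boundary(
    model: GeneModel,
    pos: int,
    side: str,
    max_offset: int,
) -> tuple[int, int] | None:
    """(exon_id, signed transcript-orientation offset) of the nearest boundary.

    Offset is t(pos) - t(boundary); ties between equidistant boundaries go to
    the upstream (smaller-ordinal) exon.
    """
    best: tuple[int, int, int] | None = None  # (|offset|, exon_id, offset)
    for exon in model.exons:
        boundary = (
            model.donor_pos(exon) if side == "donor_end" else model.acceptor_pos(exon)
        )
        offset = model.t(pos) - model.t(boundary)
        cand = (abs(offset), exon.exon_id, offset)
        if abs(offset) <= max_offset and (best is None or cand < best):
            best = cand
    if best is None:
        return None
    return best[1], best[2]


def classify_junction(
    junction: Junction,
    model: GeneModel,
    max_offset: int = 500,
) -> SpliceEvent:
    """Classify one junction into the event taxonomy.

    ``max_offset`` bounds how far (nt) an end may sit from an annotated
    boundary and still be called an alternative splice site; beyond it the
    junction is ``unassigned``.  Junctions outside the gene span are returned
    ``unassigned`` with a location note, never raised.
    """
    lo, hi = model.span
    if (
        junction.chromosome != model.chromosome
        or junction.intron_end <= lo
        or junction.intron_start >= hi
    ):
        return SpliceEvent(
            junction, "unassigned", note=f"outside {model.gene_name} span"
        )

    donor_key = model.junction_donor_key(junction.intron_start, junction.intron_end)
    acceptor_key = model.junction_acceptor_key(junction.intron_start, junction.intron_end)

    donor_hit = _nearest_boundary(model, donor_key, "donor_end", max_offset)
    acceptor_hit = _nearest_boundary(model, acceptor_key, "acceptor_start", max_offset)
    if donor_hit is None or acceptor_hit is None:
        return SpliceEvent(
            junction, "unassigned", note="no annotated boundary within max_offset"
        )
    donor_exon, donor_offset = donor_hit
    acceptor_exon, acceptor_offset = acceptor_hit

    skipped = tuple(
        e.exon_id
        for e in model.exons
        if donor_exon < e.exon_id < acceptor_exon
    )
    meta = any(
        model.exon(i).exon_class == "meta_only"
        for i in (donor_exon, acceptor_exon, *skipped)
    )
    repeated = (
        model.exon(donor_exon).repeat_block is not None
        or model.exon(acceptor_exon).repeat_block is not None
    )
    common = dict(
        donor_exon=donor_exon,
        acceptor_exon=acceptor_exon,
        involves_meta_only=meta,
        in_repeated_region=repeated,
    )

    if donor_offset == 0 and acceptor_offset == 0:
        if acceptor_exon <= donor_exon:
            return SpliceEvent(
                junction, "unassigned", note="acceptor not downstream of donor", **common
            )
        reference = model.reference_exon_ids
        consecutive = (donor_exon, acceptor_exon) in set(zip(reference, reference[1:]))
        if consecutive or not skipped:
            # consecutive in the reference isoform (e.g. 47-50 under N2A), or
            # adjacent metatranscript exons with nothing between them
            event = SpliceEvent(junction, "canonical_consecutive", **common)
        else:
            event = SpliceEvent(junction, "exon_skipping", skipped_exons=skipped, **common)
    else:
        if donor_offset != 0 and acceptor_offset != 0:
            category = "alt_both"
        elif donor_offset != 0:
            category = "alt_donor"
        else:
            category = "alt_acceptor"
        event = SpliceEvent(
            junction,
            category,
            skipped_exons=skipped,
            donor_offset_nt=donor_offset,
            acceptor_offset_nt=acceptor_offset,
            **common,
        )
    return frame_effect(event, model)


def frame_effect(event: SpliceEvent, model: GeneModel) -> SpliceEvent:
    """Attach the reading-frame consequence to a classified event.

    The net coding-length change is

        delta = donor_offset - acceptor_offset - sum(coding_length of skipped)

    in transcript orientation: a donor extending into the intron retains
    intronic sequence (+), an acceptor landing inside its exon removes coding
    sequence (-), and every exon between the assigned donor and acceptor is
    removed entirely.  Events touching the noncoding first exon (or exons with
    no coding sequence at the affected end) are ``not_applicable``.
    """
    if event.category == "unassigned":
        return event
    donor = model.exon(event.donor_exon)
    acceptor = model.exon(event.acceptor_exon)
    touched = (donor, acceptor, *(model.exon(i) for i in event.skipped_exons))
    if any(e.exon_class == "noncoding" or e.coding_length == 0 for e in touched):
        return replace(event, frame_preserving="not_applicable", frame_delta_nt=None)
    skipped_coding = sum(model.exon(i).coding_length for i in event.skipped_exons)
    delta = event.donor_offset_nt - event.acceptor_offset_nt - skipped_coding
    return replace(
        event,
        frame_delta_nt=delta,
        frame_preserving="yes" if delta % 3 == 0 else "no",
    )


def known_junction_pairs(model: GeneModel) -> set[tuple[int, int]]:
    """Every consecutive exon pair within each annotated isoform."""
    pairs: set[tuple[int, int]] = set()
    for iso in model.isoforms:
        pairs.update(iso.junctions())
    return pairs


def annotate_reported(
    events: Iterable[SpliceEvent], model: GeneModel
) -> list[SpliceEvent]:
    """Flag events whose exon pair occurs in any annotated isoform.

    A junction is previously reported when its (donor exon, acceptor exon)
    pair — with both ends exactly on annotated boundaries — is a consecutive
    pair in at least one isoform (e.g. the 47-50 junction unique to the long
    skeletal N2A isoform).
    """
    known = known_junction_pairs(model)
    out = []
    for event in events:
        reported = (
            event.category in ("canonical_consecutive", "exon_skipping")
            and (event.donor_exon, event.acceptor_exon) in known
        )
        out.append(replace(event, previously_reported=reported))
    return out


def classify_all(
    junctions: Iterable[Junction],
    model: GeneModel,
    max_offset: int = 500,
    annotate: bool = True,
) -> list[SpliceEvent]:
    """Classify a collection of junctions; optionally flag reported ones."""
    events = [classify_junction(j, model, max_offset=max_offset) for j in junctions]
    return annotate_reported(events, model) if annotate else events


def event_table(
    events: Iterable[SpliceEvent],
    model: GeneModel,
    totals: Mapping[Junction, int] | None = None,
    validation_totals: Mapping[Junction, int] | None = None,
) -> pd.DataFrame:
    """Tabulate classified events in the field's reporting style.

    One row per event: donor/acceptor exon, c.-positions of the two splice
    sites, category, signed offsets, skipped exons, frame call, flags, and —
    when count maps are given — total discovery-cohort reads and validation
    cohort reads.
    """
    rows = []
    for event in events:
        j = event.junction
        row: dict = {
            "chrom": j.chromosome,
            "intron_start": j.intron_start,
            "intron_end": j.intron_end,
            "category": event.category,
            "donor_exon": event.donor_exon,
            "acceptor_exon": event.acceptor_exon,
            "donor_offset_nt": event.donor_offset_nt,
            "acceptor_offset_nt": event.acceptor_offset_nt,
            "skipped_exons": ",".join(map(str, event.skipped_exons)) or ".",
            "frame_preserving": event.frame_preserving,
            "frame_delta_nt": event.frame_delta_nt,
            "involves_meta_only": event.involves_meta_only,
            "in_repeated_region": event.in_repeated_region,
            "previously_reported": event.previously_reported,
            "label": event.label(),
        }
        if event.category != "unassigned":
            donor_key = model.junction_donor_key(j.intron_start, j.intron_end)
            acceptor_key = model.junction_acceptor_key(j.intron_start, j.intron_end)
            # last included base on the donor side / first on the acceptor side
            shift = -1 if model.strand == "+" else 0
            try:
                row["donor_c"] = str(genomic_to_cds(model, donor_key + shift))
                row["acceptor_c"] = str(
                    genomic_to_cds(model, acceptor_key + (0 if model.strand == "+" else -1))
                )
            except ValueError:
                row["donor_c"] = row["acceptor_c"] = "."
        else:
            row["donor_c"] = row["acceptor_c"] = "."
        if totals is not None:
            row["total_reads"] = totals.get(j, 0)
        if validation_totals is not None:
            row["validation_reads"] = validation_totals.get(j, 0)
        rows.append(row)
    return pd.DataFrame(rows)
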