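"""Per-exon inclusion/exclusion support and the inclusion-rate statistic.

For each exon, ``I`` is the number of junction reads supporting its inclusion
(all junctions going into or exiting the exon, including alternative-site
junctions landing inside it) and ``E`` the number of reads supporting its
exclusion (junctions spanning clear over it; a multi-exon skipping junction
contributes its full count to every exon it spans).  The inclusion rate is

    (I / f) / ((I / f) + E)

with f = 2 for internal exons, because an included exon is entered once and
exited once so its inclusion is evidenced by two junction crossings per
molecule, while exclusion is evidenced by one.  Terminal exons have a single
flank, so f = 1 keeps the estimator unbiased there.  The statistic is the
junction-level analogue of percent-spliced-in (PSI).

Exons are categorised structurally: ``constitutively_expressed`` when no
QC-passing junction excludes them (and inclusion junctions are detected),
``constitutively_spliced_out`` when no passing junction includes them, else
``variable`` with a computed rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ase_classify import SpliceEvent
from .gene_model import Exon, GeneModel
from .junction_io import Junction

__all__ = [
    "ExonUsage",
    "inclusion_rate",
    "percent",
    "exon_support",
    "usage_table",
    "compare_cohorts",
    "usage_frame",
]

CATEGORIES = (
    "constitutively_expressed",
    "constitutively_spliced_out",
    "variable",
    "no_data",
)


@dataclass(frozen=True)
class ExonUsage:
    """Inclusion/exclusion read support and category for one exon."""

    exon_id: int
    inclusion_reads: int
    exclusion_reads: int
    inclusion_rate: float | None  # None = no data
    category: str
    supporting_skip_events: tuple[str, ...] = ()
    flanks: int = 2

    @property
    def percent(self) -> int | None:
        return None if self.inclusion_rate is None else percent(self.inclusion_rate)


def inclusion_rate(I: int, E: int, flanks: int = 2) -> float:
    """The inclusion-rate statistic (I/f) / ((I/f) + E).

    ``flanks`` is the number of junction crossings that evidence one included
    molecule: 2 for an internal exon (entered and exited), 1 for a terminal
    exon.  Undefined when I = E = 0 (no evidence either way) — raises rather
    than returning a misleading 0 or 1.
    """
    if I < 0 or E < 0:
        raise ValueError("read counts must be non-negative")
    if flanks not in (1, 2):
        raise ValueError(f"flanks must be 1 or 2, got {flanks}")
    if I == 0 and E == 0:
        raise ValueError("inclusion rate undefined for I = E = 0 (no data)")
    half = I / flanks
    return half / (half + E)


def percent(rate: float) -> int:
    """Integer percent, rounded half away from zero (reporting convention)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate {rate} outside [0, 1]")
    return int(floor(rate * 100 + 0.5))


def _exon_boundaries(model: GeneModel, exon: Exon) -> tuple[int, int]:
    """(Ts, Te): transcript-axis values of the exon's acceptor/donor boundaries."""
    return model.t(model.acceptor_pos(exon)), model.t(model.donor_pos(exon))


def exon_support(
    exon: Exon,
    events: Sequence[SpliceEvent],
    counts: Mapping[Junction, int],
    model: GeneModel,
) -> tuple[int, int, tuple[str, ...]]:
    """(I, E, supporting exclusion-event labels) for one exon.

    Geometry is evaluated in transcript orientation: a junction supports
    inclusion when its donor end lies at or within the exon or its acceptor
    end does; it supports exclusion when its donor is at/upstream of the
    exon's start and its acceptor at/downstream of its end.  Unassigned
    events are ignored.
    """
    ts, te = _exon_boundaries(model, exon)
    inclusion = 0
    exclusion = 0
    skip_labels: list[str] = []
    for event in events:
        if event.category == "unassigned":
            continue
        j = event.junction
        count = counts.get(j, 0)
        if count == 0:
            continue
        td = model.t(model.junction_donor_key(j.intron_start, j.intron_end))
        ta = model.t(model.junction_acceptor_key(j.intron_start, j.intron_end))
        if (ts < td <= te) or (ts <= ta < te):
            inclusion += count
        elif td <= ts and ta >= te:
            exclusion += count
            skip_labels.append(event.label())
    return inclusion, exclusion, tuple(dict.fromkeys(skip_labels))


def usage_table(
    model: GeneModel,
    events: Sequence[SpliceEvent],
    counts: Mapping[Junction, int],
    include_repeat_region: bool = False,
    include_noncoding: bool = False,
) -> list[ExonUsage]:
    """Per-exon usage rows, ordered by exon id.

    ``counts`` should hold pooled QC-passing junction totals (pass unfiltered
    totals to disable filtering).  Exons inside repeat blocks are excluded by
    default — short-read junction counts there are inflated by ambiguous
    mapping — and can be opted in with ``include_repeat_region``.
    """
    rows: list[ExonUsage] = []
    terminal = {model.exons[0].exon_id, model.exons[-1].exon_id}
    for exon in model.exons:
        if exon.exon_class == "noncoding" and not include_noncoding:
            continue
        if exon.repeat_block is not None and not include_repeat_region:
            continue
        I, E, skip_labels = exon_support(exon, events, counts, model)
        flanks = 1 if exon.exon_id in terminal else 2
        if I == 0 and E == 0:
            rows.append(ExonUsage(exon.exon_id, 0, 0, None, "no_data", (), flanks))
            continue
        rate = inclusion_rate(I, E, flanks=flanks)
        if E == 0:
            category = "constitutively_expressed"
        elif I == 0:
            category = "constitutively_spliced_out"
        else:
            category = "variable"
        rows.append(ExonUsage(exon.exon_id, I, E, rate, category, skip_labels, flanks))
    return rows


def usage_frame(rows: Iterable[ExonUsage]) -> pd.DataFrame:
    """Usage rows as a report-style DataFrame (exon, %, I, E, events, category)."""
    return pd.DataFrame(
        {
            "exon": r.exon_id,
            "inclusion_pct": r.percent,
            "inclusion_reads": r.inclusion_reads,
            "exclusion_reads": r.exclusion_reads,
            "skipping_events": ";".join(r.supporting_skip_events) or ".",
            "category": r.category,
        }
        for r in rows
    )


def compare_cohorts(
    usage_tables: Mapping[str, Sequence[ExonUsage]],
) -> pd.DataFrame:
    """Long-format per-exon inclusion comparison across cohorts.

    All cohorts must be computed against the same gene model (same exon id
    set); exons lacking data in a cohort propagate a missing rate.
    """
    if not usage_tables:
        raise ValueError("no cohorts to compare")
    id_sets = {name: tuple(r.exon_id for r in rows) for name, rows in usage_tables.items()}
    reference = next(iter(id_sets.values()))
    for name, ids in id_sets.items():
        if ids != reference:
            raise ValueError(
                f"cohort {name!r} computed against a different exon set"
            )
    records = []
    for name, rows in usage_tables.items():
        for r in rows:
            records.append(
                {
                    "cohort": name,
                    "exon": r.exon_id,
                    "inclusion_rate": r.inclusion_rate,
                    "inclusion_reads": r.inclusion_reads,
                    "exclusion_reads": r.exclusion_reads,
                    "category": r.category,
                }
            )
    return pd.DataFrame(records)
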