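"""Splice-junction extraction, junction-file I/O and multi-sample merging.

A junction is the intron excised by a splicing event, represented by its
0-based half-open genomic interval.  Junctions are counted from spliced
alignments by walking CIGAR strings (each N operation is one junction crossing)
or read from tab/BED junction files, then merged across samples into a
junction x sample count matrix backed by a pandas DataFrame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import pysam

__all__ = [
    "Junction",
    "JunctionCountMatrix",
    "ExtractionDiagnostics",
    "extract_junctions",
    "read_junction_file",
    "write_junction_file",
    "merge_samples",
]

# CIGAR op codes that consume the reference (M, D, N, =, X)
_REF_CONSUMING = {0, 2, 3, 7, 8}
# ops contributing aligned (anchoring) bases: M, =, X
_ALIGNED = {0, 7, 8}
_CIGAR_N = 3


@dataclass(frozen=True, order=True)
class Junction:
    """An intron interval, 0-based half-open, with an optional strand."""

    chromosome: str
    intron_start: int
    intron_end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.intron_start < 0:
            raise ValueError(f"negative intron start: {self.intron_start}")
        if self.intron_start >= self.intron_end:
            raise ValueError(
                f"intron start {self.intron_start} >= end {self.intron_end}"
            )

    @property
    def length(self) -> int:
        return self.intron_end - self.intron_start

    def key(self) -> tuple[str, int, int, str]:
        return (self.chromosome, self.intron_start, self.intron_end, self.strand)


@dataclass
class ExtractionDiagnostics:
    """Per-sample tally from extract_junctions."""

    records_seen: int = 0
    records_unmapped: int = 0
    records_malformed: int = 0
    junction_crossings: int = 0
    crossings_below_anchor: int = 0


class JunctionCountMatrix:
    """Junction x sample table of non-negative read counts.

    Rows are :class:`Junction` objects (unique), columns are sample ids
    (unique).  ``totals`` and ``samples_detected`` are the two per-junction
    summaries the QC filter operates on: total supporting reads across the
    cohort and the number of samples in which the junction was seen at all.
    """

    def __init__(self, counts: pd.DataFrame, junctions: list[Junction]):
        if counts.shape[0] != len(junctions):
            raise ValueError("counts rows != number of junctions")
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        if len(set(j.key() for j in junctions)) != len(junctions):
            raise ValueError("duplicate junctions")
        if counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        self._counts = counts.astype("int64")
        self._junctions = list(junctions)

    # -- construction --------------------------------------------------------

    @classmethod
    def from_sample_counts(
        cls, per_sample: Mapping[str, Mapping[Junction, int]]
    ) -> "JunctionCountMatrix":
        samples = list(per_sample)
        junctions = sorted({j for counts in per_sample.values() for j in counts})
        data = {
            sample: [per_sample[sample].get(j, 0) for j in junctions]
            for sample in samples
        }
        frame = pd.DataFrame(data, columns=samples, dtype="int64")
        return cls(frame, junctions)

    # -- accessors ------------------------------------------------------------

    @property
    def junctions(self) -> list[Junction]:
        return list(self._junctions)

    @property
    def samples(self) -> list[str]:
        return [str(c) for c in self._counts.columns]

    @property
    def counts(self) -> pd.DataFrame:
        return self._counts.copy()

    @property
    def n_junctions(self) -> int:
        return len(self._junctions)

    def totals(self) -> dict[Junction, int]:
        sums = self._counts.sum(axis=1)
        return {j: int(sums.iloc[i]) for i, j in enumerate(self._junctions)}

    def samples_detected(self) -> dict[Junction, int]:
        detected = (self._counts > 0).sum(axis=1)
        return {j: int(detected.iloc[i]) for i, j in enumerate(self._junctions)}

    def sample_counts(self, sample: str) -> dict[Junction, int]:
        col = self._counts[sample]
        return {
            j: int(col.iloc[i]) for i, j in enumerate(self._junctions) if col.iloc[i] > 0
        }

    def subset(self, junctions: Iterable[Junction]) -> "JunctionCountMatrix":
        keep = set(j.key() for j in junctions)
        mask = [j.key() in keep for j in self._junctions]
        return JunctionCountMatrix(
            self._counts.loc[mask].reset_index(drop=True),
            [j for j, m in zip(self._junctions, mask) if m],
        )

    # -- I/O -------------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long header frame: junction key columns + one count column per sample."""
        keys = pd.DataFrame(
            [j.key() for j in self._junctions],
            columns=["chrom", "intron_start", "intron_end", "strand"],
        )
        return pd.concat([keys, self._counts.reset_index(drop=True)], axis=1)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "JunctionCountMatrix":
        frame = pd.read_csv(path, sep="\t")
        key_cols = ["chrom", "intron_start", "intron_end", "strand"]
        junctions = [
            Junction(str(row.chrom), int(row.intron_start), int(row.intron_end), str(row.strand))
            for row in frame[key_cols].itertuples()
        ]
        counts = frame.drop(columns=key_cols)
        return cls(counts, junctions)


# -- extraction from spliced alignments ----------------------------------------


def _records_from_sam(path: str | Path) -> Iterator[pysam.AlignedSegment]:
    """Iterate alignment records from SAM text, tolerating a missing header."""
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            yield from sam
        return
    except (ValueError, NotImplementedError, OSError):
        pass
    # headerless SAM: synthesise @SQ lines from the RNAME column, then let
    # pysam parse each record against that header
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip() and not ln.startswith("@")]
    refs = []
    seen = set()
    for ln in lines:
        fields = ln.split("\t")
        if len(fields) > 2 and fields[2] != "*" and fields[2] not in seen:
            seen.add(fields[2])
            refs.append(fields[2])
    header = pysam.AlignmentHeader.from_references(refs, [2**29] * len(refs))
    for ln in lines:
        yield pysam.AlignedSegment.fromstring(ln, header)


def walk_cigar_junctions(
    reference_start: int, cigartuples: list[tuple[int, int]]
) -> list[tuple[int, int, int, int]]:
    """Introns crossed by one alignment, with their flanking anchors.

    Returns ``(intron_start, intron_end, left_anchor, right_anchor)`` per N
    operation, where anchors are the aligned (M/=/X) base counts between this
    N and the previous/next N (or the read ends).  Insertions and clips do not
    advance the reference; deletions advance it without adding anchor.
    """
    if reference_start < 0:
        raise ValueError(f"negative reference start: {reference_start}")
    pos = reference_start
    segments: list[int] = [0]  # aligned bases per inter-N segment
    introns: list[tuple[int, int]] = []
    for op, length in cigartuples:
        if op == _CIGAR_N:
            introns.append((pos, pos + length))
            segments.append(0)
            pos += length
        elif op in _ALIGNED:
            segments[-1] += length
            pos += length
        elif op in _REF_CONSUMING:  # D
            pos += length
    return [
        (start, end, segments[i], segments[i + 1])
        for i, (start, end) in enumerate(introns)
    ]


def extract_junctions(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    min_anchor: int = 8,
    diagnostics: ExtractionDiagnostics | None = None,
) -> dict[Junction, int]:
    """Count splice junctions supported by spliced alignments of one sample.

    Each N operation in a CIGAR contributes one junction crossing; a crossing
    is counted only when the aligned blocks on both sides of the N span at
    least ``min_anchor`` nt (default 8, a typical junction-caller overhang
    requirement suppressing spurious 1-2 nt alignments).  Unmapped records are
    skipped; records with malformed CIGARs are skipped with a warning and
    tallied in the diagnostics.
    """
    diag = diagnostics if diagnostics is not None else ExtractionDiagnostics()
    counts: dict[Junction, int] = {}
    records = (
        _records_from_sam(alignments)
        if isinstance(alignments, (str, Path))
        else alignments
    )
    for record in records:
        diag.records_seen += 1
        if record.is_unmapped or record.cigartuples is None:
            diag.records_unmapped += 1
            continue
        if record.reference_start < 0:
            raise ValueError(
                f"record {record.query_name}: negative position {record.reference_start}"
            )
        try:
            crossings = walk_cigar_junctions(record.reference_start, record.cigartuples)
        except (ValueError, TypeError) as exc:
            diag.records_malformed += 1
            warnings.warn(f"skipping record {record.query_name}: {exc}", stacklevel=2)
            continue
        strand = "."
        if record.has_tag("XS"):
            strand = str(record.get_tag("XS"))
        chrom = record.reference_name or "*"
        for start, end, left, right in crossings:
            diag.junction_crossings += 1
            if left < min_anchor or right < min_anchor:
                diag.crossings_below_anchor += 1
                continue
            junction = Junction(chrom, start, end, strand)
            counts[junction] = counts.get(junction, 0) + 1
    return counts


# -- junction files ------------------------------------------------------------


def read_junction_file(path: str | Path, dialect: str = "tab") -> dict[Junction, int]:
    """Read per-junction counts for one sample.

    ``tab`` dialect: chrom, intron_start, intron_end, strand, count (0-based
    half-open intron coordinates).  ``bed`` dialect: BED12 with two blocks per
    line (the junction-caller convention: blocks are the flanking aligned
    regions, the gap between them is the intron; score carries the count).
    Duplicate junction lines are summed with a warning.
    """
    if dialect not in ("tab", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    counts: dict[Junction, int] = {}
    duplicates = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if dialect == "tab":
                if len(fields) < 5:
                    raise ValueError(f"{path}:{lineno}: expected 5 tab columns")
                chrom, start, end, strand, count = fields[:5]
                start, end, count = int(start), int(end), int(count)
            else:
                if len(fields) < 12:
                    raise ValueError(f"{path}:{lineno}: expected BED12")
                chrom = fields[0]
                chrom_start = int(fields[1])
                count = int(fields[4])
                strand = fields[5]
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
                if len(sizes) != 2 or len(starts) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: junction BED12 must have exactly 2 blocks"
                    )
                start = chrom_start + starts[0] + sizes[0]
                end = chrom_start + starts[1]
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: intron start {start} >= end {end}"
                )
            junction = Junction(chrom, start, end, strand)
            if junction in counts:
                duplicates += 1
            counts[junction] = counts.get(junction, 0) + count
    if duplicates:
        warnings.warn(
            f"{path}: {duplicates} duplicate junction line(s); counts summed",
            stacklevel=2,
        )
    return counts


def write_junction_file(counts: Mapping[Junction, int], path: str | Path) -> None:
    """Write the tab dialect read by :func:`read_junction_file`."""
    with open(path, "w") as handle:
        for junction in sorted(counts):
            handle.write(
                f"{junction.chromosome}\t{junction.intron_start}\t"
                f"{junction.intron_end}\t{junction.strand}\t{counts[junction]}\n"
            )


def merge_samples(
    per_sample_counts: Mapping[str, Mapping[Junction, int]] | list[tuple[str, Mapping[Junction, int]]],
) -> JunctionCountMatrix:
    """Merge per-sample junction counts into one matrix.

    The junction set is the union across samples; absent counts are zero.
    Sample ids must be unique; an empty sample is retained as a zero column.
    """
    if isinstance(per_sample_counts, Mapping):
        items = list(per_sample_counts.items())
    else:
        items = list(per_sample_counts)
    if not items:
        raise ValueError("no samples to merge")
    ids = [sample for sample, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    return JunctionCountMatrix.from_sample_counts(dict(items))
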