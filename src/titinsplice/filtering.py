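"""Two-stage QC filtering of splicing events.

Stage one applies discovery-cohort thresholds: a junction passes when it is
supported by at least ``min_total_reads`` reads pooled across the cohort AND
detected (count > 0) in at least ``min_samples`` samples.  Stage two keeps
only junctions also seen in an independent validation cohort with strictly
more than 10 pooled reads (``validation_min_reads`` = 11); junctions failing
validation are preserved and reported separately rather than dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .junction_io import Junction, JunctionCountMatrix

__all__ = ["FilterConfig", "qc_filter", "cross_cohort_validate", "QCResult"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the two-stage QC.

    Defaults reproduce the published criteria: >= 1000 pooled reads, detected
    in >= 14 of the cohort's samples, and > 10 reads (i.e. >= 11) in the
    validation cohort.
    """

    min_total_reads: int = 1000
    min_samples: int = 14
    validation_min_reads: int = 11

    def __post_init__(self) -> None:
        if min(self.min_total_reads, self.min_samples, self.validation_min_reads) < 0:
            raise ValueError("filter thresholds must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "FilterConfig":
        """Read ``key = value`` / ``key: value`` lines (keys as field names)."""
        values: dict[str, int] = {}
        with open(path) as handle:
            for line in handle:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                for sep in ("=", ":", "\t"):
                    if sep in line:
                        key, _, val = line.partition(sep)
                        values[key.strip()] = int(val.strip())
                        break
                else:
                    raise ValueError(f"unparseable config line: {line!r}")
        unknown = set(values) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**values)


@dataclass
class QCResult:
    """Passing junction set plus per-junction diagnostics for all junctions."""

    passing: list[Junction]
    diagnostics: pd.DataFrame  # chrom/start/end/strand, total_reads, samples_detected, passed


def qc_filter(matrix: JunctionCountMatrix, config: FilterConfig = FilterConfig()) -> QCResult:
    """Apply the discovery-cohort thresholds to a junction count matrix.

    Inclusive comparisons ("at least"): exactly ``min_total_reads`` reads in
    exactly ``min_samples`` samples passes.  Diagnostics rows are emitted for
    every junction, including failures.
    """
    if matrix.n_junctions == 0:
        raise ValueError("empty junction matrix")
    if config.min_samples > len(matrix.samples):
        warnings.warn(
            f"min_samples={config.min_samples} exceeds cohort size "
            f"{len(matrix.samples)}; no junction can pass",
            stacklevel=2,
        )
    totals = matrix.totals()
    detected = matrix.samples_detected()
    rows = []
    passing = []
    for junction in matrix.junctions:
        ok = (
            totals[junction] >= config.min_total_reads
            and detected[junction] >= config.min_samples
        )
        if ok:
            passing.append(junction)
        rows.append(
            {
                "chrom": junction.chromosome,
                "intron_start": junction.intron_start,
                "intron_end": junction.intron_end,
                "strand": junction.strand,
                "total_reads": totals[junction],
                "samples_detected": detected[junction],
                "passed": ok,
            }
        )
    return QCResult(passing=passing, diagnostics=pd.DataFrame(rows))


def cross_cohort_validate(
    passing: list[Junction],
    validation_counts: Mapping[Junction, int],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[Junction], list[Junction]]:
    """Split QC-passing junctions by independent-cohort support.

    A junction is validated when present in the validation data with pooled
    count >= ``validation_min_reads`` (strictly more than 10 reads under the
    default).  Returns ``(validated, unvalidated)``; the two lists partition
    the input.  Validation counts are matched on the junction interval,
    ignoring the strand tag (cohorts may differ in strandedness annotation).
    """
    if not validation_counts:
        warnings.warn("empty validation set: nothing can validate", stacklevel=2)
    by_interval: dict[tuple[str, int, int], int] = {}
    for junction, count in validation_counts.items():
        key = (junction.chromosome, junction.intron_start, junction.intron_end)
        by_interval[key] = by_interval.get(key, 0) + count
    validated, unvalidated = [], []
    for junction in passing:
        key = (junction.chromosome, junction.intron_start, junction.intron_end)
        if by_interval.get(key, 0) >= config.validation_min_reads:
            validated.append(junction)
        else:
            unvalidated.append(junction)
    return validated, unvalidated
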