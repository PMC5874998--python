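"""Position-frequency consensus scoring of splice-site windows.

A splice site is scored against a per-position nucleotide frequency table
(the Shapiro–Senapathy scheme, the scoring model underlying tools such as
Human Splicing Finder): the raw score is the sum (or product) of the observed
nucleotides' frequencies, min–max normalised to a 0–100 consensus value so
that the per-position consensus sequence scores 100 and the anti-consensus
scores 0.

The packaged default matrices are synthetic consensus-frequency estimates in
the classic donor 9-mer layout (last 3 exonic + first 6 intronic nt, with the
invariant GT dinucleotide at intronic +1/+2) and a 15-position acceptor
window (polypyrimidine tract, branch-distal positions, the invariant AG, and
the first exonic base).  Published web-service score tables are proprietary,
so absolute values are not comparable across matrix versions; deltas between
an alternative and its canonical site under one matrix are the meaningful
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import prod
from pathlib import Path

import pandas as pd

__all__ = [
    "SpliceSiteMatrix",
    "ConsensusScore",
    "SiteComparison",
    "load_matrix",
    "default_donor_matrix",
    "default_acceptor_matrix",
    "consensus_value",
    "compare_sites",
    "read_site_windows",
]

_NUCS = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SpliceSiteMatrix:
    """Per-position nucleotide frequencies for a donor or acceptor window."""

    site_type: str  # donor | acceptor
    positions: tuple[str, ...]  # labels relative to the junction, e.g. -3..+6
    frequencies: tuple[tuple[float, float, float, float], ...]  # A,C,G,T rows

    def __post_init__(self) -> None:
        if self.site_type not in ("donor", "acceptor"):
            raise ValueError(f"site_type must be donor/acceptor, got {self.site_type!r}")
        if len(self.positions) != len(self.frequencies):
            raise ValueError("window length != frequency table length")
        for label, row in zip(self.positions, self.frequencies):
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"frequencies at position {label} do not sum to 1")
            if any(f < 0 for f in row):
                raise ValueError(f"negative frequency at position {label}")

    @property
    def window_length(self) -> int:
        return len(self.positions)

    def frequency(self, index: int, nucleotide: str) -> float:
        return self.frequencies[index][_NUCS.index(nucleotide)]


@dataclass(frozen=True)
class ConsensusScore:
    """A 0-100 consensus value, or an 'unpredicted' result for ambiguous input."""

    value: float | None
    site_sequence: str
    site_type: str

    @property
    def predicted(self) -> bool:
        return self.value is not None

    def __str__(self) -> str:
        return f"{self.value:.2f}" if self.predicted else "Unpredicted"


@dataclass(frozen=True)
class SiteComparison:
    alt: ConsensusScore
    canonical: ConsensusScore
    delta: float | None  # alt - canonical; None when either is unpredicted


def load_matrix(path: str | Path, site_type: str) -> SpliceSiteMatrix:
    """Load a matrix TSV (columns: position, A, C, G, T)."""
    frame = pd.read_csv(path, sep="\t", dtype={"position": str})
    missing = {"position", *_NUCS} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return SpliceSiteMatrix(
        site_type=site_type,
        positions=tuple(frame["position"]),
        frequencies=tuple(
            tuple(float(row[n]) for n in _NUCS) for _, row in frame.iterrows()
        ),
    )


def _packaged(name: str, site_type: str) -> SpliceSiteMatrix:
    with resources.as_file(resources.files("titinsplice") / "data" / name) as path:
        return load_matrix(path, site_type)


def default_donor_matrix() -> SpliceSiteMatrix:
    """The packaged donor 9-mer matrix (asserts the invariant GT at +1/+2)."""
    matrix = _packaged("donor_matrix.tsv", "donor")
    for label, nuc in (("+1", "G"), ("+2", "T")):
        idx = matrix.positions.index(label)
        if matrix.frequency(idx, nuc) == 0 or sum(matrix.frequencies[idx]) - matrix.frequency(idx, nuc) > 1e-9:
            raise ValueError(f"donor matrix must require {nuc} at {label}")
    return matrix


def default_acceptor_matrix() -> SpliceSiteMatrix:
    return _packaged("acceptor_matrix.tsv", "acceptor")


def consensus_value(
    sequence: str, matrix: SpliceSiteMatrix, combine: str = "sum"
) -> ConsensusScore:
    """Score one site window against a matrix on the 0-100 consensus scale.

    ``combine`` selects how per-position frequencies form the raw score:
    ``sum`` (default) or ``product``.  The value is min-max normalised so the
    best attainable window scores 100 and the worst 0.  Windows containing
    anything outside A/C/G/T (N, gaps) return an unpredicted result, never a
    number.  Case-insensitive.
    """
    if combine not in ("sum", "product"):
        raise ValueError(f"combine must be sum/product, got {combine!r}")
    seq = sequence.upper()
    if len(seq) != matrix.window_length:
        raise ValueError(
            f"window length {len(seq)} != matrix window {matrix.window_length}"
        )
    if any(ch not in _NUCS for ch in seq):
        return ConsensusScore(None, sequence, matrix.site_type)
    observed = [matrix.frequency(i, ch) for i, ch in enumerate(seq)]
    best = [max(row) for row in matrix.frequencies]
    worst = [min(row) for row in matrix.frequencies]
    agg = sum if combine == "sum" else prod
    raw, raw_max, raw_min = agg(observed), agg(best), agg(worst)
    value = 100.0 * (raw - raw_min) / (raw_max - raw_min)
    return ConsensusScore(value, sequence, matrix.site_type)


def compare_sites(
    alt_sequence: str,
    canonical_sequence: str,
    matrix: SpliceSiteMatrix,
    combine: str = "sum",
) -> SiteComparison:
    """Paired scores for an alternative site and its canonical counterpart.

    Mirrors the reporting convention "novel splice site (value for wt)"; the
    delta is alt - canonical, undefined (None) when either window is
    unpredicted.
    """
    alt = consensus_value(alt_sequence, matrix, combine=combine)
    canonical = consensus_value(canonical_sequence, matrix, combine=combine)
    delta = (
        alt.value - canonical.value
        if alt.predicted and canonical.predicted
        else None
    )
    return SiteComparison(alt=alt, canonical=canonical, delta=delta)


def read_site_windows(fasta_path: str | Path) -> list[tuple[str, str]]:
    """Read (name, window) pairs from a FASTA of site windows."""
    from Bio import SeqIO

    return [
        (record.id, str(record.seq)) for record in SeqIO.parse(str(fasta_path), "fasta")
    ]
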