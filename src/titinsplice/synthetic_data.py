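"""Simulated gene models, isoform mixtures, junction counts and spliced reads.

Everything the pipeline consumes can be generated here with known ground
truth: a toy multi-exon gene (optionally with meta-only and repeated-block
exons), a cohort of samples expressing a mixture of isoforms, junction read
counts drawn around means proportional to isoform abundance, and SAM text
whose CIGAR strings encode the junctions.  The default cohort layout mirrors
a bulk short-read muscle study: 42 samples, sequencing depth expressed as
expected junction-spanning reads per transcript unit, 86 bp single-end reads.

All randomness flows from the mandatory ``seed``; a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .gene_model import Exon, GeneModel, Isoform
from .junction_io import Junction, JunctionCountMatrix, merge_samples

__all__ = [
    "AltSiteSpec",
    "SimConfig",
    "SimTruth",
    "make_toy_gene",
    "simulate_junction_counts",
    "emit_spliced_sam",
    "emit_cohort_sam",
    "make_titin_like_model",
]


@dataclass(frozen=True)
class AltSiteSpec:
    """An alternative splice site to simulate.

    The canonical junction 3'-ward (side=donor) or 5'-ward (side=acceptor) of
    ``exon`` is duplicated with the given transcript-orientation offset and
    expressed at ``usage_fraction`` of the depth.
    """

    exon: int
    side: str  # donor | acceptor
    offset: int  # signed, transcript orientation; != 0
    usage_fraction: float

    def __post_init__(self) -> None:
        if self.side not in ("donor", "acceptor"):
            raise ValueError(f"side must be donor/acceptor, got {self.side!r}")
        if self.offset == 0:
            raise ValueError("alt-site offset must be non-zero")
        if not 0 < self.usage_fraction <= 1:
            raise ValueError("usage_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Design of one simulated cohort.

    ``isoforms`` maps isoform name -> included exon ids; ``proportions`` maps
    isoform name -> mixing proportion, either one value shared by all samples
    or one value per sample.  Proportions must sum to 1 in every sample.
    ``depth`` is the expected junction-spanning read count per transcript
    unit and sample.
    """

    n_exons: int = 6
    seed: int = 0
    n_samples: int = 42
    depth: float = 1e4
    isoforms: Mapping[str, Sequence[int]] = field(default_factory=dict)
    proportions: Mapping[str, float | Sequence[float]] = field(default_factory=dict)
    meta_only_ids: frozenset[int] = frozenset()
    frameshift_exons: frozenset[int] = frozenset()  # exons with length % 3 != 0
    repeat_blocks: tuple[str, ...] = ()
    repeat_copies: int = 0
    repeat_start: int | None = None
    alt_site_spec: tuple[AltSiteSpec, ...] = ()
    count_noise: str = "poisson"  # poisson | negative_binomial
    nb_dispersion: float = 0.1
    strand: str = "+"
    first_exon_noncoding: bool = False
    read_length: int = 86

    def __post_init__(self) -> None:
        if self.n_exons < 2:
            raise ValueError("need at least 2 exons")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.count_noise not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown count noise {self.count_noise!r}")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        if set(self.isoforms) != set(self.proportions):
            raise ValueError("isoforms and proportions must name the same set")
        for name, exon_ids in self.isoforms.items():
            if any(not 1 <= e <= self.n_exons for e in exon_ids):
                raise ValueError(f"isoform {name} references exons outside 1..{self.n_exons}")
        for sample in range(self.n_samples):
            total = sum(self._proportion(name, sample) for name in self.isoforms)
            if self.isoforms and abs(total - 1.0) > 1e-9:
                raise ValueError(f"proportions in sample {sample} sum to {total}, not 1")
        if self.repeat_blocks and (self.repeat_copies < 1 or self.repeat_start is None):
            raise ValueError("repeat_blocks needs repeat_copies >= 1 and repeat_start")

    def _proportion(self, isoform: str, sample_index: int) -> float:
        value = self.proportions[isoform]
        if isinstance(value, (int, float)):
            return float(value)
        return float(value[sample_index])


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort.

    ``exon_inclusion`` holds the true per-sample inclusion probability of each
    exon (the summed proportions of isoforms containing it); ``expected_counts``
    the pooled (cohort-total) expected count of each simulated junction;
    ``alt_sites`` the configured alternative-site events.
    """

    exon_inclusion: dict[int, tuple[float, ...]]
    expected_counts: dict[Junction, float]
    alt_sites: tuple[AltSiteSpec, ...] = ()

    def mean_inclusion(self, exon_id: int) -> float:
        values = self.exon_inclusion[exon_id]
        return float(sum(values)) / len(values)


# -- gene construction ---------------------------------------------------------


def make_toy_gene(config: SimConfig, gene_name: str = "toygene") -> GeneModel:
    """Deterministic toy gene from a SimConfig.

    Exon coding lengths are multiples of 3 (60-300 nt) except for exons named
    in ``frameshift_exons``, so the frame consequence of any simulated skip is
    controlled by construction.  Introns are 80-500 nt.  Classes and repeat
    blocks follow the config; isoforms are attached, with an implicit
    ``metatranscript`` isoform containing every exon as the reference.
    """
    rng = np.random.default_rng(config.seed)
    lengths = (rng.integers(20, 101, size=config.n_exons) * 3).astype(int)
    for exon_id in config.frameshift_exons:
        lengths[exon_id - 1] += 1
    introns = rng.integers(80, 501, size=config.n_exons - 1).astype(int)

    block_of: dict[int, str] = {}
    if config.repeat_blocks:
        span = len(config.repeat_blocks) * config.repeat_copies
        for offset in range(span):
            exon_id = config.repeat_start + offset
            if exon_id > config.n_exons:
                raise ValueError("repeat block specification exceeds gene length")
            block_of[exon_id] = config.repeat_blocks[offset % len(config.repeat_blocks)]

    exons: list[Exon] = []
    cursor = 1000
    for i in range(config.n_exons):
        exon_id = i + 1
        start, end = cursor, cursor + int(lengths[i])
        cursor = end + (int(introns[i]) if i < config.n_exons - 1 else 0)
        noncoding = config.first_exon_noncoding and exon_id == 1
        if noncoding:
            exon_class = "noncoding"
        elif exon_id in config.meta_only_ids:
            exon_class = "meta_only"
        else:
            exon_class = "canonical"
        exons.append(
            Exon(
                exon_id=exon_id,
                genomic_start=start,
                genomic_end=end,
                strand=config.strand,
                exon_class=exon_class,
                repeat_block=block_of.get(exon_id),
            )
        )
    if config.strand == "-":
        # mirror so exon 1 sits at the highest genomic coordinates
        top = cursor + 1000
        exons = [
            Exon(
                exon_id=e.exon_id,
                genomic_start=top - e.genomic_end,
                genomic_end=top - e.genomic_start,
                strand="-",
                exon_class=e.exon_class,
                repeat_block=e.repeat_block,
            )
            for e in exons
        ]
    isoforms = [Isoform("metatranscript", tuple(range(1, config.n_exons + 1)))]
    isoforms += [
        Isoform(name, tuple(sorted(exon_ids)))
        for name, exon_ids in config.isoforms.items()
        if name != "metatranscript"
    ]
    return GeneModel(
        gene_name=gene_name,
        chromosome="chrT",
        strand=config.strand,
        exons=exons,
        isoforms=isoforms,
        reference_isoform="metatranscript",
    )


def make_titin_like_model(seed: int = 364) -> GeneModel:
    """A synthetic 364-exon minus-strand model shaped like the titin metatranscript.

    Synthetic coordinates (the real gene's genomic coordinates are not
    bundled); exon 1 noncoding; meta-only flags on exons 148, 150, 159-171 and
    213-217; repeat-block labels B1-B9 cycling over exons 172-205;
    isoform-specific flags on the Novex exons 45, 46 and 48.  Isoforms:
    the full metatranscript (reference), an N2A-like adult skeletal isoform
    (all exons minus meta-only and Novex exons and exon 49), and an
    Novex3-like isoform truncated after exon 48.
    """
    meta_only = frozenset({148, 150, *range(159, 172), *range(213, 218)})
    config = SimConfig(
        n_exons=364,
        seed=seed,
        meta_only_ids=meta_only,
        repeat_blocks=tuple(f"B{i}" for i in range(1, 10)),
        repeat_copies=4,  # 36 slots; trimmed to the 34-exon span below
        repeat_start=172,
        strand="-",
        first_exon_noncoding=True,
    )
    # build with 9x4=36 block labels then trim to exons 172..205 (34 exons)
    base = make_toy_gene(config, gene_name="TTN-like")
    exons = [
        e if (e.repeat_block is None or 172 <= e.exon_id <= 205) else Exon(
            e.exon_id, e.genomic_start, e.genomic_end, e.strand, e.exon_class, None
        )
        for e in base.exons
    ]
    novex = {45, 46, 48}
    exons = [
        Exon(e.exon_id, e.genomic_start, e.genomic_end, e.strand, "isoform_specific", e.repeat_block)
        if e.exon_id in novex
        else e
        for e in exons
    ]
    all_ids = tuple(range(1, 365))
    n2a = tuple(i for i in all_ids if i not in meta_only and i not in {45, 46, 48, 49})
    isoforms = [
        Isoform("metatranscript", all_ids),
        Isoform("N2A", n2a),
        Isoform("Novex3", tuple(range(1, 49))),
    ]
    return GeneModel(
        gene_name="TTN-like",
        chromosome="chrT",
        strand="-",
        exons=exons,
        isoforms=isoforms,
        reference_isoform="metatranscript",
    )


# -- count simulation ----------------------------------------------------------


def _isoform_junctions(model: GeneModel, exon_ids: Sequence[int]) -> list[Junction]:
    out = []
    for a, b in zip(exon_ids, exon_ids[1:]):
        donor = model.donor_pos(model.exon(a))
        acceptor = model.acceptor_pos(model.exon(b))
        start, end = min(donor, acceptor), max(donor, acceptor)
        out.append(Junction(model.chromosome, start, end, model.strand))
    return out


def _alt_site_junction(model: GeneModel, spec: AltSiteSpec) -> Junction:
    sign = 1 if model.strand == "+" else -1
    if spec.side == "acceptor":
        donor_exon = model.exon(spec.exon - 1)
        donor = model.donor_pos(donor_exon)
        acceptor = model.acceptor_pos(model.exon(spec.exon)) + sign * spec.offset
    else:
        donor = model.donor_pos(model.exon(spec.exon)) + sign * spec.offset
        acceptor = model.acceptor_pos(model.exon(spec.exon + 1))
    start, end = min(donor, acceptor), max(donor, acceptor)
    return Junction(model.chromosome, start, end, model.strand)


def _draw(rng: np.random.Generator, mean: float, config: SimConfig) -> int:
    if mean <= 0:
        return 0
    if config.count_noise == "poisson":
        return int(rng.poisson(mean))
    size = 1.0 / config.nb_dispersion
    return int(rng.negative_binomial(size, size / (size + mean)))


def simulate_junction_counts(
    model: GeneModel, config: SimConfig
) -> tuple[JunctionCountMatrix, SimTruth]:
    """Draw a junction x sample count matrix with known truth.

    Per sample, every junction of every configured isoform receives a count
    drawn around mean = depth x isoform proportion (summed over isoforms
    sharing the junction); alternative-site junctions receive mean = depth x
    usage_fraction.  The truth records each exon's per-sample inclusion
    probability (summed proportions of isoforms containing it) and each
    junction's pooled expected count.
    """
    if not config.isoforms:
        raise ValueError("config defines no isoforms to simulate")
    rng = np.random.default_rng(config.seed + 1)
    iso_junctions = {
        name: _isoform_junctions(model, sorted(exon_ids))
        for name, exon_ids in config.isoforms.items()
    }
    alt_junctions = [(_alt_site_junction(model, s), s) for s in config.alt_site_spec]

    per_sample: dict[str, dict[Junction, int]] = {}
    expected: dict[Junction, float] = {}
    for s in range(config.n_samples):
        sample_id = f"sample{s + 1:02d}"
        means: dict[Junction, float] = {}
        for name in config.isoforms:
            p = config._proportion(name, s)
            for junction in iso_junctions[name]:
                means[junction] = means.get(junction, 0.0) + config.depth * p
        for junction, spec in alt_junctions:
            means[junction] = means.get(junction, 0.0) + config.depth * spec.usage_fraction
        counts = {j: _draw(rng, m, config) for j, m in means.items()}
        per_sample[sample_id] = counts
        for j, m in means.items():
            expected[j] = expected.get(j, 0.0) + m

    inclusion: dict[int, tuple[float, ...]] = {}
    for exon in model.exons:
        per_sample_p = tuple(
            sum(
                config._proportion(name, s)
                for name, exon_ids in config.isoforms.items()
                if exon.exon_id in exon_ids
            )
            for s in range(config.n_samples)
        )
        inclusion[exon.exon_id] = per_sample_p
    truth = SimTruth(
        exon_inclusion=inclusion,
        expected_counts=expected,
        alt_sites=config.alt_site_spec,
    )
    return merge_samples(per_sample), truth


# -- spliced-read emission -----------------------------------------------------


def _sam_header(model: GeneModel, extra: int = 100000) -> str:
    _, hi = model.span
    return (
        "@HD\tVN:1.6\tSO:unsorted\n"
        f"@SQ\tSN:{model.chromosome}\tLN:{hi + extra}\n"
    )


def emit_spliced_sam(
    model: GeneModel,
    counts: Mapping[Junction, int],
    read_length: int = 86,
    seed: int = 0,
    min_anchor: int = 8,
    sample_id: str = "sample",
) -> str:
    """SAM text whose spliced reads reproduce one sample's junction counts.

    For each junction with count c, emits c single-end reads whose CIGAR is
    ``<left>M<intron>N<right>M`` with the split point drawn uniformly so both
    anchors are >= ``min_anchor`` nt.  Extracting junctions from the emitted
    text (at the same anchor threshold) reproduces the counts exactly.
    """
    if read_length <= 2 * min_anchor:
        raise ValueError(
            f"read_length {read_length} too short for min_anchor {min_anchor}"
        )
    rng = np.random.default_rng(seed)
    lines = [_sam_header(model)]
    read_no = 0
    for junction in sorted(counts):
        c = counts[junction]
        if c <= 0:
            continue
        lefts = rng.integers(min_anchor, read_length - min_anchor + 1, size=c)
        for left in lefts:
            left = int(left)
            right = read_length - left
            pos1 = junction.intron_start - left + 1  # 1-based SAM POS
            if pos1 < 1:
                raise ValueError(f"junction {junction} too close to contig start")
            read_no += 1
            cigar = f"{left}M{junction.length}N{right}M"
            strand_tag = junction.strand if junction.strand in "+-" else model.strand
            lines.append(
                f"{sample_id}.r{read_no}\t0\t{junction.chromosome}\t{pos1}\t60\t"
                f"{cigar}\t*\t0\t0\t{'A' * read_length}\t*\tXS:A:{strand_tag}\n"
            )
    return "".join(lines)


def emit_cohort_sam(
    model: GeneModel,
    matrix: JunctionCountMatrix,
    read_length: int = 86,
    seed: int = 0,
    min_anchor: int = 8,
) -> dict[str, str]:
    """One SAM text per sample of the matrix (seeds derived per sample)."""
    out = {}
    for i, sample in enumerate(matrix.samples):
        out[sample] = emit_spliced_sam(
            model,
            matrix.sample_counts(sample),
            read_length=read_length,
            seed=seed + 7919 * (i + 1),
            min_anchor=min_anchor,
            sample_id=sample,
        )
    return out
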