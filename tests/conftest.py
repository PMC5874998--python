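"""Shared fixtures: small explicit gene models with hand-computable geometry."""

from __future__ import annotations

import pytest

from titinsplice.gene_model import Exon, GeneModel, Isoform


def build_model(
    lengths: list[int],
    strand: str = "+",
    intron: int = 100,
    classes: dict[int, str] | None = None,
    repeat_blocks: dict[int, str] | None = None,
    isoforms: list[Isoform] | None = None,
    origin: int = 1000,
    chromosome: str = "chr2",
    gene_name: str = "toy",
) -> GeneModel:
    """Explicit toy gene: exon lengths in transcript order, constant introns.

    For a minus-strand gene exon 1 is placed at the highest genomic
    coordinates, so transcript order always follows the given length list.
    """
    classes = classes or {}
    repeat_blocks = repeat_blocks or {}
    spans = []
    cursor = origin
    for length in lengths:
        spans.append((cursor, cursor + length))
        cursor += length + intron
    if strand == "-":
        top = cursor + origin
        spans = [(top - end, top - start) for start, end in spans]
    exons = [
        Exon(
            exon_id=i + 1,
            genomic_start=start,
            genomic_end=end,
            strand=strand,
            exon_class=classes.get(i + 1, "canonical"),
            repeat_block=repeat_blocks.get(i + 1),
        )
        for i, (start, end) in enumerate(spans)
    ]
    return GeneModel(
        gene_name=gene_name,
        chromosome=chromosome,
        strand=strand,
        exons=exons,
        isoforms=isoforms or [],
    )


@pytest.fixture
def plus_model() -> GeneModel:
    """5 coding exons, lengths 90/120/60/99/150, plus strand, introns 100."""
    return build_model([90, 120, 60, 99, 150])


@pytest.fixture
def minus_model() -> GeneModel:
    return build_model([90, 120, 60, 99, 150], strand="-")


@pytest.fixture(params=["+", "-"])
def either_strand_model(request) -> GeneModel:
    return build_model([90, 120, 60, 99, 150], strand=request.param)
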