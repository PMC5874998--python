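"""Exon/isoform model of a single complex gene.

The central object is :class:`GeneModel`: an ordered list of exons (ordinals
assigned 5'->3' in transcript orientation, so exon 1 of a minus-strand gene is
the exon with the largest genomic coordinate), a set of named isoforms given as
ordered exon-id lists, and a reference isoform that defines which exon pairs
count as "consecutive" for canonical-junction calls.

Coordinates are 0-based half-open internally.  User-facing coding positions
follow HGVS-like c.-nomenclature (1-based within the concatenated CDS of the
metatranscript; intronic positions render as ``c.N-3`` / ``c.N+5``).

Exon classes distinguish the biology of a titin-style gene: ``canonical``
exons are part of the adult reference isoform, ``meta_only`` exons appear only
in the inferred complete metatranscript, ``isoform_specific`` exons belong to
particular isoforms (e.g. the Novex exons), and ``noncoding`` marks untranslated
exons such as titin's first exon.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Exon",
    "Isoform",
    "GeneModel",
    "CdsPosition",
    "GeneModelError",
    "GeneNotFoundError",
    "ModelValidationError",
    "load_gene_model",
    "read_exon_table",
    "write_exon_table",
    "boundary_index",
    "genomic_to_cds",
]

EXON_CLASSES = ("canonical", "meta_only", "isoform_specific", "noncoding")

EXON_TABLE_COLUMNS = (
    "exon_id",
    "chrom",
    "start",
    "end",
    "strand",
    "class",
    "repeat_block",
    "coding_length",
)


class GeneModelError(ValueError):
    """Base error for gene-model loading and validation."""


class GeneNotFoundError(GeneModelError):
    """Requested gene absent from the annotation source."""


class ModelValidationError(GeneModelError):
    """Model violates a structural invariant (overlap, ordering, ...)."""


@dataclass(frozen=True)
class Exon:
    """One exon of the gene model.

    ``exon_id`` is the 1-based ordinal in transcript orientation (the field's
    "exon 11" / "exon 363" numbering).  ``coding_length`` is the number of
    nucleotides the exon contributes to the CDS; it defaults to the full exon
    length for coding classes and 0 for ``noncoding``.
    """

    exon_id: int
    genomic_start: int
    genomic_end: int
    strand: str
    exon_class: str = "canonical"
    repeat_block: str | None = None
    coding_length: int | None = None

    def __post_init__(self) -> None:
        if self.genomic_start >= self.genomic_end:
            raise ModelValidationError(
                f"exon {self.exon_id}: start {self.genomic_start} >= end {self.genomic_end}"
            )
        if self.strand not in ("+", "-"):
            raise ModelValidationError(f"exon {self.exon_id}: bad strand {self.strand!r}")
        if self.exon_class not in EXON_CLASSES:
            raise ModelValidationError(
                f"exon {self.exon_id}: unknown class {self.exon_class!r}"
            )
        if self.coding_length is None:
            object.__setattr__(
                self,
                "coding_length",
                0 if self.exon_class == "noncoding" else self.length,
            )
        if not 0 <= self.coding_length <= self.length:
            raise ModelValidationError(
                f"exon {self.exon_id}: coding_length {self.coding_length} "
                f"outside [0, {self.length}]"
            )

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start


@dataclass(frozen=True)
class Isoform:
    """A named isoform as an ordered (strictly increasing) list of exon ids."""

    name: str
    exon_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exon_ids", tuple(self.exon_ids))
        if any(b <= a for a, b in zip(self.exon_ids, self.exon_ids[1:])):
            raise ModelValidationError(
                f"isoform {self.name}: exon ids must be strictly increasing"
            )

    def junctions(self) -> list[tuple[int, int]]:
        """Consecutive exon pairs (the isoform's splice junctions)."""
        return list(zip(self.exon_ids, self.exon_ids[1:]))


@dataclass
class GeneModel:
    gene_name: str
    chromosome: str
    strand: str
    exons: list[Exon]
    isoforms: list[Isoform] = field(default_factory=list)
    reference_isoform: str | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.exon_id)
        ids = [e.exon_id for e in self.exons]
        if len(set(ids)) != len(ids):
            raise ModelValidationError("duplicate exon ids")
        # transcript order must match genomic order under the strand
        genomic = sorted(self.exons, key=lambda e: e.genomic_start)
        if self.strand == "-":
            genomic = genomic[::-1]
        if [e.exon_id for e in genomic] != ids:
            raise ModelValidationError(
                "exon ids are not ordered 5'->3' in transcript orientation"
            )
        by_pos = sorted(self.exons, key=lambda e: e.genomic_start)
        for a, b in zip(by_pos, by_pos[1:]):
            if b.genomic_start < a.genomic_end:
                raise ModelValidationError(
                    f"exons {a.exon_id} and {b.exon_id} overlap"
                )
            if b.genomic_start == a.genomic_end:
                raise ModelValidationError(
                    f"exons {a.exon_id} and {b.exon_id} share a coordinate "
                    f"({a.genomic_end}); splice boundaries would collide"
                )
        for e in self.exons:
            if e.strand != self.strand:
                raise ModelValidationError(
                    f"exon {e.exon_id} strand {e.strand} != gene strand {self.strand}"
                )
        known = set(ids)
        for iso in self.isoforms:
            missing = set(iso.exon_ids) - known
            if missing:
                raise ModelValidationError(
                    f"isoform {iso.name} references unknown exons {sorted(missing)}"
                )
        if self.reference_isoform is None and self.isoforms:
            self.reference_isoform = self.isoforms[0].name
        if self.reference_isoform is not None and not any(
            i.name == self.reference_isoform for i in self.isoforms
        ):
            raise ModelValidationError(
                f"reference isoform {self.reference_isoform!r} not among isoforms"
            )
        self._by_id = {e.exon_id: e for e in self.exons}

    # -- basic queries -------------------------------------------------------

    def exon(self, exon_id: int) -> Exon:
        try:
            return self._by_id[exon_id]
        except KeyError:
            raise KeyError(f"no exon {exon_id} in {self.gene_name}") from None

    def isoform(self, name: str) -> Isoform:
        for iso in self.isoforms:
            if iso.name == name:
                return iso
        raise KeyError(f"no isoform {name!r} in {self.gene_name}")

    @property
    def reference_exon_ids(self) -> tuple[int, ...]:
        """Exon ordering used for "consecutive" calls.

        Defaults to the metatranscript ordering (all exons) when no reference
        isoform is set.
        """
        if self.reference_isoform is None:
            return tuple(e.exon_id for e in self.exons)
        return self.isoform(self.reference_isoform).exon_ids

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(e.genomic_start for e in self.exons),
            max(e.genomic_end for e in self.exons),
        )

    # -- transcript-orientation geometry -------------------------------------

    def t(self, genomic_pos: int) -> int:
        """Transcript-axis coordinate: increases 5'->3' along the transcript."""
        return genomic_pos if self.strand == "+" else -genomic_pos

    def donor_pos(self, exon: Exon) -> int:
        """Genomic splice position of the exon's donor (3') boundary.

        Expressed as the junction-key convention: the intron coordinate that a
        junction using this donor carries (intron start on '+', intron end on
        '-').  For a minus-strand gene this is the exon's LOWER genomic
        coordinate.
        """
        return exon.genomic_end if self.strand == "+" else exon.genomic_start

    def acceptor_pos(self, exon: Exon) -> int:
        """Genomic splice position of the exon's acceptor (5') boundary."""
        return exon.genomic_start if self.strand == "+" else exon.genomic_end

    def junction_donor_key(self, intron_start: int, intron_end: int) -> int:
        """The junction end that faces the donor side, per gene strand."""
        return intron_start if self.strand == "+" else intron_end

    def junction_acceptor_key(self, intron_start: int, intron_end: int) -> int:
        return intron_end if self.strand == "+" else intron_start


@dataclass(frozen=True)
class CdsPosition:
    """A genomic position mapped onto the concatenated CDS.

    ``kind`` is ``coding`` (c.N), ``intronic`` (c.N-3 / c.N+5 relative to the
    nearest exon boundary) or ``non_coding`` (UTR / noncoding exon).
    """

    kind: str
    c_position: int | None = None
    intron_offset: int | None = None  # signed: -3 = 3 nt upstream of acceptor

    def __str__(self) -> str:
        if self.kind == "coding":
            return f"c.{self.c_position}"
        if self.kind == "intronic":
            sign = "+" if self.intron_offset > 0 else "-"
            return f"c.{self.c_position}{sign}{abs(self.intron_offset)}"
        return "non-coding"


def boundary_index(model: GeneModel) -> dict[tuple[int, str], int]:
    """Map (genomic splice position, side) -> exon_id.

    Every exon contributes exactly one ``donor_end`` and one ``acceptor_start``
    entry, in transcript orientation: the donor is the exon's 3' boundary in
    transcript direction regardless of genomic strand.  The mapping is a
    bijection (guaranteed by the model's non-overlap/gap validation).
    """
    index: dict[tuple[int, str], int] = {}
    for exon in model.exons:
        index[(model.donor_pos(exon), "donor_end")] = exon.exon_id
        index[(model.acceptor_pos(exon), "acceptor_start")] = exon.exon_id
    if len(index) != 2 * len(model.exons):
        raise ModelValidationError("splice boundaries collide across exons")
    return index


def _cumulative_coding(model: GeneModel) -> dict[int, int]:
    """Coding nucleotides in all exons strictly 5' of each exon."""
    cum: dict[int, int] = {}
    total = 0
    for exon in model.exons:
        cum[exon.exon_id] = total
        total += exon.coding_length
    return cum


def _exon_offset(model: GeneModel, exon: Exon, pos: int) -> int:
    """0-based offset of pos within the exon, in transcript orientation."""
    if model.strand == "+":
        return pos - exon.genomic_start
    return exon.genomic_end - 1 - pos


def genomic_to_cds(model: GeneModel, genomic_pos: int) -> CdsPosition:
    """Map a genomic position to a c.-position within the metatranscript CDS.

    Exonic coding positions return ``c.N`` (1-based).  Positions in noncoding
    exons (or past an exon's coding portion) return ``non-coding``.  Intronic
    positions return an HGVS-like anchored label: ``c.N-k`` when the position
    is nearer the downstream acceptor (N = first coding base of the downstream
    exon), ``c.N+k`` when nearer the upstream donor.  Within partially coding
    exons the coding portion is taken to occupy the transcript-5' end.
    """
    lo, hi = model.span
    if not lo <= genomic_pos < hi:
        raise ValueError(
            f"position {genomic_pos} outside gene span [{lo}, {hi}) of {model.gene_name}"
        )
    cum = _cumulative_coding(model)
    for exon in model.exons:
        if exon.genomic_start <= genomic_pos < exon.genomic_end:
            off = _exon_offset(model, exon, genomic_pos)
            if exon.coding_length == 0 or off >= exon.coding_length:
                return CdsPosition("non_coding")
            return CdsPosition("coding", c_position=cum[exon.exon_id] + off + 1)

    # intronic: locate the flanking exon pair in transcript order
    for up, down in zip(model.exons, model.exons[1:]):
        if model.strand == "+":
            in_intron = up.genomic_end <= genomic_pos < down.genomic_start
            dist_from_donor = genomic_pos - up.genomic_end + 1
            dist_to_acceptor = down.genomic_start - genomic_pos
        else:
            in_intron = down.genomic_end <= genomic_pos < up.genomic_start
            dist_from_donor = up.genomic_start - genomic_pos
            dist_to_acceptor = genomic_pos - down.genomic_end + 1
        if not in_intron:
            continue
        if dist_to_acceptor <= dist_from_donor:
            anchor = cum[down.exon_id] + 1  # first coding base of downstream exon
            return CdsPosition("intronic", c_position=anchor, intron_offset=-dist_to_acceptor)
        anchor = cum[up.exon_id] + up.coding_length  # last coding base upstream
        return CdsPosition("intronic", c_position=anchor, intron_offset=dist_from_donor)
    raise AssertionError("unreachable: position inside span but in no exon/intron")


# -- I/O ----------------------------------------------------------------------


def _exon_from_row(row: Mapping[str, str], lineno: int) -> Exon:
    try:
        repeat = row.get("repeat_block", "") or None
        if repeat in (".", "NA", "-"):
            repeat = None
        coding = row.get("coding_length", "")
        return Exon(
            exon_id=int(row["exon_id"]),
            genomic_start=int(row["start"]),
            genomic_end=int(row["end"]),
            strand=row["strand"],
            exon_class=row.get("class") or "canonical",
            repeat_block=repeat,
            coding_length=int(coding) if coding not in ("", ".", None) else None,
        )
    except (KeyError, ValueError, TypeError) as exc:
        if isinstance(exc, ModelValidationError):
            raise
        raise GeneModelError(f"bad exon-table row at line {lineno}: {exc}") from exc


def read_exon_table(
    path: str | Path,
    gene_name: str = "gene",
    isoforms: Iterable[Isoform] | None = None,
    reference_isoform: str | None = None,
) -> GeneModel:
    """Read the plain TSV exon-table dialect into a GeneModel.

    Columns: exon_id, chrom, start, end, strand, class, repeat_block,
    coding_length (missing class defaults to canonical; repeat_block and
    coding_length may be '.').
    """
    exons: list[Exon] = []
    chrom: str | None = None
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or "exon_id" not in reader.fieldnames:
            raise GeneModelError(f"{path}: not an exon table (missing header)")
        for lineno, row in enumerate(reader, start=2):
            exon = _exon_from_row(row, lineno)
            if chrom is None:
                chrom = row["chrom"]
            elif row["chrom"] != chrom:
                raise GeneModelError(f"{path}: multiple chromosomes in one gene")
            exons.append(exon)
    if not exons:
        raise GeneNotFoundError(f"{path}: empty exon table")
    return GeneModel(
        gene_name=gene_name,
        chromosome=chrom,
        strand=exons[0].strand,
        exons=exons,
        isoforms=list(isoforms or []),
        reference_isoform=reference_isoform,
    )


def write_exon_table(model: GeneModel, path: str | Path) -> None:
    """Write the model in the TSV dialect read by :func:`read_exon_table`."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(EXON_TABLE_COLUMNS)
        for e in model.exons:
            writer.writerow(
                [
                    e.exon_id,
                    model.chromosome,
                    e.genomic_start,
                    e.genomic_end,
                    e.strand,
                    e.exon_class,
                    e.repeat_block or ".",
                    e.coding_length,
                ]
            )


def _load_from_gff(path: str | Path, gene_name: str) -> GeneModel:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    gene = None
    for feature in db.all_features():
        attrs = {k.lower(): v for k, v in feature.attributes.items()}
        names = set()
        for key in ("gene_id", "gene_name", "name", "id", "gene"):
            names.update(attrs.get(key, []))
        if feature.featuretype in ("gene", "transcript", "mRNA") and gene_name in names:
            gene = feature
            break
    if gene is None:
        raise GeneNotFoundError(f"gene {gene_name!r} not found in {path}")
    exon_feats = sorted(
        db.children(gene, featuretype="exon"), key=lambda f: f.start
    )
    if not exon_feats:
        raise GeneNotFoundError(f"gene {gene_name!r} has no exon features in {path}")
    if gene.strand == "-":
        exon_feats = exon_feats[::-1]
    exons = [
        Exon(
            exon_id=i,
            genomic_start=f.start - 1,  # GFF is 1-based inclusive
            genomic_end=f.end,
            strand=f.strand,
        )
        for i, f in enumerate(exon_feats, start=1)
    ]
    return GeneModel(
        gene_name=gene_name,
        chromosome=exon_feats[0].seqid,
        strand=exon_feats[0].strand,
        exons=exons,
    )


def load_gene_model(annotation_source: str | Path, gene_name: str = "gene") -> GeneModel:
    """Load a GeneModel from a GTF/GFF file or a plain exon table.

    Dispatch is by extension: ``.gtf``/``.gff``/``.gff3`` go through gffutils,
    anything else is read as the TSV exon-table dialect.  Ordinal exon ids are
    assigned in transcript orientation; class flags default to canonical when
    the source carries none.
    """
    suffix = Path(annotation_source).suffix.lower()
    if suffix in (".gtf", ".gff", ".gff3"):
        return _load_from_gff(annotation_source, gene_name)
    return read_exon_table(annotation_source, gene_name=gene_name)
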