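# Methods

## Coordinate conventions and the gene model

Internally every interval is 0-based half-open on the genome; user-facing
coding positions are 1-based HGVS-like c.-labels (`c.213`, `c.1399-3`).
Exon ordinals are assigned 5′→3′ in transcript orientation, so exon 1 of a
minus-strand gene is the exon with the largest genomic coordinate. All
classification logic runs in transcript orientation after a single
normalisation step (the `t()` transform negates genomic coordinates on the
minus strand), which keeps every downstream module strand-agnostic. Exon
ordinals always follow the metatranscript numbering, even for isoforms that
skip exons, because that is how complex genes of this kind are discussed and
reported.

Models load from GTF/GFF (via gffutils) or from a plain exon-table TSV.
Validation rejects overlapping exons, exons sharing a splice coordinate
(which would make the boundary index ambiguous), and exon ordinals that
contradict the strand. `coding_length` defaults to the full exon length for
coding classes and 0 for noncoding; for partially coding exons the coding
portion is taken to occupy the transcript-5′ end of the exon — a documented
simplification that matters only for UTR-containing terminal exons, which
the frame and c.-position logic treats conservatively (events touching
noncoding sequence return `not_applicable` / `non-coding` rather than a
guess).

The packaged 364-exon titin-like model (`make_titin_like_model`) is
*synthetic*: it reproduces the metatranscript's structure — exon 1
noncoding, meta-only flags on exons 148, 150, 159–171 and 213–217,
repeat-block labels B1–B9 cycling over exons 172–205, Novex-specific exons
45/46/48, and N2A-like/Novex3-like isoform definitions — but its genomic
coordinates are generated, not the real gene's. It exists so structural
logic (ordinal assignment at scale, isoform junction sets such as 47–50,
flag propagation) can be exercised without any annotation download.

## Junction extraction

Each CIGAR `N` operation is one junction crossing; the intron interval is
computed by walking the reference-consuming operations (M/D/N/=/X) from the
alignment start, so deletions adjacent to an intron still give bit-exact
intervals while insertions and soft clips are ignored. A crossing counts
only when the aligned (M/=/X) blocks on both sides of the `N` span at least
`min_anchor` nucleotides. The default of 8 nt matches common junction-caller
overhang defaults and suppresses spurious 1–2 nt anchors; no minimum mapping
quality, uniqueness or deduplication rule is applied — junction counts are
raw read tallies. Junction strand is taken from the `XS` tag when present
and otherwise resolved against the gene model at classification time.
Malformed records are skipped with a warning and tallied in a diagnostics
object; SAM text without a header is parsed against a header synthesised
from the observed reference names.

## Event classification

For each junction end the nearest annotated boundary of the matching side
(donor ends compare against donor boundaries, acceptor ends against acceptor
boundaries) is found within `max_offset` (default 500 nt — the alternative
site must fall within the flanking exon or near intron; positions farther
from any boundary are not confidently assignable to this gene model and
return `unassigned`). When a position is equidistant from two boundaries the
upstream (transcript-orientation) exon wins; the tie-break is arbitrary but
deterministic and documented. Offsets are signed in transcript orientation
(positive = 3′-ward).

Both ends exact → `canonical_consecutive` if the exon pair is consecutive in
the reference isoform (so a junction like 47–50 is canonical under an
N2A-style reference that lacks the intervening exons), else `exon_skipping`
with the skipped set enumerated over the metatranscript exon list — meta-only
exons count as skipped. One or both ends offset → `alt_donor` /
`alt_acceptor` / `alt_both`. Events whose donor or acceptor exon carries a
repeat-block label are flagged `in_repeated_region` rather than resolved:
multimapping makes counts there unreliable, and the flag leaves the decision
to the caller. `previously_reported` marks junctions whose exon pair is
consecutive in at least one annotated isoform.

### Frame prediction

The net coding-sequence change of an event is

```
delta_nt = donor_offset − acceptor_offset − Σ coding_length(skipped exons)
```

in transcript orientation: a donor extending into the intron retains
sequence (+), an acceptor landing inside its exon removes sequence (−), and
skipped exons are removed entirely. This single expression covers pure
skips (delta = −Σ coding), small alternative-site shifts (an acceptor 3 nt
downstream → −3), and long-range alternative events whose two sites sit in
distant exons. `frame_preserving` is `yes` iff `delta_nt mod 3 == 0`.

## QC filtering

Discovery thresholds are inclusive: a junction passes with ≥ `min_total_reads`
pooled reads (default 1000) **and** detection (count > 0) in ≥ `min_samples`
samples (default 14, against a default 42-sample cohort). Cross-cohort
validation pools the validation cohort's samples and requires strictly more
than 10 reads (`validation_min_reads = 11`); it matches junctions on their
interval, ignoring strand annotation, because cohorts often differ in
strandedness metadata. Unvalidated junctions are returned, not discarded.
Raising any threshold can only shrink the passing set, and
validated/unvalidated partition the QC-passing set — both properties are
tested.

## The inclusion-rate estimator

`I` sums counts of junctions whose donor or acceptor lies at or within the
exon (alternative-site junctions landing inside an exon therefore support
its partial inclusion); `E` sums junctions spanning clear over it, each
multi-exon skip contributing its full count to every exon it spans. `E` is
computed per exon, not shared across blocks of adjacent exons, so adjacent
co-skipped exons can report the same exclusion figure without any special
casing. The rate (I/f)/((I/f)+E) uses f = 2 for internal exons and f = 1
for terminal exons (one flank only); with junction counts proportional to
transcript abundance (I ≈ f·p·d, E ≈ (1−p)·d at depth d) the estimator's
expectation is the true inclusion proportion p up to O(1/d) ratio bias,
which the simulation tests bound at 3 standard errors over 200 replicates.
Reported percentages round half away from zero to integers. Only QC-passing
junction totals enter the table by default; passing unfiltered totals
disables filtering. Exons in repeat blocks are excluded from the usage table
unless opted in, and I = E = 0 yields an explicit `no_data` row, never 0 or
1. Constitutive labels are structural (absence of passing contrary
evidence), not rate cutoffs: an exon with a 98 % rate and a real passing
skip event stays `variable`.

## Splice-site consensus values

The scorer implements min–max-normalised position-frequency scoring: raw
score = sum (default) or product of the observed nucleotides' per-position
frequencies; value = 100·(raw − raw_min)/(raw_max − raw_min) where the
extremes are the matrix's best/worst attainable windows. Windows containing
N or gaps return a first-class `Unpredicted` result. The packaged matrices
are synthetic consensus-frequency estimates in the classic donor 9-mer and
15-position acceptor layouts, with the invariant GT/AG dinucleotides at
probability 1 (asserted at load for the donor). Absolute values are
matrix-version-specific — published web-service tables are proprietary — so
cross-matrix comparisons are meaningless; the supported comparisons are
within one matrix, in particular the alternative-vs-canonical delta.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
junction reads proportional to transcript abundance. Per sample, each
isoform junction's count is drawn Poisson (default) or negative-binomial
(dispersion 0.1, to stress overdispersion) around depth × isoform
proportion; alternative-site junctions are added at depth × usage fraction.
Default study conditions: 42 samples, depth 10⁴ junction-spanning reads per
transcript unit, 86 bp single-end reads with anchors ≥ 8 nt. Ground truth
records each exon's per-sample inclusion probability and each junction's
pooled expected count. Seeds are mandatory; identical seeds give
byte-identical SAM text.

What the generator does **not** emulate: sequencing error, coverage
non-uniformity along transcripts, multimapping in repeated regions,
fragment-length effects, or library-preparation biases. Passing recovery
tests therefore demonstrates estimator correctness under proportional
sampling, not robustness to real-data artefacts — in particular, repeat-
region counts in real data are biased in ways no amount of simulated Poisson
noise reproduces, which is why the usage table excludes those exons by
default.

## Problem sizes

The test and acceptance runs use deliberately small configurations chosen to
make the statistical checks sharp: 3-exon mixture models at depth 10⁴ × 42
samples give pooled junction totals near 4×10⁵, so the 3-standard-error
recovery bands are a few 10⁻⁴ wide and any systematic estimator error would
fail them; oracle-equivalence checks use ~10³ reads and a >10⁴-point
classification grid on a 6-exon model.

## Known limitations

- Isoform-level quantification (EM across isoforms sharing junctions) is out
  of scope; the per-exon statistic is deliberately model-free.
- Phasing of multiple events on one molecule requires long reads and is not
  attempted.
- BAM input is supported only through pysam's text/binary handling of
  `AlignmentFile`; the package never decodes alignments itself.
- The c.-position mapper assumes wholly coding internal exons (the usual
  case for deep CDS positions); partial-coding placement is a convention,
  not an annotation.
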