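"""Build a titin-like gene model and query its geometry.

The model is a 364-exon minus-strand metatranscript layout with synthetic
coordinates: exon 1 noncoding, meta-only exons flagged, repeat blocks B1-B9
over exons 172-205.  c.-positions are 1-based within the concatenated CDS.
"""

from titinsplice import boundary_index, genomic_to_cds, make_titin_like_model

model = make_titin_like_model()
print(f"{model.gene_name}: {len(model.exons)} exons on strand {model.strand}")
print(f"coding exons: {sum(e.coding_length > 0 for e in model.exons)}")
print(f"meta-only exons: {sum(e.exon_class == 'meta_only' for e in model.exons)}")
print(f"repeat-block exons: {sum(e.repeat_block is not None for e in model.exons)}")

index = boundary_index(model)
print(f"boundary index: {len(index)} splice positions (2 per exon)")

# first coding base of exon 2 is c.1; a base 3 nt into the intron upstream of
# an exon's acceptor reports an HGVS-like intronic anchor
exon2 = model.exon(2)
first_coding = exon2.genomic_end - 1  # minus strand: transcript 5' end is the high coordinate
print(f"first base of exon 2 -> {genomic_to_cds(model, first_coding)}")
exon9 = model.exon(9)
intronic = exon9.genomic_end + 2  # 3 nt before the acceptor in transcript direction
print(f"3 nt upstream of exon 9 acceptor -> {genomic_to_cds(model, intronic)}")
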