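"""Classify junctions into the splicing-event taxonomy with frame prediction.

A 14-exon toy gene mimics the exon-11 skip pattern: high-count junctions
10-12 / 10-13 / 10-14 bypass exon 11, each a frame-preserving skipping event
because the skipped coding lengths are multiples of 3.
"""

from titinsplice import Junction, classify_all, event_table
from titinsplice.synthetic_data import SimConfig, make_toy_gene

model = make_toy_gene(SimConfig(n_exons=14, seed=4))


def junction(donor_exon: int, acceptor_exon: int, shift: int = 0) -> Junction:
    donor = model.donor_pos(model.exon(donor_exon))
    acceptor = model.acceptor_pos(model.exon(acceptor_exon)) + shift
    return Junction(model.chromosome, min(donor, acceptor), max(donor, acceptor), "+")


junctions = [
    junction(10, 11),            # canonical
    junction(10, 12),            # skips exon 11
    junction(10, 13),            # skips 11-12
    junction(10, 14),            # skips 11-13
    junction(5, 6, shift=4),     # alternative acceptor 4 nt inside exon 6
]
events = classify_all(junctions, model)
frame = event_table(events, model)
print(frame[["label", "category", "skipped_exons", "frame_preserving", "frame_delta_nt"]])
print()
print("delta_nt is the net coding-sequence change; multiples of 3 preserve the frame")
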