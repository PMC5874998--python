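"""Score donor splice-site windows on the 0-100 consensus-value scale.

The donor window is the last 3 exonic + first 6 intronic nucleotides; the
invariant GT dinucleotide occupies intronic positions +1/+2.  Scores are
min-max normalised per matrix, so 100 = per-position consensus and 0 =
anti-consensus; the alt-vs-canonical delta is the comparable quantity.
"""

from titinsplice import compare_sites, consensus_value, default_donor_matrix

matrix = default_donor_matrix()
for name, window in [
    ("consensus", "CAGGTAAGT"),
    ("typical", "AAGGTAAGT"),
    ("weak", "TTGGTCTCC"),
    ("ambiguous", "NAGGTAAGT"),
]:
    print(f"{name:10s} {window}: {consensus_value(window, matrix)}")

comparison = compare_sites("CAGGTACGT", "AAGGTAAGT", matrix)
print(f"\nalt {comparison.alt} vs canonical {comparison.canonical} "
      f"-> delta {comparison.delta:+.2f}")
print("a small negative delta means the alternative donor is nearly as strong "
      "as the canonical one, consistent with genuine use")
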