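"""Packaged mutagenesis primer sequences for the BS1/BS2 site-swap reporter
constructs (overlap-extension PCR primers that introduce the mouse p53
binding sites into the human PIERCE1 promoter). Shipped as fixtures so the
scanner and construct logic can be exercised on real printed sequences."""

BS1_FORWARD = (
    "AACAGGACGCCGCCTTGCCGCAGCAGGCACAGACTTGATCGCTTCTCCTCCAGGCACAATGT"
)
BS1_REVERSE = (
    "GAGGAGAAGCGATCAAGTCTGTGCCTGCTGCGGCAAGGCGGCGTCCTGTTGCCAAGCGACGG"
)
BS2_FORWARD = "GGCAGGTTCCAGACTTGCCTACAGCTAGCTGCCCGGCCCACGCGCGGCGCCTT"
BS2_REVERSE = "GTGGGCCGGGCAGCTAGCTGTAGGCAAGTCTGGAACCTGCCGGGCGACTCCCCAAG"

ALL_PRIMERS = {
    "BS1_forward": BS1_FORWARD,
    "BS1_reverse": BS1_REVERSE,
    "BS2_forward": BS2_FORWARD,
    "BS2_reverse": BS2_REVERSE,
}
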