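"""Encode one 41-bp centred-cytosine window under all seven encodings.

Prints the dimension and a few leading values of each feature vector; the
dimensions (1364, 200, 164, 64, 164, 240, 704) are fixed properties of the
encodings, and each vector is a deterministic function of the sequence.
"""

from mc4pred import DnaSample, ENCODING_ORDER, encode_sample

window = DnaSample("example", "CCCTAATTACTCCTCCCGAACTTGTCCTTTTTTACCTAGCA")
print(f"sequence ({len(window.seq)} nt, centre base {window.seq[20]!r}):")
print(f"  {window.seq}\n")

for name in ENCODING_ORDER:
    vec = encode_sample(window, name)
    head = ", ".join(f"{v:.4f}" for v in vec[:5])
    print(f"{name:>8}  dim {vec.shape[0]:>4}   [{head}, ...]")

print(
    "\nEach row is one encoding of the same window: k-mer composition,"
    "\ndinucleotide binary + local dinucleotide frequency, chemical-property"
    "\nbits + density, EIIP-weighted trinucleotide frequencies, one-hot"
    "\nprofile, and di-/tri-nucleotide physicochemical property weightings."
)
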