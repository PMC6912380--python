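"""Independent brute-force reference implementations of the encodings.

Written directly from the encoding definitions, with no imports from the
package's encoders, so they can serve as oracles in equivalence tests.
"""

import itertools

BASES = "ACGT"


def _all_kmers(k):
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def brute_kmer(seq):
    out = []
    for k in range(1, 6):
        windows = [seq[i:i + k] for i in range(len(seq) - k + 1)]
        for mer in _all_kmers(k):
            out.append(windows.count(mer) / len(windows))
    return out


def brute_bpf(seq):
    codes = {"A": [1, 0, 0, 0], "T": [0, 1, 0, 0], "G": [0, 0, 1, 0], "C": [0, 0, 0, 1]}
    out = []
    for base in seq:
        out.extend(codes[base])
    return [float(x) for x in out]


def brute_eiip(seq, eiip):
    windows = [seq[i:i + 3] for i in range(len(seq) - 2)]
    out = []
    for mer in _all_kmers(3):
        weight = eiip[mer[0]] + eiip[mer[1]] + eiip[mer[2]]
        out.append(weight * windows.count(mer) / len(windows))
    return out


def brute_dpe(seq):
    base_code = {"A": [0, 0], "C": [1, 0], "G": [1, 1], "T": [0, 1]}
    out = []
    for i in range(len(seq) - 1):
        out.extend(base_code[seq[i]] + base_code[seq[i + 1]])
    return [float(x) for x in out]


def brute_lpdf(seq):
    out = []
    for j in range(2, len(seq) + 1):
        dinuc = seq[j - 2:j]
        prefix = seq[:j]
        count = sum(1 for i in range(len(prefix) - 1) if prefix[i:i + 2] == dinuc)
        out.append(count / j)
    return out


def brute_rfhc(seq):
    chem = {"A": [1, 1, 1], "T": [0, 1, 0], "G": [1, 0, 0], "C": [0, 0, 1]}
    out = []
    for j in range(1, len(seq) + 1):
        base = seq[j - 1]
        density = seq[:j].count(base) / j
        out.extend(chem[base] + [density])
    return out


def brute_property(seq, table, k):
    # table: dict oligomer -> list of property values
    windows = [seq[i:i + k] for i in range(len(seq) - k + 1)]
    out = []
    for mer in _all_kmers(k):
        freq = windows.count(mer) / len(windows)
        out.extend(value * freq for value in table[mer])
    return out


def random_valid_window(rng, length=41, center=20):
    seq = list(rng.choice(list(BASES), size=length))
    seq[center] = "C"
    return "".join(seq)
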