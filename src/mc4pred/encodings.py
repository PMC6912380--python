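"""The seven fixed-dimension sequence feature encodings.

Each encoder maps one 41-nt centred-cytosine window to a real vector of a
fixed, documented dimension:

================  ====  =======================================================
name              dim   summary
================  ====  =======================================================
Kmer              1364  k-mer occurrence frequencies, k = 1..5, per-k normalised
M6AMRFS            200  dinucleotide binary encoding (DPE, 160) + local
                        position-specific dinucleotide frequency (LPDF, 40)
RFHC               164  per-position chemical-property bits + cumulative density
EIIP                64  trinucleotide frequencies weighted by summed
                        electron-ion interaction pseudopotentials
BPF                164  per-position one-hot profile (A,T,G,C order)
DPCP               240  dinucleotide frequencies x 15 physicochemical properties
TPCP               704  trinucleotide frequencies x 11 physicochemical properties
================  ====  =======================================================

All encoders are deterministic pure functions of the sequence (plus, for
DPCP/TPCP, a property table). K-mer axes are ordered lexicographically with
A < C < G < T. Oligomer frequencies use overlapping windows: a 41-mer holds
40 dinucleotides and 39 trinucleotides.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import DnaSample, FeatureMatrix, ENCODING_DIMS
from .tables import (
    BPF_ORDER,
    CHEM_CODE,
    DPE_BASE_CODE,
    EIIP_VALUES,
    TRINUCLEOTIDES,
    PropertyTableError,
    default_dinucleotide_table,
    default_trinucleotide_table,
    kmers,
)

#: Canonical encoding order (presentation order used throughout the package).
ENCODING_ORDER = ("Kmer", "M6AMRFS", "RFHC", "EIIP", "BPF", "DPCP", "TPCP")

_KMER_RANGE = range(1, 6)
_KMER_INDEX = {k: {mer: i for i, mer in enumerate(kmers(k))} for k in _KMER_RANGE}
_TRINUC_INDEX = {mer: i for i, mer in enumerate(TRINUCLEOTIDES)}


def _as_seq(s: "DnaSample | str") -> str:
    return s.seq if isinstance(s, DnaSample) else str(s).upper()


def _kmer_counts(seq: str, k: int) -> np.ndarray:
    counts = np.zeros(4 ** k)
    index = _KMER_INDEX[k]
    for i in range(len(seq) - k + 1):
        counts[index[seq[i:i + k]]] += 1
    return counts


def encode_kmer(s: "DnaSample | str") -> np.ndarray:
    """k-mer composition, k = 1..5: concatenated per-k frequency blocks.

    Within each block the entry for a k-mer is count / (N - k + 1), so each
    block sums to one; blocks are ordered k = 1..5, entries lexicographic.
    """
    seq = _as_seq(s)
    blocks = [_kmer_counts(seq, k) / (len(seq) - k + 1) for k in _KMER_RANGE]
    return np.concatenate(blocks)


def encode_bpf(s: "DnaSample | str") -> np.ndarray:
    """Binary profile feature: per-position one-hot code in (A, T, G, C) order."""
    seq = _as_seq(s)
    out = np.zeros(4 * len(seq))
    for j, base in enumerate(seq):
        out[4 * j + BPF_ORDER.index(base)] = 1.0
    return out


def encode_eiip(s: "DnaSample | str", table: dict[str, float] | None = None) -> np.ndarray:
    """EIIP of trinucleotides: (EIIP_a + EIIP_b + EIIP_c) x f_abc per trinucleotide."""
    seq = _as_seq(s)
    eiip = EIIP_VALUES if table is None else table
    counts = _kmer_counts(seq, 3)
    freqs = counts / (len(seq) - 2)
    weights = np.array(
        [eiip[t[0]] + eiip[t[1]] + eiip[t[2]] for t in TRINUCLEOTIDES]
    )
    return weights * freqs


def encode_dpe(s: "DnaSample | str") -> np.ndarray:
    """Dinucleotide binary encoding: 4 bits per overlapping dinucleotide.

    Each dinucleotide's 4-bit code is the concatenation of per-base 2-bit
    codes A=(0,0), C=(1,0), G=(1,1), T=(0,1).
    """
    seq = _as_seq(s)
    out = np.empty(4 * (len(seq) - 1))
    for j in range(len(seq) - 1):
        out[4 * j: 4 * j + 2] = DPE_BASE_CODE[seq[j]]
        out[4 * j + 2: 4 * j + 4] = DPE_BASE_CODE[seq[j + 1]]
    return out


def encode_lpdf(s: "DnaSample | str") -> np.ndarray:
    """Local position-specific dinucleotide frequency.

    For j = 2..N (1-based), f_j = (occurrences of the dinucleotide ending at
    position j within the length-j prefix) / j.
    """
    seq = _as_seq(s)
    out = np.empty(len(seq) - 1)
    for j in range(2, len(seq) + 1):
        dinuc = seq[j - 2:j]
        prefix = seq[:j]
        count = sum(1 for i in range(j - 1) if prefix[i:i + 2] == dinuc)
        out[j - 2] = count / j
    return out


def encode_m6amrfs(s: "DnaSample | str") -> np.ndarray:
    """DPE (160) followed by LPDF (40): the combined 200-dim descriptor."""
    return np.concatenate([encode_dpe(s), encode_lpdf(s)])


def encode_rfhc(s: "DnaSample | str") -> np.ndarray:
    """Ring-function-hydrogen-chemical encoding: (a, b, c, d_j) per position.

    (a, b, c) are the purine / weak-H-bond / amino indicator bits of the base;
    d_j is the cumulative density of that base in the length-j prefix.
    """
    seq = _as_seq(s)
    out = np.empty(4 * len(seq))
    seen = {b: 0 for b in "ACGT"}
    for j, base in enumerate(seq, start=1):
        seen[base] += 1
        out[4 * (j - 1): 4 * (j - 1) + 3] = CHEM_CODE[base]
        out[4 * (j - 1) + 3] = seen[base] / j
    return out


def _property_encode(seq: str, table: pd.DataFrame, k: int, n_props: int) -> np.ndarray:
    if table.shape != (4 ** k, n_props):
        raise PropertyTableError(
            f"expected a {4 ** k} x {n_props} table, got {table.shape[0]} x {table.shape[1]}"
        )
    counts = _kmer_counts(seq, k)
    freqs = counts / (len(seq) - k + 1)
    # oligomer-major, property-minor
    return (table.to_numpy(dtype=float) * freqs[:, None]).ravel()


def encode_dpcp(s: "DnaSample | str", table: pd.DataFrame | None = None) -> np.ndarray:
    """Dinucleotide physicochemical properties: property value x f_NN, 16 x 15."""
    if table is None:
        table = default_dinucleotide_table()
    return _property_encode(_as_seq(s), table, 2, 15)


def encode_tpcp(s: "DnaSample | str", table: pd.DataFrame | None = None) -> np.ndarray:
    """Trinucleotide physicochemical properties: property value x f_NNN, 64 x 11."""
    if table is None:
        table = default_trinucleotide_table()
    return _property_encode(_as_seq(s), table, 3, 11)


_SIMPLE_ENCODERS = {
    "Kmer": encode_kmer,
    "M6AMRFS": encode_m6amrfs,
    "RFHC": encode_rfhc,
    "EIIP": encode_eiip,
    "BPF": encode_bpf,
    "DPE": encode_dpe,
    "LPDF": encode_lpdf,
}


def encode_sample(
    s: "DnaSample | str",
    encoding: str,
    dpcp_table: pd.DataFrame | None = None,
    tpcp_table: pd.DataFrame | None = None,
) -> np.ndarray:
    """Encode one sample under a named encoding; dimension is asserted."""
    if encoding in _SIMPLE_ENCODERS:
        vec = _SIMPLE_ENCODERS[encoding](s)
    elif encoding == "DPCP":
        vec = encode_dpcp(s, dpcp_table)
    elif encoding == "TPCP":
        vec = encode_tpcp(s, tpcp_table)
    else:
        raise KeyError(f"unknown encoding {encoding!r}")
    expected = ENCODING_DIMS[encoding]
    if vec.shape != (expected,):
        raise AssertionError(
            f"{encoding} produced dimension {vec.shape[0]}, expected {expected}"
        )
    return vec


def encode_samples(
    samples: Sequence[DnaSample],
    encoding: str,
    dpcp_table: pd.DataFrame | None = None,
    tpcp_table: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Encode a sample list into a :class:`FeatureMatrix` (rows in input order)."""
    if encoding == "DPCP" and dpcp_table is None:
        dpcp_table = default_dinucleotide_table()
    if encoding == "TPCP" and tpcp_table is None:
        tpcp_table = default_trinucleotide_table()
    rows = [
        encode_sample(s, encoding, dpcp_table=dpcp_table, tpcp_table=tpcp_table)
        for s in samples
    ]
    values = (
        np.vstack(rows) if rows else np.empty((0, ENCODING_DIMS[encoding]))
    )
    return FeatureMatrix([s.id for s in samples], encoding, values)


def encode_all(
    samples: Sequence[DnaSample],
    dpcp_table: pd.DataFrame | None = None,
    tpcp_table: pd.DataFrame | None = None,
    encodings: Iterable[str] = ENCODING_ORDER,
) -> dict[str, FeatureMatrix]:
    """Encode samples under every encoding (canonical order), tables shared."""
    if dpcp_table is None:
        dpcp_table = default_dinucleotide_table()
    if tpcp_table is None:
        tpcp_table = default_trinucleotide_table()
    return {
        name: encode_samples(samples, name, dpcp_table=dpcp_table, tpcp_table=tpcp_table)
        for name in encodings
    }
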