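"""Lookup tables used by the sequence encodings.

Holds the electron-ion interaction pseudopotentials (EIIP), the three-bit
nucleotide chemical-property codes, the two-bit per-base code behind the
dinucleotide binary encoding, and default dinucleotide (16 x 15) and
trinucleotide (64 x 11) physicochemical property tables.

The default property tables are documented substitutes assembled from
standard, exactly-specified quantities — unified nearest-neighbour
thermodynamics, crystallographic base-step geometry averages, and
compositional descriptors — min-max normalised to [0, 1]. Users reproducing a
specific published property set should load their own table with
:func:`load_property_table`; every encoder accepts a custom table.
"""

from __future__ import annotations

import itertools
import os

import numpy as np
import pandas as pd

#: Electron-ion interaction pseudopotential per nucleotide (dimensionless).
EIIP_VALUES = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}

#: Chemical-property bits (purine ring count, weak H-bond, amino group).
CHEM_CODE = {
    "A": (1, 1, 1),
    "T": (0, 1, 0),
    "G": (1, 0, 0),
    "C": (0, 0, 1),
}

#: Per-base 2-bit code whose pairwise concatenation yields the dinucleotide
#: binary encoding; it is the unique concatenative code consistent with the
#: reference tuples AT=(0,0,0,1), AA=(0,0,0,0), GG=(1,1,1,1), AC=(0,0,1,0).
DPE_BASE_CODE = {"A": (0, 0), "C": (1, 0), "G": (1, 1), "T": (0, 1)}

#: One-hot order for the binary profile feature: A, T, G, C.
BPF_ORDER = "ATGC"

ALPHABET = "ACGT"


def kmers(k: int) -> list[str]:
    """All k-mers over ACGT in lexicographic order (A < C < G < T)."""
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


DINUCLEOTIDES = kmers(2)
TRINUCLEOTIDES = kmers(3)

# Unified nearest-neighbour thermodynamics (enthalpy kcal/mol, entropy
# cal/mol/K, free energy at 37C kcal/mol), given 5'->3' per dinucleotide step.
_NN_DH = {
    "AA": -7.9, "AT": -7.2, "TA": -7.2, "CA": -8.5, "GT": -8.4,
    "CT": -7.8, "GA": -8.2, "CG": -10.6, "GC": -9.8, "GG": -8.0,
}
_NN_DS = {
    "AA": -22.2, "AT": -20.4, "TA": -21.3, "CA": -22.7, "GT": -22.4,
    "CT": -21.0, "GA": -22.2, "CG": -27.2, "GC": -24.4, "GG": -19.9,
}
_NN_DG = {
    "AA": -1.00, "AT": -0.88, "TA": -0.58, "CA": -1.45, "GT": -1.44,
    "CT": -1.28, "GA": -1.30, "CG": -2.17, "GC": -2.24, "GG": -1.84,
}

# Crystallographic base-step geometry averages (degrees / Angstrom).
_TWIST = {
    "AA": 35.1, "AC": 31.5, "AG": 31.9, "AT": 29.3,
    "CA": 37.3, "CC": 32.9, "CG": 36.1, "CT": 31.9,
    "GA": 36.3, "GC": 33.6, "GG": 32.9, "GT": 31.5,
    "TA": 37.8, "TC": 36.3, "TG": 37.3, "TT": 35.1,
}
_ROLL = {
    "AA": 0.7, "AC": 0.7, "AG": 4.5, "AT": 1.1,
    "CA": 4.7, "CC": 3.6, "CG": 5.4, "CT": 4.5,
    "GA": 1.9, "GC": 0.3, "GG": 3.6, "GT": 0.7,
    "TA": 3.3, "TC": 1.9, "TG": 4.7, "TT": 0.7,
}
_TILT = {
    "AA": -1.4, "AC": -0.1, "AG": -1.7, "AT": 0.0,
    "CA": 0.5, "CC": -0.1, "CG": 0.0, "CT": 1.7,
    "GA": -1.5, "GC": 0.0, "GG": 0.1, "GT": 0.1,
    "TA": 0.0, "TC": 1.5, "TG": -0.5, "TT": 1.4,
}
_SHIFT = {
    "AA": -0.03, "AC": 0.13, "AG": 0.09, "AT": 0.0,
    "CA": 0.09, "CC": 0.05, "CG": 0.0, "CT": -0.09,
    "GA": -0.28, "GC": 0.0, "GG": -0.05, "GT": -0.13,
    "TA": 0.0, "TC": 0.28, "TG": -0.09, "TT": 0.03,
}
_SLIDE = {
    "AA": -0.08, "AC": -0.58, "AG": -0.25, "AT": -0.59,
    "CA": 0.53, "CC": -0.22, "CG": 0.41, "CT": -0.25,
    "GA": 0.09, "GC": -0.38, "GG": -0.22, "GT": -0.58,
    "TA": 0.05, "TC": 0.09, "TG": 0.53, "TT": -0.08,
}
_RISE = {
    "AA": 3.27, "AC": 3.36, "AG": 3.34, "AT": 3.31,
    "CA": 3.33, "CC": 3.42, "CG": 3.39, "CT": 3.34,
    "GA": 3.37, "GC": 3.40, "GG": 3.42, "GT": 3.36,
    "TA": 3.42, "TC": 3.37, "TG": 3.33, "TT": 3.27,
}


def _complement(dinuc: str) -> str:
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    return comp[dinuc[1]] + comp[dinuc[0]]


def _nn_lookup(table: dict[str, float], dinuc: str) -> float:
    # nearest-neighbour parameters are symmetric under reverse complement
    return table[dinuc] if dinuc in table else table[_complement(dinuc)]


def _raw_dinucleotide_table() -> pd.DataFrame:
    rows = {}
    for nn in DINUCLEOTIDES:
        gc = sum(b in "GC" for b in nn) / 2.0
        purine = sum(b in "AG" for b in nn) / 2.0
        keto = sum(b in "GT" for b in nn) / 2.0
        dh = _nn_lookup(_NN_DH, nn)
        ds = _nn_lookup(_NN_DS, nn)
        dg = _nn_lookup(_NN_DG, nn)
        rows[nn] = {
            "Twist": _TWIST[nn],
            "Tilt": _TILT[nn],
            "Roll": _ROLL[nn],
            "Shift": _SHIFT[nn],
            "Slide": _SLIDE[nn],
            "Rise": _RISE[nn],
            "Enthalpy": dh,
            "Entropy": ds,
            "FreeEnergy": dg,
            # melting-point proxy of the isolated step (Kelvin scale shifted)
            "MeltStability": dh * 1000.0 / ds,
            "StackingStability": dh - dg,
            "GCContent": gc,
            "PurineContent": purine,
            "KetoContent": keto,
            "Bendability": (abs(_ROLL[nn]) + abs(_TILT[nn])) / 2.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[DINUCLEOTIDES]


def _minmax(frame: pd.DataFrame) -> pd.DataFrame:
    lo, hi = frame.min(axis=0), frame.max(axis=0)
    span = (hi - lo).replace(0.0, 1.0)
    return (frame - lo) / span


def default_dinucleotide_table() -> pd.DataFrame:
    """Default 16 x 15 dinucleotide property table, min-max normalised to [0, 1]."""
    return _minmax(_raw_dinucleotide_table())


def default_trinucleotide_table() -> pd.DataFrame:
    """Default 64 x 11 trinucleotide property table, normalised to [0, 1].

    Constructed by averaging the two overlapping dinucleotide steps of each
    trinucleotide over eleven of the dinucleotide properties, then min-max
    normalising — a smooth, exactly-reproducible stand-in for published
    trinucleotide sets.
    """
    raw = _raw_dinucleotide_table()
    cols = [
        "Twist", "Tilt", "Roll", "Shift", "Slide", "Rise",
        "Enthalpy", "Entropy", "FreeEnergy", "GCContent", "Bendability",
    ]
    rows = {
        nnn: (raw.loc[nnn[:2], cols] + raw.loc[nnn[1:], cols]) / 2.0
        for nnn in TRINUCLEOTIDES
    }
    return _minmax(pd.DataFrame.from_dict(rows, orient="index").loc[TRINUCLEOTIDES])


class PropertyTableError(ValueError):
    """A property table violates its shape or value contract."""


def validate_property_table(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Check an oligomer property table (k=2 dinucleotide, k=3 trinucleotide).

    Requires every k-mer over ACGT exactly once (rows are re-ordered
    lexicographically), at least one property column, and all values in
    [0, 1]. Returns the re-ordered table.
    """
    expected = kmers(k)
    index = [str(i).upper() for i in table.index]
    if sorted(index) != sorted(expected):
        raise PropertyTableError(
            f"table must index all {len(expected)} {k}-mers exactly once"
        )
    table = table.copy()
    table.index = index
    table = table.loc[expected]
    if table.shape[1] < 1:
        raise PropertyTableError("table has no property columns")
    values = table.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise PropertyTableError("table contains missing values")
    if values.min() < 0.0 or values.max() > 1.0:
        raise PropertyTableError("table values must lie in [0, 1] (normalise first)")
    return table


def load_property_table(path: str | os.PathLike, k: int) -> pd.DataFrame:
    """Load a user property table: delimited text, first column the oligomer,
    remaining columns properties, header row required."""
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return validate_property_table(frame, k)
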