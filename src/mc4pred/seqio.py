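"""Reading, writing and validating fixed-length DNA samples and feature matrices.

The atomic data unit is a 41-nt window over {A,C,G,T} whose central base
(1-based position 21) is a cytosine — the candidate methylation site. Samples
travel as FASTA; feature matrices as TSV with a header row.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

WINDOW_LENGTH = 41
#: 0-based index of the candidate cytosine (1-based position 21).
CENTER_INDEX = 20
ALPHABET = "ACGT"

POSITIVE = "4mC"
NEGATIVE = "non-4mC"

#: Fixed dimensions of every named encoding (asserted throughout the package).
ENCODING_DIMS = {
    "Kmer": 1364,
    "M6AMRFS": 200,
    "RFHC": 164,
    "EIIP": 64,
    "BPF": 164,
    "DPCP": 240,
    "TPCP": 704,
    "DPE": 160,
    "LPDF": 40,
    "PF28": 28,
}


class ValidationError(ValueError):
    """A sample violates the 41-nt centred-cytosine data model."""


class FastaParseError(ValueError):
    """Malformed FASTA input."""


@dataclass(frozen=True)
class DnaSample:
    """One 41-nt centred-cytosine window, optionally labelled 4mC / non-4mC."""

    id: str
    seq: str
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if self.label not in (None, POSITIVE, NEGATIVE):
            raise ValidationError(
                f"{self.id}: label must be {POSITIVE!r} or {NEGATIVE!r}, got {self.label!r}"
            )

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE

    def validation_errors(self) -> list[str]:
        """Human-readable list of invariant violations (empty when valid)."""
        problems = []
        if len(self.seq) != WINDOW_LENGTH:
            problems.append(f"length {len(self.seq)} != {WINDOW_LENGTH}")
        bad = sorted(set(self.seq) - set(ALPHABET))
        if bad:
            problems.append(f"non-ACGT characters {bad}")
        if len(self.seq) > CENTER_INDEX and self.seq[CENTER_INDEX] != "C":
            problems.append(
                f"position {CENTER_INDEX + 1} is {self.seq[CENTER_INDEX]!r}, not 'C'"
            )
        return problems

    @property
    def is_valid(self) -> bool:
        return not self.validation_errors()


def validate_samples(samples: Iterable[DnaSample]) -> None:
    """Raise :class:`ValidationError` naming every offending sample id."""
    bad = [(s.id, "; ".join(s.validation_errors())) for s in samples if not s.is_valid]
    if bad:
        detail = ", ".join(f"{sid} ({msg})" for sid, msg in bad)
        raise ValidationError(f"invalid samples: {detail}")


def _parse_label(description: str) -> str | None:
    # labels travel in FASTA headers as "...|label=4mC" / "...|label=non-4mC"
    for token in description.split("|"):
        if token.startswith("label="):
            value = token[len("label="):].strip()
            if value in ("pos", POSITIVE):
                return POSITIVE
            if value in ("neg", NEGATIVE):
                return NEGATIVE
            raise FastaParseError(f"unrecognised label {value!r} in {description!r}")
    return None


def read_fasta(path: str | os.PathLike, strict: bool = True) -> list[DnaSample]:
    """Read 41-nt samples from FASTA, uppercasing sequence letters.

    In strict mode any record violating the data model aborts the read with a
    :class:`ValidationError` listing the offending ids. In non-strict mode
    offenders are skipped; the skipped ids are available on the exception-free
    return path via :func:`read_fasta_report`.
    """
    samples, skipped = read_fasta_report(path, strict=strict)
    return samples


def read_fasta_report(
    path: str | os.PathLike, strict: bool = True
) -> tuple[list[DnaSample], list[str]]:
    """As :func:`read_fasta`, but also return the ids skipped in non-strict mode."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise FastaParseError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records and os.path.getsize(path) > 0:
        with open(path) as fh:
            head = fh.read(1)
        if head != ">":
            raise FastaParseError(f"{path} is not FASTA (does not start with '>')")
    samples: list[DnaSample] = []
    skipped: list[str] = []
    offenders: list[str] = []
    for rec in records:
        name = rec.id.split("|", 1)[0]
        sample = DnaSample(name, str(rec.seq).upper(), _parse_label(rec.description))
        if sample.is_valid:
            samples.append(sample)
        elif strict:
            offenders.append(f"{sample.id} ({'; '.join(sample.validation_errors())})")
        else:
            skipped.append(sample.id)
    if offenders:
        raise ValidationError(f"invalid records in {path}: " + ", ".join(offenders))
    return samples, skipped


def write_fasta(samples: Iterable[DnaSample], path: str | os.PathLike) -> None:
    """Write samples as FASTA, embedding labels as ``|label=`` header tokens."""
    records = []
    for s in samples:
        name = s.id if s.label is None else f"{s.id}|label={s.label}"
        records.append(SeqRecord(Seq(s.seq), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


@dataclass
class FeatureMatrix:
    """A rectangular encoding of a sample list under one named encoding.

    Rows follow ``sample_ids`` order; the column count must equal the
    documented dimension of ``encoding_name``.
    """

    sample_ids: list[str]
    encoding_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"{self.values.shape[0]} rows for {len(self.sample_ids)} sample ids"
            )
        expected = ENCODING_DIMS.get(self.encoding_name)
        if expected is not None and self.values.shape[1] != expected:
            raise ValueError(
                f"{self.encoding_name} expects {expected} columns, got {self.values.shape[1]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column_names(self) -> list[str]:
        return [f"{self.encoding_name}_{i}" for i in range(self.values.shape[1])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="id"),
            columns=self.column_names(),
        )


def write_feature_matrix(m: FeatureMatrix, path: str | os.PathLike) -> None:
    """Write a feature matrix as TSV (header row; one row per sample, led by id)."""
    m.to_frame().to_csv(path, sep="\t", float_format="%.12g")


def read_feature_matrix(path: str | os.PathLike) -> FeatureMatrix:
    """Read a TSV written by :func:`write_feature_matrix`."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.empty and frame.columns.size == 0:
        raise ValueError(f"{path} holds no feature columns")
    first = frame.columns[0]
    encoding_name = first.rsplit("_", 1)[0]
    return FeatureMatrix(
        sample_ids=[str(i) for i in frame.index],
        encoding_name=encoding_name,
        values=frame.to_numpy(dtype=float).reshape(len(frame.index), len(frame.columns)),
    )


def labels_to_array(samples: Sequence[DnaSample]) -> np.ndarray:
    """Binary label vector (1 = 4mC) for labelled samples; error if any unlabelled."""
    missing = [s.id for s in samples if s.label is None]
    if missing:
        raise ValidationError(f"unlabelled samples: {missing[:5]}")
    return np.array([1 if s.is_positive else 0 for s in samples], dtype=int)
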