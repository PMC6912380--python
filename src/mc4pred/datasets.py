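"""Benchmark construction and synthetic labelled data.

Covers redundancy filtering of fixed-length windows by pairwise identity,
cross-class contamination filtering, repeated stratified benchmark /
independent splits, and a seeded generator of synthetic 4mC-like data whose
positives carry upstream C enrichment and downstream T enrichment while
negatives carry leading A runs — the position-specific composition structure
observed around genuine methylation sites.

Identity between two gap-free 41-mers is Hamming identity (matching positions
/ 41). The greedy incremental clustering used here is a deliberate,
documented stand-in for CD-HIT: with fixed-length ungapped windows the two
agree in spirit, though CD-HIT's word-filtered global alignment identity can
differ near the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import (
    ALPHABET,
    CENTER_INDEX,
    NEGATIVE,
    POSITIVE,
    WINDOW_LENGTH,
    DnaSample,
)


def pairwise_identity(a: "DnaSample | str", b: "DnaSample | str") -> float:
    """Fraction of positions at which the two equal-length sequences agree."""
    sa = a.seq if isinstance(a, DnaSample) else a
    sb = b.seq if isinstance(b, DnaSample) else b
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return sum(x == y for x, y in zip(sa, sb)) / len(sa)


def greedy_redundancy_filter(
    samples: Sequence[DnaSample], cutoff: float
) -> list[DnaSample]:
    """Greedy incremental clustering in input order.

    A sample is retained iff its identity to every previously retained sample
    is <= cutoff; output preserves input order, so the retained set is
    pairwise non-redundant at the cutoff.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    kept: list[DnaSample] = []
    for s in samples:
        if all(pairwise_identity(s, r) <= cutoff for r in kept):
            kept.append(s)
    return kept


def cross_set_filter(
    negatives: Sequence[DnaSample],
    positives: Sequence[DnaSample],
    cutoff: float = 0.6,
) -> list[DnaSample]:
    """Drop negatives whose identity to any positive exceeds the cutoff.

    The rule is strictly "greater than": a negative at identity exactly
    ``cutoff`` is retained.
    """
    return [
        n
        for n in negatives
        if all(pairwise_identity(n, p) <= cutoff for p in positives)
    ]


@dataclass(frozen=True)
class SplitPlan:
    """One benchmark / independent partition of a labelled sample collection."""

    repeat_index: int
    benchmark_ids: frozenset[str]
    independent_ids: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if self.benchmark_ids & self.independent_ids:
            raise ValueError("benchmark and independent sets overlap")


def make_splits(
    pos: Sequence[DnaSample],
    neg: Sequence[DnaSample],
    frac: float = 0.8,
    repeats: int = 10,
    seed: int = 0,
    benchmark_counts: tuple[int, int] | None = None,
) -> list[SplitPlan]:
    """Repeated stratified benchmark / independent splits.

    Per repeat, ``floor(frac * n)`` samples of each class are drawn without
    replacement into the benchmark set; the remainder form the independent
    set. ``benchmark_counts=(n_pos, n_neg)`` overrides the per-class counts so
    round published sizes (e.g. 800/800 out of 980/980) are exactly
    reproducible. Deterministic under ``seed``; repeats differ.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError(f"frac must be in (0, 1), got {frac}")
    if not pos or not neg:
        raise ValueError("both classes must be nonempty")
    if benchmark_counts is None:
        n_pos, n_neg = int(frac * len(pos)), int(frac * len(neg))
    else:
        n_pos, n_neg = benchmark_counts
    if not (0 < n_pos < len(pos) and 0 < n_neg < len(neg)):
        raise ValueError("benchmark counts must leave both parts nonempty")
    rng = np.random.default_rng(seed)
    plans = []
    for r in range(1, repeats + 1):
        bench: set[str] = set()
        indep: set[str] = set()
        for samples, n_bench in ((pos, n_pos), (neg, n_neg)):
            order = rng.permutation(len(samples))
            bench.update(samples[i].id for i in order[:n_bench])
            indep.update(samples[i].id for i in order[n_bench:])
        plans.append(
            SplitPlan(
                repeat_index=r,
                benchmark_ids=frozenset(bench),
                independent_ids=frozenset(indep),
                seed=seed,
            )
        )
    return plans


def apply_split(
    samples: Sequence[DnaSample], plan: SplitPlan
) -> tuple[list[DnaSample], list[DnaSample]]:
    """Partition samples into (benchmark, independent) lists per a plan."""
    bench = [s for s in samples if s.id in plan.benchmark_ids]
    indep = [s for s in samples if s.id in plan.independent_ids]
    missing = len(samples) - len(bench) - len(indep)
    if missing:
        raise ValueError(f"{missing} samples are covered by neither part of the plan")
    return bench, indep


#: Motif blocks planted in positives: C runs upstream / mid, a T run downstream.
#: Positions are 1-based inclusive ranges.
POSITIVE_MOTIFS: tuple[tuple[int, int, str], ...] = (
    (1, 3, "C"),
    (15, 17, "C"),
    (28, 32, "T"),
)
#: Motif block planted in negatives: a leading A run.
NEGATIVE_MOTIFS: tuple[tuple[int, int, str], ...] = ((1, 3, "A"),)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic 4mC data generator.

    ``effect_size`` is the per-block planting probability in [0, 1]: at 0 the
    two classes are identically distributed (uniform background, centre C);
    at 1 every class motif is always present.
    """

    n_per_class: int = 400
    effect_size: float = 0.8
    seed: int = 0
    positive_motifs: tuple[tuple[int, int, str], ...] = POSITIVE_MOTIFS
    negative_motifs: tuple[tuple[int, int, str], ...] = NEGATIVE_MOTIFS

    def __post_init__(self) -> None:
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")


def _draw(rng: np.random.Generator, motifs, effect_size: float) -> str:
    bases = list(rng.choice(list(ALPHABET), size=WINDOW_LENGTH))
    for start, stop, base in motifs:
        if rng.random() < effect_size:
            for p in range(start - 1, stop):
                bases[p] = base
    bases[CENTER_INDEX] = "C"
    return "".join(bases)


def generate_synthetic(cfg: SyntheticConfig) -> list[DnaSample]:
    """Generate ``n_per_class`` positives then negatives, seeded and valid.

    Sequences are uniform over ACGT with the centre forced to C; each class
    motif block is planted independently with probability ``effect_size``.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = [
        DnaSample(f"pos{i + 1}", _draw(rng, cfg.positive_motifs, cfg.effect_size), POSITIVE)
        for i in range(cfg.n_per_class)
    ]
    samples += [
        DnaSample(f"neg{i + 1}", _draw(rng, cfg.negative_motifs, cfg.effect_size), NEGATIVE)
        for i in range(cfg.n_per_class)
    ]
    return samples
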