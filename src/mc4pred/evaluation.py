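"""Performance metrics, repeated-split protocols and descriptive analyses.

Binary-classification quality is summarised by confusion counts plus
sensitivity SN = TP/(TP+FN), specificity SP = TN/(TN+FP), accuracy
ACC = (TP+TN)/total, the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)),

defined as 0 when the denominator vanishes, and the area under the ROC curve
computed by the rank-based trapezoidal method. Descriptive analyses cover
position-specific nucleotide enrichment between classes (two-proportion
z-tests with Benjamini-Hochberg correction) and the Pearson correlation
structure of probabilistic features with average-linkage clustering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .seqio import ALPHABET, CENTER_INDEX, WINDOW_LENGTH, DnaSample

METRIC_NAMES = ("MCC", "ACC", "SN", "SP", "AUC")


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the five summary metrics of one evaluation."""

    TP: int
    TN: int
    FP: int
    FN: int
    SN: float
    SP: float
    ACC: float
    MCC: float
    AUC: float

    def as_dict(self) -> dict[str, float]:
        return {
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "SN": self.SN, "SP": self.SP, "ACC": self.ACC,
            "MCC": self.MCC, "AUC": self.AUC,
        }


def mcc_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when the denominator is 0."""
    denom = math.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0.0:
        warnings.warn("MCC denominator is zero; reporting 0", stacklevel=2)
        return 0.0
    return (tp * tn - fp * fn) / denom


def compute_metrics(
    labels: Sequence[int],
    predictions: Sequence[int],
    probabilities: Sequence[float] | None = None,
) -> MetricsReport:
    """Confusion counts plus SN/SP/ACC/MCC and (given scores) AUC.

    ``labels`` and ``predictions`` are binary with 1 = 4mC. AUC requires
    ``probabilities`` and both classes present in the truth; a single-class
    truth raises.
    """
    y = np.asarray(labels, dtype=int)
    yhat = np.asarray(predictions, dtype=int)
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions differ in length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("single-class truth: SN/SP/AUC undefined")
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / (tp + tn + fp + fn)
    mcc = mcc_from_counts(tp, tn, fp, fn)
    if probabilities is None:
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))
    return MetricsReport(TP=tp, TN=tn, FP=fp, FN=fn, SN=sn, SP=sp, ACC=acc,
                         MCC=mcc, AUC=auc)


@dataclass
class RepeatedEvaluation:
    """Per-repeat metric reports plus their mean and standard deviation."""

    reports: list[MetricsReport]
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        frame = pd.DataFrame([r.as_dict() for r in self.reports])
        self.summary = frame[list(METRIC_NAMES)].agg(["mean", "std"])

    def mean(self, metric: str) -> float:
        return float(self.summary.loc["mean", metric])

    def std(self, metric: str) -> float:
        return float(self.summary.loc["std", metric])


ModelBuilder = Callable[[Sequence[DnaSample], int], object]


def _predict_with(model, samples: Sequence[DnaSample]) -> tuple[np.ndarray, np.ndarray]:
    """(labels, probabilities) from any model exposing predict_samples."""
    report = model.predict_samples(samples)
    return report["label"].to_numpy(dtype=int), report["probability"].to_numpy(dtype=float)


def crossval(
    samples: Sequence[DnaSample],
    model_builder: ModelBuilder,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> RepeatedEvaluation:
    """Repeated stratified k-fold cross-validation of a model builder.

    Per repeat, samples are partitioned into stratified folds; the builder is
    fit on each training portion (seeded per repeat) and scored on the held-out
    fold; pooled out-of-fold predictions give that repeat's metrics.
    """
    from .seqio import labels_to_array

    y = labels_to_array(samples)
    if min(np.bincount(y, minlength=2)) < folds:
        raise ValueError(f"each class needs at least {folds} samples for {folds} folds")
    reports = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        pred = np.empty(len(samples), dtype=int)
        prob = np.empty(len(samples), dtype=float)
        for train_idx, test_idx in skf.split(np.zeros(len(samples)), y):
            if len(set(y[train_idx])) < 2:
                raise ValueError("fold without both classes")
            model = model_builder([samples[i] for i in train_idx], seed + r)
            labels_hat, probs_hat = _predict_with(model, [samples[i] for i in test_idx])
            pred[test_idx] = labels_hat
            prob[test_idx] = probs_hat
        reports.append(compute_metrics(y, pred, prob))
    return RepeatedEvaluation(reports)


def independent_eval(model, independent: Sequence[DnaSample]) -> MetricsReport:
    """Score a trained model on an untouched labelled set.

    Raises on any id overlap between the model's recorded training ids and
    the evaluation set (leakage guard).
    """
    from .seqio import labels_to_array

    if not independent:
        raise ValueError("independent set is empty")
    train_ids = set(getattr(model, "training_ids", ()))
    overlap = train_ids & {s.id for s in independent}
    if overlap:
        raise ValueError(f"independent set overlaps training ids: {sorted(overlap)[:5]}")
    y = labels_to_array(independent)
    pred, prob = _predict_with(model, independent)
    return compute_metrics(y, pred, prob)


def compare_auc_ttest(
    auc_a: Sequence[float], auc_b: Sequence[float], paired: bool = False
) -> float:
    """Two-tailed t-test p-value comparing two sets of per-split AUCs.

    Unpaired equal-variance by default; ``paired=True`` pairs splits. Two
    degenerate identical samples (zero variance, equal means) give p = 1.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape and paired:
        raise ValueError("paired test needs equal-length vectors")
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    if paired:
        result = stats.ttest_rel(a, b)
    else:
        result = stats.ttest_ind(a, b, equal_var=True)
    return float(result.pvalue)


@dataclass
class EnrichmentProfile:
    """Per-position, per-base composition comparison between classes.

    ``table`` has one row per (position, base) with counts in each class, the
    frequency difference (positive minus negative), the two-proportion z
    statistic, its p-value and the Benjamini-Hochberg q-value. The centre
    position is constant ('C' in both classes) and is flagged.
    """

    table: pd.DataFrame
    n_positive: int
    n_negative: int


def position_enrichment(
    positives: Sequence[DnaSample], negatives: Sequence[DnaSample]
) -> EnrichmentProfile:
    """Position-specific nucleotide enrichment of positives vs negatives."""
    if not positives or not negatives:
        raise ValueError("both classes must be nonempty")
    n_pos, n_neg = len(positives), len(negatives)
    rows = []
    for pos in range(WINDOW_LENGTH):
        for base in ALPHABET:
            cp = sum(1 for s in positives if s.seq[pos] == base)
            cn = sum(1 for s in negatives if s.seq[pos] == base)
            fp_, fn_ = cp / n_pos, cn / n_neg
            constant = pos == CENTER_INDEX
            if constant or (cp + cn == 0) or (cp == n_pos and cn == n_neg):
                z, p = 0.0, 1.0
            else:
                z, p = proportions_ztest([cp, cn], [n_pos, n_neg])
            rows.append({
                "position": pos + 1,
                "base": base,
                "count_positive": cp,
                "count_negative": cn,
                "freq_difference": fp_ - fn_,
                "z": float(z),
                "p_value": float(p),
                "is_center": constant,
            })
    table = pd.DataFrame(rows)
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return EnrichmentProfile(table=table, n_positive=n_pos, n_negative=n_neg)


@dataclass
class CorrelationMatrix:
    """Pearson correlations between probabilistic features, with clustering.

    ``order`` is the average-linkage dendrogram leaf permutation and
    ``cluster_labels`` the memberships at a two-cluster cut. Zero-variance
    columns yield NaN correlations and are flagged in ``degenerate_columns``.
    """

    matrix: pd.DataFrame
    order: list[int]
    cluster_labels: np.ndarray
    degenerate_columns: list[str]


def correlation_analysis(features: pd.DataFrame) -> CorrelationMatrix:
    """Pearson matrix + average-linkage clustering of feature columns."""
    if len(features) < 3:
        raise ValueError("need at least 3 samples to correlate features")
    values = features.to_numpy(dtype=float)
    stds = values.std(axis=0)
    degenerate = [str(c) for c, s in zip(features.columns, stds) if s == 0.0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    matrix = pd.DataFrame(corr, index=features.columns, columns=features.columns)
    # cluster on 1 - r, treating NaN (degenerate) as maximally distant
    dist = 1.0 - np.nan_to_num(corr, nan=-1.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [int(i) for i in hierarchy.leaves_list(linkage)]
    cluster_labels = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    return CorrelationMatrix(
        matrix=matrix,
        order=order,
        cluster_labels=cluster_labels,
        degenerate_columns=degenerate,
    )
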