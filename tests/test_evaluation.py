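import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef

from mc4pred import (
    SyntheticConfig,
    compare_auc_ttest,
    compute_metrics,
    correlation_analysis,
    crossval,
    generate_synthetic,
    position_enrichment,
)
from mc4pred.evaluation import mcc_from_counts
from mc4pred.seqio import NEGATIVE, POSITIVE


def _confusion_vectors(tp, fn, tn, fp):
    labels = [1] * (tp + fn) + [0] * (tn + fp)
    preds = [1] * tp + [0] * fn + [0] * tn + [1] * fp
    return labels, preds


# ------------------------------------------------------------------- metrics

def test_hand_computed_confusion_table():
    labels, preds = _confusion_vectors(tp=8, fn=4, tn=6, fp=2)
    scores = [0.9] * 8 + [0.4] * 4 + [0.1] * 6 + [0.8] * 2
    rep = compute_metrics(labels, preds, scores)
    assert (rep.TP, rep.FN, rep.TN, rep.FP) == (8, 4, 6, 2)
    assert rep.SN == pytest.approx(8 / 12)
    assert rep.SP == pytest.approx(0.75)
    assert rep.ACC == pytest.approx(0.7)
    expected_mcc = (8 * 6 - 2 * 4) / np.sqrt(12 * 10 * 8 * 10)
    assert rep.MCC == pytest.approx(expected_mcc)
    assert rep.MCC == pytest.approx(0.4082, abs=5e-4)


def test_perfect_and_inverted_predictions():
    labels = [1, 1, 0, 0]
    perfect = compute_metrics(labels, labels, [0.9, 0.8, 0.1, 0.2])
    assert perfect.SN == perfect.SP == perfect.ACC == perfect.AUC == 1.0
    assert perfect.MCC == 1.0
    inverted = compute_metrics(labels, [0, 0, 1, 1], [0.1, 0.2, 0.9, 0.8])
    assert inverted.ACC == 0.0 and inverted.MCC == -1.0 and inverted.AUC == 0.0


def test_accuracy_uses_tp_plus_tn_numerator():
    """The correct ACC numerator is TP+TN; the alternative TP+FN reading would
    give a different value on this table, confirming the divergence is
    intentional."""
    labels, preds = _confusion_vectors(tp=8, fn=4, tn=6, fp=2)
    rep = compute_metrics(labels, preds)
    assert rep.ACC == pytest.approx((8 + 6) / 20)
    assert rep.ACC != pytest.approx((8 + 4) / 20)


def test_mcc_matches_library_cross_check(rng):
    labels = rng.integers(0, 2, size=200)
    preds = rng.integers(0, 2, size=200)
    if len(set(labels)) < 2:
        pytest.skip("degenerate draw")
    rep = compute_metrics(labels, preds)
    assert rep.MCC == pytest.approx(matthews_corrcoef(labels, preds), abs=1e-12)


def test_mcc_zero_denominator_reports_zero():
    with pytest.warns(UserWarning):
        # no predicted positives: TP+FP = 0 zeroes the denominator
        assert mcc_from_counts(0, 5, 0, 5) == 0.0


def test_single_class_truth_raises():
    with pytest.raises(ValueError):
        compute_metrics([1, 1], [1, 0], [0.9, 0.1])


def test_metric_ranges_on_random_inputs(rng):
    for _ in range(20):
        labels = rng.integers(0, 2, size=50)
        preds = rng.integers(0, 2, size=50)
        if len(set(labels)) < 2:
            continue
        rep = compute_metrics(labels, preds, rng.random(50))
        assert -1.0 <= rep.MCC <= 1.0
        for value in (rep.ACC, rep.SN, rep.SP, rep.AUC):
            assert 0.0 <= value <= 1.0


def test_random_scores_give_chance_auc(rng):
    labels = np.repeat([0, 1], 1000)
    rep = compute_metrics(labels, rng.integers(0, 2, size=2000), rng.random(2000))
    se = np.sqrt(0.25 / 2000) * 2  # rough SE of AUC near 0.5
    assert abs(rep.AUC - 0.5) < 3 * max(se, 0.577 / np.sqrt(2000))


# ------------------------------------------------------------------- t-tests

def test_identical_auc_vectors_give_p_one():
    assert compare_auc_ttest([0.8] * 10, [0.8] * 10) == 1.0


def test_separated_auc_vectors_give_tiny_p(rng):
    a = 0.9 + rng.normal(0, 1e-3, size=10)
    b = 0.5 + rng.normal(0, 1e-3, size=10)
    assert compare_auc_ttest(a, b) < 1e-3


def test_ttest_is_symmetric(rng):
    a = rng.random(10)
    b = rng.random(10)
    assert compare_auc_ttest(a, b) == pytest.approx(compare_auc_ttest(b, a))


def test_ttest_matches_brute_force_statistic(rng):
    a, b = rng.random(10), rng.random(10)
    # pooled-variance two-sample t by hand
    sp2 = (9 * a.var(ddof=1) + 9 * b.var(ddof=1)) / 18
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 10))
    from scipy.stats import t as tdist
    expected = 2 * tdist.sf(abs(t), df=18)
    assert compare_auc_ttest(a, b) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------- enrichment

def test_identical_sets_show_no_enrichment():
    samples = generate_synthetic(SyntheticConfig(n_per_class=30, seed=1))
    pos = [s for s in samples if s.label == POSITIVE]
    profile = position_enrichment(pos, pos)
    assert np.allclose(profile.table["freq_difference"], 0.0)


def test_planted_motifs_are_recovered():
    samples = generate_synthetic(SyntheticConfig(n_per_class=300, effect_size=1.0, seed=2))
    pos = [s for s in samples if s.label == POSITIVE]
    neg = [s for s in samples if s.label == NEGATIVE]
    profile = position_enrichment(pos, neg)
    t = profile.table.set_index(["position", "base"])
    for position in (1, 2, 3):
        assert t.loc[(position, "C"), "p_value"] < 0.01
        assert t.loc[(position, "C"), "freq_difference"] > 0
        assert t.loc[(position, "A"), "freq_difference"] < 0  # negatives' A run
    for position in (28, 29, 30, 31, 32):
        assert t.loc[(position, "T"), "p_value"] < 0.01


def test_centre_position_is_constant_cytosine():
    samples = generate_synthetic(SyntheticConfig(n_per_class=20, seed=3))
    pos = [s for s in samples if s.label == POSITIVE]
    neg = [s for s in samples if s.label == NEGATIVE]
    profile = position_enrichment(pos, neg)
    row = profile.table.set_index(["position", "base"]).loc[(21, "C")]
    assert row["count_positive"] == 20 and row["count_negative"] == 20
    assert bool(row["is_center"])
    # per-position counts sum to class sizes
    sums = profile.table.groupby("position")[["count_positive", "count_negative"]].sum()
    assert (sums["count_positive"] == 20).all() and (sums["count_negative"] == 20).all()


# --------------------------------------------------------------- correlation

def test_duplicated_column_has_unit_correlation(rng):
    x = rng.random(100)
    frame = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.random(100)})
    result = correlation_analysis(frame)
    assert result.matrix.loc["a", "b"] == pytest.approx(1.0)
    assert np.allclose(np.diag(result.matrix), 1.0)
    assert len(result.order) == 3 and len(result.cluster_labels) == 3


def test_independent_columns_have_small_correlations(rng):
    frame = pd.DataFrame(rng.random((1000, 6)))
    result = correlation_analysis(frame)
    off = result.matrix.to_numpy()[~np.eye(6, dtype=bool)]
    assert np.abs(off).max() < 0.12


def test_correlation_matches_direct_formula(rng):
    frame = pd.DataFrame(rng.random((20, 4)))
    result = correlation_analysis(frame)
    x = frame.to_numpy()
    centred = x - x.mean(axis=0)
    manual = (centred.T @ centred) / np.outer(
        np.linalg.norm(centred, axis=0), np.linalg.norm(centred, axis=0)
    )
    np.testing.assert_allclose(result.matrix.to_numpy(), manual, atol=1e-12)


def test_zero_variance_column_is_flagged(rng):
    frame = pd.DataFrame({"a": rng.random(50), "flat": np.ones(50), "b": rng.random(50)})
    result = correlation_analysis(frame)
    assert result.degenerate_columns == ["flat"]
    assert np.isnan(result.matrix.loc["flat", "a"])


def test_two_block_structure_clusters_apart(rng):
    base1, base2 = rng.random(300), rng.random(300)
    frame = pd.DataFrame({
        "a1": base1, "a2": base1 + rng.normal(0, 0.05, 300),
        "b1": base2, "b2": base2 + rng.normal(0, 0.05, 300),
    })
    result = correlation_analysis(frame)
    labels = dict(zip(frame.columns, result.cluster_labels))
    assert labels["a1"] == labels["a2"]
    assert labels["b1"] == labels["b2"]
    assert labels["a1"] != labels["b1"]


# ------------------------------------------------------------------ crossval

class _MajorityModel:
    """Deterministic stub: predicts the training majority class."""

    def __init__(self, samples, seed):
        votes = sum(1 if s.label == POSITIVE else 0 for s in samples)
        self.majority = int(votes * 2 >= len(samples))
        self.training_ids = [s.id for s in samples]

    def predict_samples(self, samples):
        return pd.DataFrame(
            {"label": self.majority, "probability": float(self.majority)},
            index=[s.id for s in samples],
        )


class _OracleModel:
    """Stub that reads the true label (upper bound sanity)."""

    def __init__(self, samples, seed):
        self.training_ids = [s.id for s in samples]

    def predict_samples(self, samples):
        y = [1 if s.label == POSITIVE else 0 for s in samples]
        return pd.DataFrame(
            {"label": y, "probability": [float(v) for v in y]},
            index=[s.id for s in samples],
        )


def test_crossval_is_deterministic_and_summary_recomputable():
    samples = generate_synthetic(SyntheticConfig(n_per_class=30, seed=5))
    a = crossval(samples, _OracleModel, folds=5, repeats=4, seed=1)
    b = crossval(samples, _OracleModel, folds=5, repeats=4, seed=1)
    assert a.summary.equals(b.summary)
    accs = [r.ACC for r in a.reports]
    assert a.mean("ACC") == pytest.approx(np.mean(accs))
    assert a.std("ACC") == pytest.approx(np.std(accs, ddof=1), nan_ok=True)
    assert a.mean("ACC") == 1.0  # the oracle stub is perfect


def test_crossval_chance_level_for_uninformative_model():
    samples = generate_synthetic(SyntheticConfig(n_per_class=40, effect_size=0.0, seed=6))
    result = crossval(samples, _MajorityModel, folds=5, repeats=3, seed=2)
    se = np.sqrt(0.25 / 80)
    assert abs(result.mean("ACC") - 0.5) <= 3 * se + 1e-9


def test_crossval_rejects_insufficient_classes():
    samples = generate_synthetic(SyntheticConfig(n_per_class=3, seed=7))
    with pytest.raises(ValueError):
        crossval(samples, _MajorityModel, folds=5, repeats=1, seed=0)
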