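"""Two-layer stacked ensemble for 4mC site prediction.

The base layer crosses four classifier families — random forest (RF),
extremely randomised trees (ERT), gradient boosting (GB) and an RBF support
vector machine (SVM) — with the seven sequence encodings, giving 28
probability estimators. Each training sample's 28 out-of-fold base
probabilities form its probabilistic feature vector; four meta-predictors
(one per family) are fit on those vectors, and their probabilities are fused
by averaging, with a decision threshold of 0.5 (ties go to the positive
class).

Out-of-fold discipline: the probabilistic features used to train the meta
layer are always produced by base models that never saw the sample, via a
shared stratified k-fold scheme. The deployed base models are refit on the
full training set afterwards.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import ParameterGrid, StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .encodings import ENCODING_ORDER, encode_all
from .seqio import DnaSample, labels_to_array, validate_samples
from .tables import default_dinucleotide_table, default_trinucleotide_table

#: Canonical classifier-family order for the 28-column probabilistic vector.
FAMILY_ORDER = ("RF", "ERT", "GB", "SVM")

#: Canonical 28 columns: encoding-major, family-minor.
PF28_COLUMNS = tuple(
    f"{enc}:{fam}" for enc in ENCODING_ORDER for fam in FAMILY_ORDER
)

MODEL_FORMAT_VERSION = 1


def default_grids() -> dict[str, dict[str, list]]:
    """Reduced desk-scale hyperparameter grids (per classifier family)."""
    return {
        "RF": {"n_estimators": [200], "max_features": ["sqrt"]},
        "ERT": {"n_estimators": [200], "max_features": ["sqrt"]},
        "GB": {
            "n_estimators": [100], "learning_rate": [0.1],
            "max_depth": [3], "max_features": ["sqrt"],
        },
        "SVM": {"C": [1.0], "gamma": ["scale"]},
    }


def full_grids() -> dict[str, dict[str, list]]:
    """The wide search ranges (heavy; intended for full-scale reruns)."""
    return {
        "RF": {"n_estimators": [100, 200, 300, 400, 500],
               "max_features": ["sqrt", "log2"]},
        "ERT": {"n_estimators": [100, 200, 300, 400, 500],
                "max_features": ["sqrt", "log2"]},
        "GB": {"n_estimators": [50, 100, 200], "learning_rate": [0.01, 0.1],
               "max_depth": [3, 5]},
        "SVM": {"C": [2.0 ** e for e in range(-5, 6)],
                "gamma": [2.0 ** e for e in range(-7, 4)]},
    }


def make_estimator(family: str, params: Mapping, seed: int, probability: bool = True):
    """Construct an unfitted probability estimator of one family."""
    params = dict(params)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "ERT":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    if family == "GB":
        return GradientBoostingClassifier(random_state=seed, **params)
    if family == "SVM":
        svc = SVC(random_state=seed, **params)
        if not probability:
            return svc
        # Platt sigmoid calibration on internal stratified 5-fold CV
        return CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)
    raise KeyError(f"unknown classifier family {family!r}")


@dataclass(frozen=True)
class BaseModelSpec:
    """One (classifier family x encoding) slot of the base layer."""

    family: str
    encoding: str
    grid: Mapping[str, list] | None = None
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if self.family not in FAMILY_ORDER:
            raise ValueError(f"family must be one of {FAMILY_ORDER}")

    @property
    def column(self) -> str:
        return f"{self.encoding}:{self.family}"


def all_specs(
    grids: Mapping[str, Mapping[str, list]] | None = None, cv_folds: int = 10
) -> list[BaseModelSpec]:
    """The 28 base-model specs in canonical (encoding-major) order."""
    grids = grids or default_grids()
    return [
        BaseModelSpec(family=fam, encoding=enc, grid=grids[fam], cv_folds=cv_folds)
        for enc in ENCODING_ORDER
        for fam in FAMILY_ORDER
    ]


@dataclass
class BaseModel:
    """A fitted base probability estimator with its chosen hyperparameters."""

    spec: BaseModelSpec
    estimator: object
    best_params: dict
    cv_accuracy: float | None

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        positive_col = list(self.estimator.classes_).index(1)
        return proba[:, positive_col]


def select_params(
    X: np.ndarray, y: np.ndarray, spec: BaseModelSpec, seed: int
) -> tuple[dict, float | None]:
    """Grid-search hyperparameters by mean stratified-CV accuracy.

    A single-candidate grid skips the vacuous search (score None). Ties break
    on grid order, so the choice is deterministic under a fixed seed.
    """
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("training labels contain a single class")
    candidates = list(ParameterGrid(dict(spec.grid or default_grids()[spec.family])))
    best_params, best_score = candidates[0], None
    if len(candidates) > 1:
        if counts.min() < spec.cv_folds:
            raise ValueError(
                f"each class needs >= {spec.cv_folds} samples for grid-search CV"
            )
        cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=seed)
        best_score = -np.inf
        for params in candidates:
            est = make_estimator(spec.family, params, seed, probability=False)
            score = cross_val_score(est, X, y, cv=cv, scoring="accuracy").mean()
            if score > best_score:
                best_score, best_params = score, params
    return dict(best_params), best_score


def tune_and_fit_base(
    X: np.ndarray, y: np.ndarray, spec: BaseModelSpec, seed: int
) -> BaseModel:
    """Grid search (see :func:`select_params`) then refit on all training data."""
    best_params, best_score = select_params(X, y, spec, seed)
    estimator = make_estimator(spec.family, best_params, seed, probability=True)
    estimator.fit(X, y)
    return BaseModel(
        spec=spec,
        estimator=estimator,
        best_params=dict(best_params),
        cv_accuracy=None if best_score is None else float(best_score),
    )


def _spec_seed(seed: int, index: int) -> int:
    return (seed * 1009 + index) % (2 ** 31 - 1)


def oof_probabilities(
    matrices: Mapping[str, "object"],
    y: np.ndarray,
    specs: Sequence[BaseModelSpec],
    folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Out-of-fold probabilistic features for every training sample.

    Each sample's probability under a spec comes from an estimator fit on the
    other folds only (shared stratified fold scheme, so the leakage guarantee
    holds uniformly). Hyperparameters are the spec's grid-search choice on
    the full training data; only the probability estimates are out-of-fold.
    Returns the n x len(specs) feature frame and the fold assignment vector.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(y, dtype=int)
    n = len(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_of = np.full(n, -1, dtype=int)
    split = list(skf.split(np.zeros(n), y))
    for f, (_, test_idx) in enumerate(split):
        fold_of[test_idx] = f
    out = np.full((n, len(specs)), np.nan)
    for j, spec in enumerate(specs):
        X = matrices[spec.encoding].values
        spec_seed = _spec_seed(seed, j)
        best_params, _ = select_params(X, y, spec, spec_seed)
        for f, (train_idx, test_idx) in enumerate(split):
            if len(set(y[train_idx])) < 2:
                raise ValueError(f"fold {f} holds a single class")
            est = make_estimator(spec.family, best_params, spec_seed)
            est.fit(X[train_idx], y[train_idx])
            proba = est.predict_proba(X[test_idx])
            positive_col = list(est.classes_).index(1)
            out[test_idx, j] = proba[:, positive_col]
    if np.isnan(out).any():
        raise AssertionError("out-of-fold bookkeeping left unfilled entries")
    sample_ids = next(iter(matrices.values())).sample_ids
    frame = pd.DataFrame(out, index=sample_ids, columns=[s.column for s in specs])
    return frame, fold_of


def fuse(meta_probs: Sequence[float], threshold: float = 0.5) -> tuple[float, int]:
    """Voting fusion of the four meta probabilities.

    The ensemble probability is their arithmetic mean; the label is positive
    (1) iff the mean reaches the threshold.
    """
    probs = np.asarray(meta_probs, dtype=float)
    if probs.shape != (len(FAMILY_ORDER),):
        raise ValueError(f"expected {len(FAMILY_ORDER)} meta probabilities")
    if probs.min() < 0.0 or probs.max() > 1.0:
        raise ValueError("meta probabilities must lie in [0, 1]")
    probability = float(probs.mean())
    return probability, int(probability >= threshold)


@dataclass
class EnsembleModel:
    """The trained two-layer predictor: 28 base models, 4 meta-predictors."""

    base_models: dict[str, BaseModel]
    meta_models: dict[str, BaseModel]
    dpcp_table: pd.DataFrame
    tpcp_table: pd.DataFrame
    training_ids: tuple[str, ...]
    seed: int
    threshold: float = 0.5
    columns: tuple[str, ...] = PF28_COLUMNS
    oof_features: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in self.columns if c not in self.base_models]
        if missing:
            raise ValueError(f"base layer incomplete; missing {missing[:4]}...")

    # -- prediction ---------------------------------------------------------

    def predict_probabilistic_matrix(self, samples: Sequence[DnaSample]) -> pd.DataFrame:
        """The 28 base-model probabilities per sample (canonical column order)."""
        validate_samples(samples)
        matrices = encode_all(samples, dpcp_table=self.dpcp_table,
                              tpcp_table=self.tpcp_table)
        n = len(samples)
        out = np.empty((n, len(self.columns)))
        for j, col in enumerate(self.columns):
            model = self.base_models[col]
            out[:, j] = model.predict_proba_positive(matrices[model.spec.encoding].values)
        return pd.DataFrame(out, index=[s.id for s in samples], columns=list(self.columns))

    def predict_probabilistic(self, sample: DnaSample) -> np.ndarray:
        """One sample's 28-dim probabilistic feature vector."""
        return self.predict_probabilistic_matrix([sample]).to_numpy()[0]

    def predict_meta_matrix(self, pf: pd.DataFrame) -> pd.DataFrame:
        """The four meta-predictor probabilities for given 28-dim features."""
        X = pf.to_numpy(dtype=float)
        out = {fam: self.meta_models[fam].predict_proba_positive(X)
               for fam in FAMILY_ORDER}
        return pd.DataFrame(out, index=pf.index)

    def predict_samples(self, samples: Sequence[DnaSample]) -> pd.DataFrame:
        """Per-sample report: fused probability, label, meta and base probabilities."""
        if not len(samples):
            return pd.DataFrame(
                columns=["probability", "label", *FAMILY_ORDER, *self.columns]
            )
        pf = self.predict_probabilistic_matrix(samples)
        meta = self.predict_meta_matrix(pf)
        fused = [fuse(row, self.threshold) for row in meta.to_numpy()]
        report = pd.DataFrame(
            {
                "probability": [p for p, _ in fused],
                "label": [lab for _, lab in fused],
            },
            index=pf.index,
        )
        return pd.concat([report, meta.add_prefix("meta_"), pf], axis=1)

    def predict_report(self, samples: Sequence[DnaSample]) -> pd.DataFrame:
        """As :meth:`predict_samples`, but invalid records get a per-row error
        message instead of aborting the batch."""
        valid = [s for s in samples if s.is_valid]
        report = self.predict_samples(valid) if valid else pd.DataFrame(
            columns=["probability", "label"]
        )
        report = report.copy()
        report["error"] = ""
        for s in samples:
            if not s.is_valid:
                report.loc[s.id, ["probability", "label"]] = [np.nan, -1]
                report.loc[s.id, "error"] = "; ".join(s.validation_errors())
        return report.loc[[s.id for s in samples]] if len(samples) else report

    # -- persistence --------------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": self}, path)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "EnsembleModel":
        bundle = joblib.load(path)
        if not isinstance(bundle, dict) or bundle.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"{path} is not a version-{MODEL_FORMAT_VERSION} model bundle"
            )
        model = bundle["model"]
        if not isinstance(model, cls):
            raise ValueError(f"{path} does not hold an {cls.__name__}")
        return model


def train_4mcpred_el(
    samples: Sequence[DnaSample],
    seed: int = 0,
    grids: Mapping[str, Mapping[str, list]] | None = None,
    cv_folds: int = 10,
    oof_folds: int = 10,
    dpcp_table: pd.DataFrame | None = None,
    tpcp_table: pd.DataFrame | None = None,
) -> EnsembleModel:
    """Train the full two-layer predictor on a labelled benchmark set.

    Pipeline: encode all seven representations; tune and fit the 28 base
    models; build out-of-fold probabilistic features; fit the four
    meta-predictors on them; package everything with the voting fusion.
    Deterministic under a fixed seed.
    """
    validate_samples(samples)
    y = labels_to_array(samples)
    if np.bincount(y, minlength=2).min() < max(2, oof_folds):
        raise ValueError("both classes need at least oof_folds samples")
    if dpcp_table is None:
        dpcp_table = default_dinucleotide_table()
    if tpcp_table is None:
        tpcp_table = default_trinucleotide_table()
    matrices = encode_all(samples, dpcp_table=dpcp_table, tpcp_table=tpcp_table)
    specs = all_specs(grids, cv_folds=cv_folds)

    # meta-layer inputs: strictly out-of-fold base probabilities
    pf_train, _ = oof_probabilities(matrices, y, specs, folds=oof_folds, seed=seed)

    # deployed base layer: refit on the full benchmark
    base_models = {}
    for j, spec in enumerate(specs):
        base_models[spec.column] = tune_and_fit_base(
            matrices[spec.encoding].values, y, spec, _spec_seed(seed, j)
        )

    meta_models = {}
    meta_grids = grids or default_grids()
    for i, fam in enumerate(FAMILY_ORDER):
        spec = BaseModelSpec(family=fam, encoding="PF28", grid=meta_grids[fam],
                             cv_folds=cv_folds)
        meta_models[fam] = tune_and_fit_base(
            pf_train.to_numpy(dtype=float), y, spec, _spec_seed(seed, 100 + i)
        )

    return EnsembleModel(
        base_models=base_models,
        meta_models=meta_models,
        dpcp_table=dpcp_table,
        tpcp_table=tpcp_table,
        training_ids=tuple(s.id for s in samples),
        seed=seed,
        oof_features=pf_train,
    )
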