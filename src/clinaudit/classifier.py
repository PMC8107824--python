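"""L2-regularized logistic disease models with the two-stage tuning protocol.

The model family is deliberately simple and interpretable: a logistic
regression over binary indicators (questionnaire symptoms, smoking, and the
one-hot expanded peak-flow level).  Training follows a fixed protocol:
single-disease subset -> stratified 80/20 split -> regularization strength
tuned by cross-validated AUC -> minority class weight tuned by
cross-validated F1 (or MCC) -> final fit on the training split.

Deployment-population mismatch is handled by prior-shift recalibration of
the intercept: for a model trained at prevalence pihat and deployed where
the true prevalence is pi,

    beta0* = beta0 + log(pi / (1 - pi)) - log(pihat / (1 - pihat)),

with every slope untouched.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import metrics
from .cohort import Cohort, select_single_disease_training_set
from .errors import EmptyClassError, SamplingError, SchemaError

#: Extra model columns appended after the questionnaire panel.
EXTRA_FEATURES = ("smoking", "peak_flow_medium", "peak_flow_low")


def design_matrix(cohort: Cohort) -> pd.DataFrame:
    """Binary design matrix: questionnaire panel + smoking + peak-flow dummies.

    The ordered peak-flow level is one-hot expanded into two indicators
    (medium, low) with "high" as the reference level.
    """
    frame = cohort.to_dataframe()
    out = frame[cohort.feature_names].astype(int).copy()
    out["smoking"] = frame["smoking"].astype(int)
    out["peak_flow_medium"] = (frame["peak_flow_category"] == "medium").astype(int)
    out["peak_flow_low"] = (frame["peak_flow_category"] == "low").astype(int)
    return out


def disease_labels(cohort: Cohort, disease: str, policy: str = "exact") -> np.ndarray:
    """Binary labels for a disease.

    ``policy="exact"``: positive iff the disease set is exactly {disease}
    (the one-vs-rest training convention).  ``policy="membership"``: positive
    iff the disease appears in the set (comorbid records positive) — the
    labeling used by the whole-cohort resampling audits.
    """
    if policy == "exact":
        return np.array(
            [int(r.diseases == frozenset({disease})) for r in cohort.records]
        )
    if policy == "membership":
        return np.array([int(disease in r.diseases) for r in cohort.records])
    raise ValueError(f"unknown label policy {policy!r}")


@dataclass
class TrainedModel:
    """Fitted logistic model plus the tuning metadata needed for audits."""

    intercept: float
    coefficients: dict[str, float]
    regularization_strength: float
    class_weights: dict[str, float]
    training_prevalence: float
    feature_names: list[str]
    tuning_log: dict = field(default_factory=dict)
    #: Prevalence the current intercept is calibrated to (equals
    #: training_prevalence until the intercept is recalibrated).
    calibration_prevalence: float | None = None
    #: Intercept as fitted, before any prevalence adjustment; the anchor that
    #: makes chained adjustments compose exactly.
    base_intercept: float | None = None

    def __post_init__(self) -> None:
        if self.calibration_prevalence is None:
            self.calibration_prevalence = self.training_prevalence
        if self.base_intercept is None:
            self.base_intercept = self.intercept
        if list(self.coefficients) != list(self.feature_names):
            raise SchemaError("coefficients must cover exactly feature_names")

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "regularization_strength": self.regularization_strength,
            "class_weights": {str(k): v for k, v in self.class_weights.items()},
            "training_prevalence": self.training_prevalence,
            "calibration_prevalence": self.calibration_prevalence,
            "base_intercept": self.base_intercept,
            "feature_names": list(self.feature_names),
            "tuning_log": self.tuning_log,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_dict(cls, raw: dict) -> "TrainedModel":
        return cls(
            intercept=raw["intercept"],
            coefficients={k: raw["coefficients"][k] for k in raw["feature_names"]},
            regularization_strength=raw["regularization_strength"],
            class_weights=raw["class_weights"],
            training_prevalence=raw["training_prevalence"],
            feature_names=list(raw["feature_names"]),
            tuning_log=raw.get("tuning_log", {}),
            calibration_prevalence=raw.get("calibration_prevalence"),
            base_intercept=raw.get("base_intercept"),
        )

    @classmethod
    def from_json(cls, path) -> "TrainedModel":
        with open(path) as handle:
            return cls.from_dict(json.load(handle))


@dataclass
class TuningResult:
    grid: list[float]
    criterion: str
    scores: list[float]
    selected: float


@dataclass
class ProtocolConfig:
    """Knobs of the training protocol with the package defaults."""

    c_grid: list[float] = field(
        default_factory=lambda: [10.0 ** k for k in range(-3, 4)]
    )
    weight_grid: list[float] = field(default_factory=lambda: [1, 2, 3, 5, 8, 13])
    folds: int = 5
    test_fraction: float = 0.2
    weight_criterion: str = "f1"
    negative_policy: str = "healthy"
    seed: int = 0


def _validate_design(X: pd.DataFrame) -> np.ndarray:
    values = np.asarray(X, dtype=float)
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError("design matrix must be binary (0/1) with no missing values")
    return values


def fit_logistic(
    X: pd.DataFrame,
    y,
    C: float = 1.0,
    class_weights: dict | None = None,
) -> TrainedModel:
    """Fit an L2-penalized, class-weighted logistic regression.

    Deterministic for identical inputs; the solver runs to tight tolerance so
    coefficients agree with an independent penalized-likelihood optimizer.
    """
    values = _validate_design(X)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise EmptyClassError("both classes required to fit")
    estimator = LogisticRegression(
        C=C,
        class_weight=class_weights,
        solver="lbfgs",
        max_iter=10000,
        tol=1e-10,
    )
    estimator.fit(values, y)
    names = list(X.columns)
    return TrainedModel(
        intercept=float(estimator.intercept_[0]),
        coefficients={n: float(b) for n, b in zip(names, estimator.coef_[0])},
        regularization_strength=C,
        class_weights={str(k): float(v) for k, v in (class_weights or {}).items()},
        training_prevalence=float(np.mean(y)),
        feature_names=names,
    )


def predict_proba(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """logistic(beta0 + beta . x) per record."""
    missing = [n for n in model.feature_names if n not in X.columns]
    if missing:
        raise SchemaError(f"missing feature columns {missing}")
    values = np.asarray(X[model.feature_names], dtype=float)
    beta = np.array([model.coefficients[n] for n in model.feature_names])
    logits = model.intercept + values @ beta
    return 1.0 / (1.0 + np.exp(-logits))


def _cv_auc(values, y, C, class_weights, folds, seed) -> float:
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in splitter.split(values, y):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise SamplingError("a cross-validation fold lost one class")
        est = LogisticRegression(
            C=C, class_weight=class_weights, solver="lbfgs",
            max_iter=10000, tol=1e-8,
        )
        est.fit(values[train_idx], y[train_idx])
        held = est.predict_proba(values[test_idx])[:, 1]
        scores.append(metrics.auc_score(held, y[test_idx]))
    return float(np.mean(scores))


def _cv_threshold_metric(values, y, C, class_weights, folds, seed, criterion) -> float:
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scorer = metrics.f1_score if criterion == "f1" else metrics.mcc
    scores = []
    for train_idx, test_idx in splitter.split(values, y):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise SamplingError("a cross-validation fold lost one class")
        est = LogisticRegression(
            C=C, class_weight=class_weights, solver="lbfgs",
            max_iter=10000, tol=1e-8,
        )
        est.fit(values[train_idx], y[train_idx])
        held = est.predict_proba(values[test_idx])[:, 1]
        counts = metrics.confusion_counts(held, y[test_idx], 0.5)
        scores.append(scorer(counts))
    return float(np.mean(scores))


def tune_regularization(
    X: pd.DataFrame, y, grid=None, folds: int = 5, seed: int = 0
) -> TuningResult:
    """Pick the regularization strength C by cross-validated mean AUC.

    Ties break toward the smallest C (strongest regularization).
    """
    values = _validate_design(X)
    y = np.asarray(y, dtype=int)
    grid = sorted(set(grid if grid is not None else ProtocolConfig().c_grid))
    if not grid:
        raise ValueError("empty C grid")
    scores = [_cv_auc(values, y, C, None, folds, seed) for C in grid]
    best = int(np.argmax(scores))  # argmax takes the first (smallest C) on ties
    return TuningResult(grid=grid, criterion="AUC", scores=scores, selected=grid[best])


def tune_class_weights(
    X: pd.DataFrame,
    y,
    C: float,
    weight_grid=None,
    folds: int = 5,
    seed: int = 0,
    criterion: str = "f1",
) -> TuningResult:
    """Pick the minority-class weight multiplier by cross-validated F1 or MCC.

    The minority class (by training frequency) receives the candidate weight,
    the majority class weight 1.  Ties break toward the smallest weight.
    """
    if criterion not in ("f1", "mcc"):
        raise ValueError(f"criterion must be f1 or mcc, got {criterion!r}")
    values = _validate_design(X)
    y = np.asarray(y, dtype=int)
    weight_grid = sorted(set(weight_grid if weight_grid is not None else ProtocolConfig().weight_grid))
    if not weight_grid:
        raise ValueError("empty weight grid")
    minority = int(np.mean(y) < 0.5)
    scores = []
    for w in weight_grid:
        class_weights = {minority: float(w), 1 - minority: 1.0}
        scores.append(
            _cv_threshold_metric(values, y, C, class_weights, folds, seed, criterion)
        )
    best = int(np.argmax(scores))
    return TuningResult(
        grid=list(weight_grid), criterion=criterion, scores=scores,
        selected=weight_grid[best],
    )


def adjust_intercept_for_prevalence(
    model: TrainedModel, target_prevalence: float
) -> TrainedModel:
    """Prior-shift the intercept to a deployment prevalence.

    The new intercept is computed from the as-fitted anchor,

        beta0* = beta0_base + logit(pi) - logit(pihat),

    so chained adjustments compose exactly (pihat -> pi1 -> pi2 equals
    pihat -> pi2 bit for bit).  Slopes are untouched.
    """
    pi = float(target_prevalence)
    if not 0.0 < pi < 1.0:
        raise ValueError(f"target prevalence must lie in (0,1), got {pi}")
    pihat = model.training_prevalence
    shift = math.log(pi / (1 - pi)) - math.log(pihat / (1 - pihat))
    log = dict(model.tuning_log)
    log["prevalence_adjustments"] = log.get("prevalence_adjustments", []) + [
        {"from": model.calibration_prevalence, "to": pi, "shift": shift}
    ]
    return dataclasses.replace(
        model,
        intercept=model.base_intercept + shift,
        calibration_prevalence=pi,
        tuning_log=log,
    )


def coefficient_report(model: TrainedModel) -> list[dict]:
    """Features ranked by |beta| descending (name-sorted ties), rank from 1."""
    ordered = sorted(
        model.coefficients.items(), key=lambda item: (-abs(item[1]), item[0])
    )
    return [
        {"feature": name, "beta": beta, "rank": rank}
        for rank, (name, beta) in enumerate(ordered, start=1)
    ]


def train_disease_model(
    cohort: Cohort, disease: str, protocol: ProtocolConfig | None = None
) -> TrainedModel:
    """Run the full training protocol for one disease model.

    Single-disease subset -> stratified 80/20 split (stratified jointly on
    label and gender) -> C tuned by CV AUC -> minority weight tuned by CV F1
    -> final fit on the training split.  Grids, scores, selections, the seed
    and the held-out AUC are all recorded in ``tuning_log``.
    """
    protocol = protocol or ProtocolConfig()
    subset = select_single_disease_training_set(
        cohort, disease, negative_policy=protocol.negative_policy
    )
    X = design_matrix(subset)
    y = disease_labels(subset, disease, policy="exact")
    strata = [f"{label}|{r.gender}" for label, r in zip(y, subset.records)]
    # joint label x gender stratification needs >= 2 members per cell;
    # otherwise fall back to label-only strata
    counts = {s: strata.count(s) for s in set(strata)}
    if min(counts.values()) < 2:
        strata = [str(label) for label in y]
    idx_train, idx_test = train_test_split(
        np.arange(len(subset)),
        test_size=protocol.test_fraction,
        stratify=strata,
        random_state=protocol.seed,
    )
    X_train, y_train = X.iloc[idx_train], y[idx_train]
    X_test, y_test = X.iloc[idx_test], y[idx_test]

    c_result = tune_regularization(
        X_train, y_train, grid=protocol.c_grid, folds=protocol.folds,
        seed=protocol.seed,
    )
    w_result = tune_class_weights(
        X_train, y_train, C=c_result.selected, weight_grid=protocol.weight_grid,
        folds=protocol.folds, seed=protocol.seed,
        criterion=protocol.weight_criterion,
    )
    minority = int(np.mean(y_train) < 0.5)
    class_weights = {minority: float(w_result.selected), 1 - minority: 1.0}
    model = fit_logistic(X_train, y_train, C=c_result.selected, class_weights=class_weights)
    test_scores = predict_proba(model, X_test)
    model.tuning_log = {
        "disease": disease,
        "seed": protocol.seed,
        "folds": protocol.folds,
        "negative_policy": protocol.negative_policy,
        "n_train": int(len(idx_train)),
        "n_test": int(len(idx_test)),
        "c_grid": c_result.grid,
        "c_scores": c_result.scores,
        "selected_c": c_result.selected,
        "cv_auc_at_selected_c": c_result.scores[c_result.grid.index(c_result.selected)],
        "weight_grid": w_result.grid,
        "weight_scores": w_result.scores,
        "weight_criterion": w_result.criterion,
        "selected_weight": w_result.selected,
        "test_auc": metrics.auc_score(test_scores, y_test),
    }
    return model
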