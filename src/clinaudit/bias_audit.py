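"""Resampling audits for systematic and sampling bias.

Two experiments, both summarized as median AUC plus interquartile range over
many seeded iterations:

* **Systematic bias** — per iteration, carve two equal-size homogeneous test
  groups (e.g. all-male and all-female), train on the remainder, and compare
  per-group AUC.  A gap that persists under this demographically balanced
  design points at the data-generating process itself (e.g. the
  smoking-gender confound), not at training-set composition.

* **Sampling bias** — hold one demographically balanced test set fixed and
  sweep the demographic composition of a fixed-size training set (default
  50/62.5/75/87.5% of the first group).  Composition-dependent accuracy
  would indicate sampling bias; a flat profile rules it out.

The audits run on the whole cohort with membership labels (a record is
positive for a disease if the disease appears in its label set), matching
the partition sizes of the case study (test 80+80 of 303, training 104 from
the 143-record remainder).  Hyperparameters are tuned once per audit and
held fixed across iterations, so the resampling isolates the effect of
training-set membership at constant model capacity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import metrics
from .classifier import ProtocolConfig, design_matrix, disease_labels, \
    tune_class_weights, tune_regularization
from .cohort import Cohort
from .errors import AuditError, ConfigurationError, SamplingError
from .metrics import ROCCurve, iqr_summary


@dataclass
class SamplingBiasConfig:
    """Design of one sampling-bias sweep."""

    group_attribute: str
    group_levels: tuple[str, str]
    proportions: list[float] = field(
        default_factory=lambda: [0.5, 0.625, 0.75, 0.875]
    )
    n_train: int = 104
    test_per_group: int = 80
    iterations: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if any(not 0.0 < p < 1.0 for p in self.proportions):
            raise ConfigurationError("proportions must lie strictly in (0,1)")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")
        if len(self.group_levels) != 2:
            raise ConfigurationError("exactly two group levels required")

    def to_dict(self) -> dict:
        return {
            "group_attribute": self.group_attribute,
            "group_levels": list(self.group_levels),
            "proportions": list(self.proportions),
            "n_train": self.n_train,
            "test_per_group": self.test_per_group,
            "iterations": self.iterations,
            "seed": self.seed,
        }


def default_gender_audit_config(**overrides) -> SamplingBiasConfig:
    """The case-study gender sweep: train N=104, fixed test of 80+80,
    proportion of males 50/62.5/75/87.5%, 1000 iterations."""
    config = SamplingBiasConfig(
        group_attribute="gender",
        group_levels=("male", "female"),
        n_train=104,
        test_per_group=80,
    )
    for key, value in overrides.items():
        setattr(config, key, value)
    return config


def default_ses_audit_config(**overrides) -> SamplingBiasConfig:
    """The case-study SES sweep: train N=140, fixed test of 29+29, proportion
    of low-SES swept down 50/37.5/25/12.5%, 1000 iterations."""
    config = SamplingBiasConfig(
        group_attribute="ses",
        group_levels=("low", "high"),
        proportions=[0.5, 0.375, 0.25, 0.125],
        n_train=140,
        test_per_group=29,
    )
    for key, value in overrides.items():
        setattr(config, key, value)
    return config


def make_fixed_balanced_test_set(
    cohort: Cohort, group_attribute: str, per_group: int, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Sample a demographically balanced held-out test set.

    Exactly ``per_group`` records per attribute level, without replacement;
    the pool is the disjoint complement.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    levels = cohort.group_levels(group_attribute)
    test_idx: list[int] = []
    for level in levels:
        members = [
            i for i, r in enumerate(cohort.records)
            if str(r.attribute(group_attribute)) == level
        ]
        if len(members) < per_group:
            raise SamplingError(
                f"group {group_attribute}={level!r} has {len(members)} records, "
                f"fewer than the requested {per_group}"
            )
        test_idx.extend(rng.choice(members, size=per_group, replace=False))
    test_set = set(test_idx)
    test = cohort.subset(sorted(test_set))
    pool = cohort.subset([i for i in range(len(cohort)) if i not in test_set])
    return test, pool


def sample_training_composition(
    pool: Cohort,
    group_attribute: str,
    proportion_a: float,
    n_train: int,
    seed: int = 0,
    group_levels: tuple[str, str] | None = None,
) -> Cohort:
    """Draw a training set with an exact demographic composition.

    Level a receives round-half-up(proportion_a * n_train) records, level b
    the remainder, both without replacement from the pool (so disjointness
    from any previously removed test set holds by construction).
    """
    if not 0.0 < proportion_a < 1.0:
        raise ConfigurationError(
            f"proportion must lie strictly in (0,1), got {proportion_a}"
        )
    rng = np.random.default_rng(seed)
    levels = group_levels or tuple(pool.group_levels(group_attribute))
    n_a = int(np.floor(proportion_a * n_train + 0.5))
    quotas = {levels[0]: n_a, levels[1]: n_train - n_a}
    chosen: list[int] = []
    for level, quota in quotas.items():
        members = [
            i for i, r in enumerate(pool.records)
            if str(r.attribute(group_attribute)) == level
        ]
        if len(members) < quota:
            raise SamplingError(
                f"pool holds {len(members)} records with "
                f"{group_attribute}={level!r}, fewer than the quota {quota}"
            )
        chosen.extend(rng.choice(members, size=quota, replace=False))
    return pool.subset(sorted(chosen))


@dataclass
class SystematicBiasResult:
    """Per-group AUC distribution under homogeneous test groups."""

    disease: str
    group_attribute: str
    test_group_size: int
    iterations: int
    seed: int
    per_group: dict[str, dict]
    roc_curves: dict[str, ROCCurve]
    iqr_overlap: bool

    def to_dict(self, include_samples: bool = False) -> dict:
        groups = {}
        for level, stats in self.per_group.items():
            entry = {k: stats[k] for k in ("median_auc", "q1", "q3", "iqr")}
            if include_samples:
                entry["aucs"] = stats["aucs"]
            groups[level] = entry
        return {
            "disease": self.disease,
            "group_attribute": self.group_attribute,
            "test_group_size": self.test_group_size,
            "iterations": self.iterations,
            "seed": self.seed,
            "per_group": groups,
            "iqr_overlap": self.iqr_overlap,
        }


@dataclass
class SamplingBiasResult:
    """Median AUC + IQR per (training proportion, evaluation group)."""

    disease: str
    config: SamplingBiasConfig
    #: (proportion, evaluation group in {"all", level_a, level_b}) -> stats
    cells: dict[tuple[float, str], dict]

    def to_dict(self, include_samples: bool = False) -> dict:
        out_cells = {}
        for (proportion, group), stats in self.cells.items():
            entry = {k: stats[k] for k in ("median_auc", "q1", "q3", "iqr")}
            if include_samples:
                entry["aucs"] = stats["aucs"]
            out_cells[f"{proportion}|{group}"] = entry
        return {"disease": self.disease, "config": self.config.to_dict(),
                "cells": out_cells}

    def to_json(self, path, include_samples: bool = False) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(include_samples), handle, indent=2, sort_keys=True)
            handle.write("\n")

    def to_tidy_frame(self) -> pd.DataFrame:
        """Long-format table (proportion, group, statistic, value) for plots."""
        rows = []
        for (proportion, group), stats in sorted(self.cells.items()):
            for statistic in ("median_auc", "iqr", "q1", "q3"):
                rows.append(
                    {"proportion": proportion, "group": group,
                     "statistic": statistic, "value": stats[statistic]}
                )
        return pd.DataFrame(rows)


def _iteration_rng(master_seed: int, stage: int, iteration: int) -> np.random.Generator:
    """Independently reproducible stream per (stage, iteration) cell."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, stage, iteration])
    )


def _fit_and_score(values, y, train_idx, C, class_weights):
    est = LogisticRegression(
        C=C, class_weight=class_weights, solver="lbfgs",
        max_iter=10000, tol=1e-8,
    )
    est.fit(values[train_idx], y[train_idx])
    return est


def _tune_once(X, y, protocol: ProtocolConfig):
    """One two-stage tuning pass; the selected (C, weights) are reused across
    all audit iterations."""
    c_result = tune_regularization(
        X, y, grid=protocol.c_grid, folds=protocol.folds, seed=protocol.seed
    )
    w_result = tune_class_weights(
        X, y, C=c_result.selected, weight_grid=protocol.weight_grid,
        folds=protocol.folds, seed=protocol.seed,
        criterion=protocol.weight_criterion,
    )
    minority = int(np.mean(y) < 0.5)
    class_weights = {minority: float(w_result.selected), 1 - minority: 1.0}
    return c_result.selected, class_weights


def _homogeneous_group_sample(rng, idx, y, size, level, max_attempts=100):
    """Plain random draw of a homogeneous test group; redrawn (deterministic
    via the iteration stream) in the rare event one class is missing."""
    for _ in range(max_attempts):
        take = rng.choice(idx, size=size, replace=False)
        if 0 < int(y[take].sum()) < size:
            return take
    raise AuditError(
        f"group {level!r} cannot host both classes at test size {size}"
    )


def systematic_bias_test(
    cohort: Cohort,
    disease: str,
    group_attribute: str,
    protocol: ProtocolConfig | None = None,
    iterations: int = 200,
    seed: int = 0,
    test_group_size: int | None = None,
    label_policy: str = "membership",
) -> SystematicBiasResult:
    """Audit for systematic bias on equal-size homogeneous test groups.

    Per iteration: draw one homogeneous test group per attribute level (both
    the same size, default half the smaller group), train on a random 80%
    subsample of the remaining records — random training-set membership is
    the variance the IQR yardstick measures — and record per-group AUC.
    Aggregates median and IQR per group plus a pooled per-group ROC over all
    iterations.
    """
    protocol = protocol or ProtocolConfig()
    X = design_matrix(cohort)
    values = np.asarray(X, dtype=float)
    y = disease_labels(cohort, disease, policy=label_policy)
    groups = np.array([str(r.attribute(group_attribute)) for r in cohort.records])
    levels = sorted(str(g) for g in set(groups))

    by_level = {}
    for level in levels:
        idx = np.flatnonzero(groups == level)
        pos = idx[y[idx] == 1]
        neg = idx[y[idx] == 0]
        if len(pos) == 0 or len(neg) == 0:
            raise AuditError(
                f"group {group_attribute}={level!r} lacks one class entirely"
            )
        by_level[level] = (idx, pos, neg)

    size = test_group_size or int(min(len(v[0]) for v in by_level.values()) // 2)
    C, class_weights = _tune_once(X, y, protocol)

    aucs: dict[str, list[float]] = {level: [] for level in levels}
    pooled_scores: dict[str, list[np.ndarray]] = {level: [] for level in levels}
    pooled_labels: dict[str, list[np.ndarray]] = {level: [] for level in levels}
    for i in range(iterations):
        rng = _iteration_rng(seed, 0, i)
        test_groups = {
            level: _homogeneous_group_sample(rng, idx, y, size, level)
            for level, (idx, pos, neg) in by_level.items()
        }
        test_all = np.concatenate(list(test_groups.values()))
        assert len(set(test_all)) == len(test_all)
        remainder = np.setdiff1d(np.arange(len(cohort)), test_all)
        n_train = int(np.floor((1.0 - protocol.test_fraction) * len(remainder)))
        train_idx = rng.choice(remainder, size=n_train, replace=False)
        if len(np.unique(y[train_idx])) < 2:
            train_idx = remainder
        est = _fit_and_score(values, y, train_idx, C, class_weights)
        for level, t_idx in test_groups.items():
            scores = est.predict_proba(values[t_idx])[:, 1]
            aucs[level].append(metrics.auc_score(scores, y[t_idx]))
            pooled_scores[level].append(scores)
            pooled_labels[level].append(y[t_idx])

    per_group = {}
    roc_curves = {}
    for level in levels:
        summary = iqr_summary(aucs[level])
        per_group[level] = {
            "median_auc": summary.median, "q1": summary.q1, "q3": summary.q3,
            "iqr": summary.iqr, "aucs": list(map(float, aucs[level])),
        }
        roc_curves[level] = metrics.roc_curve(
            np.concatenate(pooled_scores[level]),
            np.concatenate(pooled_labels[level]),
            group_label=level,
        )
    overlap = True
    if len(levels) == 2:
        a, b = (per_group[level] for level in levels)
        overlap = a["q1"] <= b["q3"] and b["q1"] <= a["q3"]
    return SystematicBiasResult(
        disease=disease, group_attribute=group_attribute, test_group_size=size,
        iterations=iterations, seed=seed, per_group=per_group,
        roc_curves=roc_curves, iqr_overlap=overlap,
    )


def sampling_bias_audit(
    cohort: Cohort,
    disease: str,
    config: SamplingBiasConfig,
    protocol: ProtocolConfig | None = None,
    label_policy: str = "membership",
) -> SamplingBiasResult:
    """Audit for sampling bias with a fixed balanced test set.

    Builds the balanced test set once; for each (proportion, iteration)
    samples a training composition from the pool, trains, and scores AUC on
    the whole test set and on each group separately.  Feasibility of every
    quota is checked before any training; iteration streams derive from the
    master seed and the (proportion, iteration) pair, so any cell is
    independently reproducible.
    """
    protocol = protocol or ProtocolConfig()
    config.validate()
    test, pool = make_fixed_balanced_test_set(
        cohort, config.group_attribute, config.test_per_group, seed=config.seed
    )
    level_a, level_b = config.group_levels
    pool_groups = np.array(
        [str(r.attribute(config.group_attribute)) for r in pool.records]
    )
    for proportion in config.proportions:
        n_a = int(np.floor(proportion * config.n_train + 0.5))
        for level, quota in ((level_a, n_a), (level_b, config.n_train - n_a)):
            available = int(np.sum(pool_groups == level))
            if quota > available:
                raise SamplingError(
                    f"proportion {proportion}: quota {quota} for "
                    f"{config.group_attribute}={level!r} exceeds the "
                    f"{available} pool records"
                )

    X_pool = design_matrix(pool)
    pool_values = np.asarray(X_pool, dtype=float)
    y_pool = disease_labels(pool, disease, policy=label_policy)
    X_test = design_matrix(test)
    test_values = np.asarray(X_test, dtype=float)
    y_test = disease_labels(test, disease, policy=label_policy)
    test_groups = np.array(
        [str(r.attribute(config.group_attribute)) for r in test.records]
    )
    test_ids = {r.patient_id for r in test.records}

    C, class_weights = _tune_once(X_pool, y_pool, protocol)

    eval_masks = {
        "all": np.ones(len(test), dtype=bool),
        level_a: test_groups == level_a,
        level_b: test_groups == level_b,
    }
    level_indices = {
        level: np.flatnonzero(pool_groups == level) for level in (level_a, level_b)
    }
    cells: dict[tuple[float, str], dict] = {}
    samples: dict[tuple[float, str], list[float]] = {
        (p, g): [] for p in config.proportions for g in eval_masks
    }
    for p_index, proportion in enumerate(config.proportions):
        n_a = int(np.floor(proportion * config.n_train + 0.5))
        quotas = ((level_a, n_a), (level_b, config.n_train - n_a))
        for i in range(config.iterations):
            rng = _iteration_rng(config.seed, p_index + 1, i)
            train_idx = np.concatenate(
                [rng.choice(level_indices[level], size=quota, replace=False)
                 for level, quota in quotas]
            )
            assert not ({pool.records[j].patient_id for j in train_idx} & test_ids)
            est = _fit_and_score(pool_values, y_pool, train_idx, C, class_weights)
            scores = est.predict_proba(test_values)[:, 1]
            for group, mask in eval_masks.items():
                samples[(proportion, group)].append(
                    metrics.auc_score(scores[mask], y_test[mask])
                )
    for key, values_list in samples.items():
        summary = iqr_summary(values_list)
        cells[key] = {
            "median_auc": summary.median, "q1": summary.q1, "q3": summary.q3,
            "iqr": summary.iqr, "aucs": list(map(float, values_list)),
        }
    return SamplingBiasResult(disease=disease, config=config, cells=cells)
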