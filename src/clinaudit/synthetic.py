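"""Seeded generator of case-study-like synthetic cohorts.

The generator reproduces the documented composition of the pulmonary
screening study exactly (gender, SES, smoking and disease-subgroup quotas)
and draws symptoms and peak-flow readings from disease-conditional
distributions.  The smoking-gender confound — roughly 55% of men smoking and
no women — together with a positive smoking weight on COPD assignment is
what makes the cohort a useful test-bed for the bias audits: a gender gap in
COPD-model performance is baked into the data-generating process itself.

The study data are described, not deposited, so the generative model here is
the package's own; every knob lives in :class:`GeneratorConfig` and the
default values are documented in ``data/default_cohort.yaml``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .cohort import Cohort, PatientRecord, discretize_peak_flow
from .errors import ConfigurationError

#: Canonical order of disease categories (a category may carry two tokens).
DISEASE_CATEGORIES = (
    "AR",
    "Asthma",
    "Asthma+AR",
    "COPD",
    "COPD+AR",
    "Healthy",
    "Other",
)

_CATEGORY_TOKENS = {
    "AR": frozenset({"AR"}),
    "Asthma": frozenset({"Asthma"}),
    "Asthma+AR": frozenset({"Asthma", "AR"}),
    "COPD": frozenset({"COPD"}),
    "COPD+AR": frozenset({"COPD", "AR"}),
    "Healthy": frozenset(),
    "Other": frozenset({"Other"}),
}

#: Categories whose assignment odds are multiplied for smokers.
_SMOKING_WEIGHTED = ("COPD", "COPD+AR")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class GeneratorConfig:
    """Full parameterization of a synthetic case-study cohort."""

    n_male: int
    n_female: int
    disease_counts: dict[str, int]
    smoking_rate_by_gender: dict[str, float]
    ses_split: float
    smoking_rate_by_ses: dict[str, float]
    smoking_copd_weight: float
    peak_flow_params: dict[str, dict[str, float]]
    symptom_emission: dict[str, dict[str, float]]
    peak_flow_cuts: tuple[float, float] = (0.8, 0.5)
    seed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_male + self.n_female

    @property
    def feature_names(self) -> list[str]:
        first = self.symptom_emission[DISEASE_CATEGORIES[0]]
        return list(first.keys())

    def validate(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ConfigurationError("gender counts must be non-negative")
        if sum(self.disease_counts.values()) != self.n_total:
            raise ConfigurationError(
                f"disease_counts sum to {sum(self.disease_counts.values())} "
                f"but the cohort holds {self.n_total} records"
            )
        unknown = set(self.disease_counts) - set(DISEASE_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown disease categories {sorted(unknown)}")
        for name, rate in list(self.smoking_rate_by_gender.items()) + list(
            self.smoking_rate_by_ses.items()
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"smoking rate {name!r}={rate} outside [0,1]")
        if not 0.0 <= self.ses_split <= 1.0:
            raise ConfigurationError("ses_split outside [0,1]")
        panel = set(self.feature_names)
        for cat in DISEASE_CATEGORIES:
            if cat not in self.symptom_emission:
                raise ConfigurationError(f"missing symptom emissions for {cat!r}")
            if set(self.symptom_emission[cat]) != panel:
                raise ConfigurationError(
                    f"symptom panel for {cat!r} differs from {sorted(panel)}"
                )
            for feat, p in self.symptom_emission[cat].items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"emission p({feat}|{cat})={p} outside [0,1]"
                    )
            if cat not in self.peak_flow_params:
                raise ConfigurationError(f"missing peak_flow_params for {cat!r}")

    def to_dict(self) -> dict:
        return {
            "n_male": self.n_male,
            "n_female": self.n_female,
            "disease_counts": dict(self.disease_counts),
            "smoking_rate_by_gender": dict(self.smoking_rate_by_gender),
            "ses_split": self.ses_split,
            "smoking_rate_by_ses": dict(self.smoking_rate_by_ses),
            "smoking_copd_weight": self.smoking_copd_weight,
            "peak_flow_params": {k: dict(v) for k, v in self.peak_flow_params.items()},
            "symptom_emission": {k: dict(v) for k, v in self.symptom_emission.items()},
            "peak_flow_cuts": list(self.peak_flow_cuts),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorConfig":
        raw = dict(raw)
        raw["peak_flow_cuts"] = tuple(raw.get("peak_flow_cuts", (0.8, 0.5)))
        return cls(**raw)


@dataclass
class NoiseInjection:
    """Controlled feature corruption targeted at one demographic group.

    Flipping a fraction of a group's questionnaire bits plants a known
    systematic bias, which is how the audits' detection power is validated.
    """

    target_group: tuple[str, str]
    flip_rate: float
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.flip_rate <= 1.0:
            raise ConfigurationError("flip_rate outside [0,1]")


def default_case_study_config(seed: int | None = None) -> GeneratorConfig:
    """The documented case-study composition with a fixed default seed."""
    ref = importlib.resources.files("clinaudit.data") / "default_cohort.yaml"
    config = GeneratorConfig.from_dict(yaml.safe_load(ref.read_text()))
    if seed is not None:
        config.seed = seed
    return config


def gender_exchangeable_config(seed: int | None = None) -> GeneratorConfig:
    """Default composition with gender made exchangeable.

    Both genders receive the cohort-average smoking rate, so smoking (and,
    through it, disease assignment) no longer depends on gender; symptom
    emissions already depend on disease only.  Used as the null condition in
    false-alarm checks.
    """
    config = default_case_study_config(seed=seed)
    config.smoking_rate_by_gender = {"male": 0.31, "female": 0.31}
    return config


def _named_streams(seed: int, feature_names: list[str]) -> dict[str, np.random.Generator]:
    """Labeled child streams so adding a feature never perturbs earlier draws."""
    labels = ["smoking", "ses", "disease", "peak_flow"] + [
        f"symptom:{name}" for name in feature_names
    ]
    children = np.random.SeedSequence(seed).spawn(len(labels))
    return {label: np.random.default_rng(child) for label, child in zip(labels, children)}


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a cohort satisfying every configured quota exactly.

    Sampling order: gender is fixed by quota; smoking is assigned by exact
    per-gender quota, then reconciled with the SES targets by allocating
    smokers preferentially to low SES; disease categories are filled by
    weighted sampling without replacement where smoking multiplies the odds
    of the COPD categories; symptoms and peak flow are drawn per record from
    disease-conditional distributions.  Identical seeds give identical
    cohorts.
    """
    config.validate()
    n = config.n_total
    features = config.feature_names
    streams = _named_streams(config.seed, features)

    genders = np.array(["male"] * config.n_male + ["female"] * config.n_female)

    # Smoking: exact quota per gender.
    smoking = np.zeros(n, dtype=int)
    for gender in ("male", "female"):
        idx = np.flatnonzero(genders == gender)
        rate = config.smoking_rate_by_gender.get(gender, 0.0)
        k = _round_half_up(rate * len(idx))
        if k > len(idx):
            raise ConfigurationError(
                f"{k} {gender} smokers requested but only {len(idx)} {gender} records"
            )
        chosen = streams["smoking"].choice(idx, size=k, replace=False)
        smoking[chosen] = 1

    # SES: exact low/high quota; smokers preferentially low-SES so the
    # configured SES-smoking gradient holds as closely as the gender quota
    # allows.
    n_low = _round_half_up(config.ses_split * n)
    smokers = np.flatnonzero(smoking == 1)
    nonsmokers = np.flatnonzero(smoking == 0)
    s = len(smokers)
    w_low = config.smoking_rate_by_ses.get("low", 0.5) * n_low
    w_high = config.smoking_rate_by_ses.get("high", 0.5) * (n - n_low)
    if w_low + w_high > 0:
        t_low = _round_half_up(s * w_low / (w_low + w_high))
    else:
        t_low = _round_half_up(s * n_low / n) if n else 0
    t_low = min(t_low, n_low, s)
    t_low = max(t_low, n_low - len(nonsmokers))
    ses = np.array(["high"] * n, dtype=object)
    low_smokers = streams["ses"].choice(smokers, size=t_low, replace=False) if s else []
    ses[np.asarray(low_smokers, dtype=int)] = "low"
    low_nonsmokers = streams["ses"].choice(
        nonsmokers, size=n_low - t_low, replace=False
    )
    ses[np.asarray(low_nonsmokers, dtype=int)] = "low"

    # Disease categories: COPD-bearing categories first, with smoker-inflated
    # odds (Gumbel top-k = weighted sampling without replacement), the rest by
    # uniform partition of the remaining records.
    category = np.array([""] * n, dtype=object)
    remaining = np.arange(n)
    rng_disease = streams["disease"]
    for cat in _SMOKING_WEIGHTED:
        quota = config.disease_counts.get(cat, 0)
        if quota == 0:
            continue
        if quota > len(remaining):
            raise ConfigurationError(f"quota for {cat!r} exceeds remaining records")
        log_w = config.smoking_copd_weight * smoking[remaining]
        keys = rng_disease.gumbel(size=len(remaining)) + log_w
        take = remaining[np.argsort(keys)[::-1][:quota]]
        category[take] = cat
        remaining = np.setdiff1d(remaining, take)
    shuffled = rng_disease.permutation(remaining)
    offset = 0
    for cat in DISEASE_CATEGORIES:
        if cat in _SMOKING_WEIGHTED:
            continue
        quota = config.disease_counts.get(cat, 0)
        category[shuffled[offset : offset + quota]] = cat
        offset += quota

    # Peak flow: disease-conditional Gaussian ratio, clipped and discretized.
    rng_pf = streams["peak_flow"]
    ratios = np.empty(n)
    for i in range(n):
        params = config.peak_flow_params[category[i]]
        ratios[i] = max(0.0, rng_pf.normal(params["mean"], params["sd"]))
    pf_levels = [discretize_peak_flow(r, config.peak_flow_cuts) for r in ratios]

    # Symptoms: one stream per feature, disease-conditional Bernoulli.
    symptoms = {}
    for name in features:
        rng_f = streams[f"symptom:{name}"]
        p = np.array([config.symptom_emission[category[i]][name] for i in range(n)])
        symptoms[name] = (rng_f.random(n) < p).astype(int)

    width = max(3, len(str(n)))
    records = [
        PatientRecord(
            patient_id=f"P{i + 1:0{width}d}",
            gender=str(genders[i]),
            ses=str(ses[i]),
            smoking=int(smoking[i]),
            peak_flow_category=pf_levels[i],
            questionnaire={name: int(symptoms[name][i]) for name in features},
            diseases=_CATEGORY_TOKENS[category[i]],
        )
        for i in range(n)
    ]
    cohort = Cohort(records=records, feature_names=features, provenance="generated")
    cohort.validate()
    return cohort


def inject_group_noise(cohort: Cohort, noise: NoiseInjection) -> Cohort:
    """Flip questionnaire bits of one group's records at ``flip_rate``.

    Only the targeted records are touched; each feature bit flips
    independently, so the expected flipped fraction equals ``flip_rate``.
    Returns a new cohort, leaving the input unchanged.
    """
    noise.validate()
    attribute, level = noise.target_group
    if str(level) not in cohort.group_levels(attribute):
        raise ConfigurationError(f"no records with {attribute}={level!r}")
    out = cohort.copy()
    rng = np.random.default_rng(noise.seed)
    for record in out.records:
        if str(record.attribute(attribute)) != str(level):
            continue
        for name in out.feature_names:
            if rng.random() < noise.flip_rate:
                record.questionnaire[name] = 1 - record.questionnaire[name]
    return out
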