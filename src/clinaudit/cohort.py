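"""Tabular patient-cohort data model, CSV I/O and descriptive crosstabs.

A cohort is an ordered collection of patients, each carrying protected
attributes (gender, socio-economic status), a smoking flag, a discretized
peak-flow reading, a panel of binary questionnaire symptoms, and a set of
pulmonary-disease labels drawn from {COPD, Asthma, AR, Other}.  A patient
with an empty disease set is a healthy control.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import pandas as pd

from .errors import EmptyClassError, ParseError, SchemaError

MANDATORY_COLUMNS = [
    "patient_id",
    "gender",
    "ses",
    "smoking",
    "peak_flow_category",
    "diseases",
]

GENDER_LEVELS = ("male", "female")
SES_LEVELS = ("low", "high")
PEAK_FLOW_LEVELS = ("high", "medium", "low")
#: Canonical ordering of disease tokens (used for serialization).
DISEASE_TOKENS = ("COPD", "Asthma", "AR", "Other")
#: Diseases for which one-vs-rest models are trained.
MODELED_DISEASES = ("COPD", "Asthma", "AR")

#: Record attributes (beyond questionnaire features) usable for grouping.
GROUP_ATTRIBUTES = ("gender", "ses", "smoking", "peak_flow_category")


@dataclass
class PatientRecord:
    """One study subject.

    ``questionnaire`` maps symptom names to 0/1 indicators; ``diseases`` is a
    frozenset of tokens from :data:`DISEASE_TOKENS`.  A record is healthy iff
    its disease set is empty ("Other" counts as a label, not as healthy).
    """

    patient_id: str
    gender: str
    ses: str
    smoking: int
    peak_flow_category: str
    questionnaire: dict[str, int] = field(default_factory=dict)
    diseases: frozenset[str] = field(default_factory=frozenset)

    @property
    def is_healthy(self) -> bool:
        return len(self.diseases) == 0

    def validate(self) -> None:
        if self.gender not in GENDER_LEVELS:
            raise SchemaError(f"unknown gender {self.gender!r}")
        if self.ses not in SES_LEVELS:
            raise SchemaError(f"unknown ses {self.ses!r}")
        if self.smoking not in (0, 1):
            raise SchemaError(f"smoking must be 0/1, got {self.smoking!r}")
        if self.peak_flow_category not in PEAK_FLOW_LEVELS:
            raise SchemaError(
                f"peak_flow_category must be one of {PEAK_FLOW_LEVELS}, "
                f"got {self.peak_flow_category!r}"
            )
        for name, value in self.questionnaire.items():
            if value not in (0, 1):
                raise SchemaError(f"questionnaire item {name!r} must be 0/1")
        unknown = self.diseases - set(DISEASE_TOKENS)
        if unknown:
            raise SchemaError(f"unknown disease tokens {sorted(unknown)}")

    def attribute(self, name: str):
        """Look up a grouping attribute or questionnaire feature by name."""
        if name in GROUP_ATTRIBUTES:
            return getattr(self, name)
        if name in self.questionnaire:
            return self.questionnaire[name]
        raise SchemaError(f"unknown attribute or feature {name!r}")


@dataclass
class Cohort:
    """Ordered collection of records sharing one questionnaire panel."""

    records: list[PatientRecord]
    feature_names: list[str]
    provenance: str = "loaded"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise SchemaError("patient_id values are not unique")
        expected = set(self.feature_names)
        for r in self.records:
            r.validate()
            if set(r.questionnaire) != expected:
                raise SchemaError(
                    f"record {r.patient_id} does not carry the shared "
                    f"questionnaire panel"
                )

    def subset(self, indices) -> "Cohort":
        """New cohort holding the records at ``indices`` (original order kept
        as given)."""
        return Cohort(
            records=[self.records[i] for i in indices],
            feature_names=list(self.feature_names),
            provenance=self.provenance,
        )

    def copy(self) -> "Cohort":
        return Cohort(
            records=[copy.deepcopy(r) for r in self.records],
            feature_names=list(self.feature_names),
            provenance=self.provenance,
        )

    def group_levels(self, attribute: str) -> list[str]:
        """Distinct values of a grouping attribute, sorted for determinism."""
        return sorted({str(r.attribute(attribute)) for r in self.records})

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "patient_id": r.patient_id,
                "gender": r.gender,
                "ses": r.ses,
                "smoking": r.smoking,
                "peak_flow_category": r.peak_flow_category,
                "diseases": ";".join(
                    t for t in DISEASE_TOKENS if t in r.diseases
                ),
            }
            for name in self.feature_names:
                row[name] = r.questionnaire[name]
            rows.append(row)
        return pd.DataFrame(rows, columns=MANDATORY_COLUMNS + self.feature_names)


def _parse_binary(value, column: str, row: int) -> int:
    text = str(value).strip()
    if text in ("0", "1"):
        return int(text)
    raise ParseError(
        f"non-binary value {value!r} in column {column!r} at data row {row}"
    )


def read_cohort_csv(path, schema="auto") -> Cohort:
    """Read a cohort from CSV.

    Mandatory columns are ``patient_id,gender,ses,smoking,peak_flow_category,
    diseases`` (diseases as ``;``-joined tokens, empty string = healthy).
    With ``schema="auto"`` every remaining column is treated as a binary
    questionnaire feature; a feature-name list restricts the panel explicitly.
    Missing or non-binary feature values are rejected with the row index.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for column in MANDATORY_COLUMNS:
        if column not in frame.columns:
            raise SchemaError(f"missing mandatory column {column!r}")
    if schema == "auto":
        feature_names = [c for c in frame.columns if c not in MANDATORY_COLUMNS]
    else:
        feature_names = list(schema)
        missing = [c for c in feature_names if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing feature columns {missing}")

    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row = row._asdict()
        tokens = [t for t in str(row["diseases"]).split(";") if t]
        record = PatientRecord(
            patient_id=str(row["patient_id"]),
            gender=str(row["gender"]),
            ses=str(row["ses"]),
            smoking=_parse_binary(row["smoking"], "smoking", i),
            peak_flow_category=str(row["peak_flow_category"]),
            questionnaire={
                name: _parse_binary(row[name], name, i) for name in feature_names
            },
            diseases=frozenset(tokens),
        )
        records.append(record)
    cohort = Cohort(records=records, feature_names=feature_names, provenance="loaded")
    cohort.validate()
    return cohort


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort as UTF-8 CSV with a stable column order."""
    cohort.to_dataframe().to_csv(path, index=False)


def select_single_disease_training_set(
    cohort: Cohort, disease: str, negative_policy: str = "healthy"
) -> Cohort:
    """Build the one-vs-rest training subset for a disease model.

    Positives are records whose disease set is exactly ``{disease}`` —
    comorbid records are excluded so the positive label is unambiguous.
    Negatives default to healthy controls only (``negative_policy="healthy"``);
    ``"rest"`` instead keeps every record lacking the disease (comorbid with
    other diseases and "Other" included).
    """
    if disease not in MODELED_DISEASES:
        raise ValueError(
            f"disease must be one of {MODELED_DISEASES}, got {disease!r}"
        )
    if negative_policy not in ("healthy", "rest"):
        raise ValueError(f"unknown negative_policy {negative_policy!r}")
    indices = []
    n_pos = 0
    for i, r in enumerate(cohort.records):
        if r.diseases == frozenset({disease}):
            indices.append(i)
            n_pos += 1
        elif negative_policy == "healthy" and r.is_healthy:
            indices.append(i)
        elif negative_policy == "rest" and disease not in r.diseases:
            indices.append(i)
    if n_pos == 0:
        raise EmptyClassError(f"no single-disease positives for {disease!r}")
    if n_pos == len(indices):
        raise EmptyClassError(f"no negatives for {disease!r} under policy")
    return cohort.subset(indices)


@dataclass
class CrosstabResult:
    """Feature-by-group contingency summary (e.g. smoking by gender)."""

    group_attribute: str
    feature: str
    #: group level -> (count with feature, count without feature)
    per_group_counts: dict[str, tuple[int, int]]
    #: group level -> fraction of the group with the feature
    per_group_rate: dict[str, float]


def feature_crosstab(
    cohort: Cohort, feature: str, group_attribute: str
) -> CrosstabResult:
    """Count a binary feature within each level of a grouping attribute."""
    counts: dict[str, list[int]] = {}
    for r in cohort.records:
        level = str(r.attribute(group_attribute))
        value = int(r.attribute(feature))
        cell = counts.setdefault(level, [0, 0])
        if value:
            cell[0] += 1
        else:
            cell[1] += 1
    per_group_counts = {g: (c[0], c[1]) for g, c in sorted(counts.items())}
    per_group_rate = {
        g: c[0] / (c[0] + c[1]) for g, c in per_group_counts.items()
    }
    return CrosstabResult(
        group_attribute=group_attribute,
        feature=feature,
        per_group_counts=per_group_counts,
        per_group_rate=per_group_rate,
    )


def discretize_peak_flow(raw_ratio: float, cuts: tuple[float, float] = (0.8, 0.5)) -> str:
    """Map a peak-flow reading (fraction of predicted normal) to a level.

    ``high`` if the ratio is at or above the upper cut, ``low`` if strictly
    below the lower cut, ``medium`` otherwise (boundaries belong upward).
    """
    upper, lower = cuts
    if not (0 < lower < upper <= 1):
        raise ValueError(f"cuts must be strictly decreasing in (0, 1], got {cuts}")
    if raw_ratio < 0:
        raise ValueError(f"peak-flow ratio must be non-negative, got {raw_ratio}")
    if raw_ratio >= upper:
        return "high"
    if raw_ratio >= lower:
        return "medium"
    return "low"
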