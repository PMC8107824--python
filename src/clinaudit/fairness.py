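"""Group-fairness assessment and operating-point selection.

Three group-fairness criteria for a binary classifier over groups a and b:

* demographic parity (independence): P(Yhat=1|G=a) = P(Yhat=1|G=b);
* equality of opportunity (separation on positives): equal true-positive
  rates;
* equality of odds: equal true-positive AND false-positive rates —
  geometrically a common point of the two groups' ROC curves.

With unequal base rates and an imperfect classifier these criteria cannot
all hold at once, so the toolkit reports the empirical gap of each at a
chosen operating point rather than pretending all can be zeroed.  The
equalized-odds point is found either as the shared threshold minimizing
max(tpr gap, fpr gap), or as the geometric intersection of the two
piecewise-linear ROC curves with per-group thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import metrics
from .errors import ClinauditError
from .metrics import ROCCurve


@dataclass
class GroupRate:
    positive_rate: float
    tpr: float  # nan when the group has no positives
    fpr: float  # nan when the group has no negatives
    prevalence: float
    n: int


@dataclass
class OperatingPoint:
    """A deployed decision rule: one threshold per group (identical values in
    shared mode) and the (fpr, tpr) each group achieves there."""

    mode: str  # "shared_threshold" | "per_group_threshold"
    thresholds: dict[str, float]
    achieved: dict[str, tuple[float, float]]
    accuracy_at_point: float | None = None
    #: all interior ROC intersections found (per-group mode)
    intersections: list[tuple[float, float]] = field(default_factory=list)
    #: set when per-group mode fell back to the closest-approach point
    no_intersection_warning: bool = False


@dataclass
class FairnessReport:
    criterion: str
    gaps: dict[str, float | None]
    satisfied_at_tolerance: bool | None
    tolerance: float
    rates: dict[str, GroupRate]
    operating_point: OperatingPoint | None
    note: str | None = None

    def to_dict(self) -> dict:
        point = None
        if self.operating_point is not None:
            point = {
                "mode": self.operating_point.mode,
                "thresholds": dict(self.operating_point.thresholds),
                "achieved": {
                    g: list(p) for g, p in self.operating_point.achieved.items()
                },
                "accuracy_at_point": self.operating_point.accuracy_at_point,
            }
        return {
            "criterion": self.criterion,
            "gaps": dict(self.gaps),
            "satisfied_at_tolerance": self.satisfied_at_tolerance,
            "tolerance": self.tolerance,
            "rates": {
                g: {"positive_rate": r.positive_rate, "tpr": r.tpr,
                    "fpr": r.fpr, "prevalence": r.prevalence, "n": r.n}
                for g, r in self.rates.items()
            },
            "operating_point": point,
            "note": self.note,
        }


def group_rates(scores, labels, groups, operating_point) -> dict[str, GroupRate]:
    """Exact empirical rates per group at a threshold or operating point.

    ``operating_point`` may be a single shared threshold (float) or an
    :class:`OperatingPoint` carrying per-group thresholds.  A group missing
    one class gets nan for the undefined rate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    groups = np.asarray([str(g) for g in groups])
    out: dict[str, GroupRate] = {}
    for level in sorted(str(g) for g in set(groups)):
        mask = groups == level
        if isinstance(operating_point, OperatingPoint):
            if level not in operating_point.thresholds:
                raise LookupError(f"no threshold for group {level!r}")
            threshold = operating_point.thresholds[level]
        else:
            threshold = float(operating_point)
        s, y = scores[mask], labels[mask]
        predicted = s >= threshold
        n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
        out[level] = GroupRate(
            positive_rate=float(np.mean(predicted)),
            tpr=float(np.mean(predicted[y == 1])) if n_pos else float("nan"),
            fpr=float(np.mean(predicted[y == 0])) if n_neg else float("nan"),
            prevalence=n_pos / (n_pos + n_neg),
            n=int(mask.sum()),
        )
    return out


def _two_levels(rates: dict[str, GroupRate]) -> tuple[GroupRate, GroupRate]:
    if len(rates) != 2:
        raise ClinauditError(f"exactly two groups required, got {len(rates)}")
    a, b = sorted(rates)
    return rates[a], rates[b]


def demographic_parity_gap(rates: dict[str, GroupRate]) -> float:
    """|positive_rate(a) - positive_rate(b)|; 0 iff independence holds here."""
    a, b = _two_levels(rates)
    return abs(a.positive_rate - b.positive_rate)


def equal_opportunity_gap(rates: dict[str, GroupRate]) -> float:
    """|tpr(a) - tpr(b)|; 0 iff separation holds on the positives here."""
    a, b = _two_levels(rates)
    if math.isnan(a.tpr) or math.isnan(b.tpr):
        raise ClinauditError("tpr undefined in a group (no positives)")
    return abs(a.tpr - b.tpr)


def equalized_odds_gap(rates: dict[str, GroupRate]) -> tuple[float, float]:
    """(tpr gap, fpr gap); both 0 iff equalized odds holds here."""
    a, b = _two_levels(rates)
    if any(math.isnan(v) for v in (a.tpr, b.tpr, a.fpr, b.fpr)):
        raise ClinauditError("a rate is undefined in one group")
    return abs(a.tpr - b.tpr), abs(a.fpr - b.fpr)


def _segment_intersections(p1, p2, q1, q2, eps=1e-12):
    """Proper intersection point(s) of two 2-D segments (parallel skipped)."""
    d1 = p2 - p1
    d2 = q2 - q1
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < eps:
        return []
    diff = q1 - p1
    t = (diff[0] * d2[1] - diff[1] * d2[0]) / denom
    u = (diff[0] * d1[1] - diff[1] * d1[0]) / denom
    if -eps <= t <= 1 + eps and -eps <= u <= 1 + eps:
        return [(p1 + np.clip(t, 0, 1) * d1, float(np.clip(t, 0, 1)),
                 float(np.clip(u, 0, 1)))]
    return []


def _curve_points(curve: ROCCurve) -> np.ndarray:
    return np.column_stack([curve.fpr, curve.tpr])


def _finite_thresholds(curve: ROCCurve) -> np.ndarray:
    t = np.array(curve.thresholds, dtype=float)
    t[~np.isfinite(t)] = 1.0  # the all-negative anchor; scores live in [0,1]
    return np.clip(t, 0.0, 1.0)


def _interpolate_threshold(curve: ROCCurve, seg: int, frac: float) -> float:
    t = _finite_thresholds(curve)
    return float(t[seg] + frac * (t[seg + 1] - t[seg]))


def _is_anchor(point, eps=1e-9) -> bool:
    return (abs(point[0]) < eps and abs(point[1]) < eps) or (
        abs(point[0] - 1) < eps and abs(point[1] - 1) < eps
    )


def _closest_approach(pa: np.ndarray, pb: np.ndarray):
    """Closest pair of vertices between two polylines (fallback point)."""
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return (pa[i] + pb[j]) / 2.0, int(i), int(j)


def find_equalized_odds_point(
    roc_a: ROCCurve, roc_b: ROCCurve, mode: str = "shared_threshold"
) -> OperatingPoint:
    """Operating point enforcing (approximate) equalized odds.

    shared_threshold (default): sweep the union of both curves' thresholds
    and take the one minimizing max(tpr gap, fpr gap); ties go to the higher
    tpr, then the lower fpr.  Candidates where both groups sit at a trivial
    anchor ((0,0) or (1,1)) are excluded unless nothing else exists.

    per_group_threshold: geometric intersection of the two piecewise-linear
    curves, excluding the trivial anchors; among multiple interior
    intersections the one with the highest tpr is returned and all are
    reported.  Without an interior intersection the closest-approach point
    is returned with a warning flag.
    """
    label_a = roc_a.group_label or "a"
    label_b = roc_b.group_label or "b"
    if mode == "shared_threshold":
        candidates = np.unique(
            np.concatenate([_finite_thresholds(roc_a), _finite_thresholds(roc_b)])
        )
        best = None
        for lam in candidates:
            fa = roc_a.point_at_threshold(lam)
            fb = roc_b.point_at_threshold(lam)
            trivial = (
                _is_anchor(fa) and _is_anchor(fb)
                and abs(fa[0] - fb[0]) < 1e-9 and abs(fa[1] - fb[1]) < 1e-9
            )
            gap = max(abs(fa[1] - fb[1]), abs(fa[0] - fb[0]))
            key = (trivial, gap, -(fa[1] + fb[1]) / 2, (fa[0] + fb[0]) / 2)
            if best is None or key < best[0]:
                best = (key, lam, fa, fb)
        _, lam, fa, fb = best
        return OperatingPoint(
            mode=mode,
            thresholds={label_a: float(lam), label_b: float(lam)},
            achieved={label_a: fa, label_b: fb},
        )
    if mode != "per_group_threshold":
        raise ValueError(f"unknown mode {mode!r}")

    pa, pb = _curve_points(roc_a), _curve_points(roc_b)
    hits = []
    for i in range(len(pa) - 1):
        for j in range(len(pb) - 1):
            for point, t, u in _segment_intersections(
                pa[i], pa[i + 1], pb[j], pb[j + 1]
            ):
                if _is_anchor(point):
                    continue
                hits.append((point, i, t, j, u))
    if hits:
        hits.sort(key=lambda h: (-h[0][1], h[0][0]))
        point, i, t, j, u = hits[0]
        return OperatingPoint(
            mode=mode,
            thresholds={
                label_a: _interpolate_threshold(roc_a, i, t),
                label_b: _interpolate_threshold(roc_b, j, u),
            },
            achieved={
                label_a: (float(point[0]), float(point[1])),
                label_b: (float(point[0]), float(point[1])),
            },
            intersections=[(float(p[0]), float(p[1])) for p, *_ in hits],
        )
    point, i, j = _closest_approach(pa, pb)
    return OperatingPoint(
        mode=mode,
        thresholds={
            label_a: float(_finite_thresholds(roc_a)[i]),
            label_b: float(_finite_thresholds(roc_b)[j]),
        },
        achieved={
            label_a: (float(pa[i][0]), float(pa[i][1])),
            label_b: (float(pb[j][0]), float(pb[j][1])),
        },
        no_intersection_warning=True,
    )


def _shared_threshold_minimizing(scores, labels, groups, objective):
    """Sweep all observed scores as shared thresholds, minimize ``objective``
    over non-trivial points; ties to higher mean tpr."""
    scores = np.asarray(scores, dtype=float)
    candidates = np.unique(np.concatenate([scores, [np.max(scores) + 1.0]]))
    best = None
    for lam in candidates:
        rates = group_rates(scores, labels, groups, float(lam))
        a, b = _two_levels(rates)
        trivial = {a.positive_rate, b.positive_rate} <= {0.0} or {
            a.positive_rate, b.positive_rate
        } <= {1.0}
        value = objective(rates)
        mean_tpr = np.nanmean([a.tpr, b.tpr])
        key = (trivial, value, -mean_tpr)
        if best is None or key < best[0]:
            best = (key, float(lam))
    return best[1]


def assess_fairness(
    scores, labels, groups, criterion: str = "equalized_odds",
    tolerance: float = 0.02,
) -> FairnessReport:
    """Choose the operating point for a fairness criterion and report all
    three gaps there.

    parity: shared threshold equalizing positive rates; opportunity: shared
    threshold minimizing the tpr gap; odds: the shared-threshold equalized-
    odds point.  The satisfied flag tests the criterion's own gap(s) against
    the tolerance.
    """
    if criterion not in ("demographic_parity", "equal_opportunity", "equalized_odds"):
        raise ValueError(f"unknown criterion {criterion!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    groups = np.asarray([str(g) for g in groups])
    levels = sorted(str(g) for g in set(groups))
    if len(levels) < 2:
        return FairnessReport(
            criterion=criterion,
            gaps={"parity_gap": None, "tpr_gap": None, "fpr_gap": None},
            satisfied_at_tolerance=None, tolerance=tolerance,
            rates=group_rates(scores, labels, groups, 0.5),
            operating_point=None,
            note="single group present; between-group gaps are undefined",
        )
    if criterion == "equalized_odds":
        curves = {
            level: metrics.roc_curve(
                scores[groups == level], labels[groups == level], group_label=level
            )
            for level in levels
        }
        point = find_equalized_odds_point(
            curves[levels[0]], curves[levels[1]], mode="shared_threshold"
        )
        lam = point.thresholds[levels[0]]
    else:
        if criterion == "demographic_parity":
            objective = demographic_parity_gap
        else:
            objective = equal_opportunity_gap
        lam = _shared_threshold_minimizing(scores, labels, groups, objective)
        point = None
    rates = group_rates(scores, labels, groups, lam)
    tpr_gap, fpr_gap = equalized_odds_gap(rates)
    gaps = {
        "parity_gap": demographic_parity_gap(rates),
        "tpr_gap": tpr_gap,
        "fpr_gap": fpr_gap,
    }
    counts = metrics.confusion_counts(scores, labels, lam)
    if point is None:
        point = OperatingPoint(
            mode="shared_threshold",
            thresholds={level: float(lam) for level in levels},
            achieved={
                level: (rates[level].fpr, rates[level].tpr) for level in levels
            },
        )
    point.accuracy_at_point = metrics.accuracy(counts)
    if criterion == "demographic_parity":
        satisfied = gaps["parity_gap"] <= tolerance
    elif criterion == "equal_opportunity":
        satisfied = gaps["tpr_gap"] <= tolerance
    else:
        satisfied = max(gaps["tpr_gap"], gaps["fpr_gap"]) <= tolerance
    return FairnessReport(
        criterion=criterion, gaps=gaps, satisfied_at_tolerance=bool(satisfied),
        tolerance=tolerance, rates=rates, operating_point=point,
    )


def check_criteria_compatibility(
    rates: dict[str, GroupRate], tolerance: float = 0.0
) -> dict[str, bool]:
    """Flag which of the three criteria the given rates satisfy at tolerance.

    With unequal prevalences and a classifier that discriminates (tpr != fpr)
    the three flags cannot all be true at tolerance 0 — positive rates are
    prevalence-weighted mixtures of tpr and fpr, so equalized odds forces a
    parity gap of |prevalence gap| * |tpr - fpr|.
    """
    a, b = _two_levels(rates)
    tpr_gap = abs(a.tpr - b.tpr)
    fpr_gap = abs(a.fpr - b.fpr)
    return {
        "demographic_parity": abs(a.positive_rate - b.positive_rate) <= tolerance,
        "equal_opportunity": tpr_gap <= tolerance,
        "equalized_odds": max(tpr_gap, fpr_gap) <= tolerance,
    }
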