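"""Cost-weighted ROC operating points and prevalence-aware predictive values.

The operating point on an empirical ROC curve is chosen where the curve's
tangent has slope

    S = ((1 - p) / p) * delta,

with ``p`` the prevalence of the positive outcome and ``delta`` the
"error overcost" ratio

    delta = (cost_FP - cost_RN) / (cost_FN - cost_RP),

i.e. the net cost of a false positive over the net cost of a false
negative.  A delta of 2 doubles the weight of false positives, pushing
the cutoff toward high positive predictive value.  Empirical ROC curves
are step functions, so the tangent condition is realised as maximisation
of the linear functional

    J(point) = Se - S * (1 - Sp),

which on the upper convex hull selects exactly the point where adjacent
hull-segment slopes bracket S.  Predictive values follow the standard
prevalence-weighted forms

    PPV = p Se / (p Se + (1 - p)(1 - Sp))
    NPV = (1 - p) Sp / ((1 - p) Sp + p (1 - Se)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort_model import (
    GOOD_VS_REST,
    OutcomeDichotomy,
    PatientRecord,
    dichotomize,
    score_total,
)
from .course_dynamics import classify_course, impute_gp_items, nds_interval_stable

__all__ = [
    "CostSpec",
    "ThresholdCriterion",
    "ROCPoint",
    "ThresholdResult",
    "InvalidCostError",
    "delta_ratio",
    "target_slope",
    "build_roc",
    "select_cutoff",
    "predictive_values",
    "derive_thresholds",
    "predictor_values",
]

POSITIVE_IF_ABOVE = "positive_if_above"
POSITIVE_IF_BELOW = "positive_if_below"


class InvalidCostError(ValueError):
    """Raised when a cost specification leaves delta undefined or <= 0."""


@dataclass(frozen=True)
class CostSpec:
    """Unit costs of false positive / real negative / false negative /
    real positive decisions."""

    cost_FP: float
    cost_RN: float
    cost_FN: float
    cost_RP: float

    def __post_init__(self) -> None:
        if any(c < 0 for c in (self.cost_FP, self.cost_RN,
                               self.cost_FN, self.cost_RP)):
            raise InvalidCostError("costs must be non-negative")
        if self.cost_FN <= self.cost_RP or self.cost_FP <= self.cost_RN:
            raise InvalidCostError(
                "need cost_FN > cost_RP and cost_FP > cost_RN for a "
                "positive, well-defined delta")


def delta_ratio(costs: CostSpec) -> float:
    """Error-overcost ratio delta = (cost_FP - cost_RN)/(cost_FN - cost_RP)."""
    return (costs.cost_FP - costs.cost_RN) / (costs.cost_FN - costs.cost_RP)


def target_slope(p: float, delta: float) -> float:
    """ROC tangent slope S = ((1 - p)/p) * delta at prevalence p."""
    if not 0 < p < 1:
        raise ValueError(f"prevalence p={p} must lie in (0, 1)")
    if delta <= 0:
        raise InvalidCostError("delta must be > 0")
    return (1 - p) / p * delta


@dataclass(frozen=True)
class ThresholdCriterion:
    """Prevalence, cost ratio and the implied target tangent slope."""

    prevalence_p: float
    delta: float
    target_slope_S: float

    def __post_init__(self) -> None:
        expected = target_slope(self.prevalence_p, self.delta)
        if not math.isclose(self.target_slope_S, expected, rel_tol=0, abs_tol=1e-12 * max(1.0, expected)):
            raise ValueError(
                f"target_slope_S={self.target_slope_S} inconsistent with "
                f"((1-p)/p)*delta={expected}")

    @classmethod
    def from_prevalence(cls, p: float, delta: float = 2.0) -> "ThresholdCriterion":
        return cls(prevalence_p=p, delta=delta,
                   target_slope_S=target_slope(p, delta))


@dataclass(frozen=True)
class ROCPoint:
    cutoff: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class ThresholdResult:
    """A selected cutoff with its operating characteristics.

    ``ppv``/``npv`` are None when undefined (no predicted positives /
    negatives at the operating point)."""

    cutoff: float
    orientation: str
    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "orientation": self.orientation,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def _check_orientation(orientation: str) -> None:
    if orientation not in (POSITIVE_IF_ABOVE, POSITIVE_IF_BELOW):
        raise ValueError(f"unknown orientation {orientation!r}")


def build_roc(scores: Sequence[float], labels: Sequence[int],
              orientation: str = POSITIVE_IF_ABOVE) -> list[ROCPoint]:
    """Empirical ROC: one operating point per distinct score plus the two
    trivial endpoints, ties grouped at one cutoff.

    Cutoffs are placed at midpoints between adjacent distinct scores
    (with -inf/+inf endpoints); a positive call is score > cutoff for
    ``positive_if_above`` and score < cutoff for ``positive_if_below``.
    """
    _check_orientation(orientation)
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1 or len(s) == 0:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    distinct, inverse = np.unique(s, return_inverse=True)
    pos_at = np.bincount(inverse, weights=y, minlength=len(distinct))
    neg_at = np.bincount(inverse, minlength=len(distinct)) - pos_at
    cutoffs = np.concatenate(
        ([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]))
    # cumulative positives/negatives strictly below each cutoff
    below_pos = np.concatenate(([0.0], np.cumsum(pos_at)))
    below_neg = np.concatenate(([0.0], np.cumsum(neg_at)))
    if orientation == POSITIVE_IF_ABOVE:
        tp, fp = n_pos - below_pos, n_neg - below_neg
    else:
        tp, fp = below_pos, below_neg
    points = [ROCPoint(cutoff=float(c), sensitivity=float(t / n_pos),
                       specificity=float(1 - f / n_neg))
              for c, t, f in zip(cutoffs, tp, fp)]
    # order along the curve from (0, 0) to (1, 1) in (1-Sp, Se) space
    points.sort(key=lambda pt: (1 - pt.specificity, pt.sensitivity))
    return points


def predictive_values(p: float, sensitivity: float, specificity: float
                      ) -> tuple[Optional[float], Optional[float]]:
    """Prevalence-weighted (PPV, NPV); None where the denominator is 0."""
    for name, v in (("p", p), ("sensitivity", sensitivity),
                    ("specificity", specificity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name}={v} outside [0, 1]")
    ppv_den = p * sensitivity + (1 - p) * (1 - specificity)
    npv_den = (1 - p) * specificity + p * (1 - sensitivity)
    ppv = p * sensitivity / ppv_den if ppv_den > 0 else None
    npv = (1 - p) * specificity / npv_den if npv_den > 0 else None
    return ppv, npv


def select_cutoff(roc: Sequence[ROCPoint], criterion: ThresholdCriterion,
                  orientation: str = POSITIVE_IF_ABOVE) -> ThresholdResult:
    """The ROC point maximising Se - S (1 - Sp); ties break toward higher
    specificity (then lower sensitivity, for determinism)."""
    if not roc:
        raise ValueError("empty ROC")
    _check_orientation(orientation)
    S = criterion.target_slope_S
    best = max(roc, key=lambda pt: (pt.sensitivity - S * (1 - pt.specificity),
                                    pt.specificity, -pt.sensitivity))
    ppv, npv = predictive_values(criterion.prevalence_p,
                                 best.sensitivity, best.specificity)
    return ThresholdResult(cutoff=best.cutoff, orientation=orientation,
                           sensitivity=best.sensitivity,
                           specificity=best.specificity, ppv=ppv, npv=npv)


# ---------------------------------------------------------------------------
# Cohort-level derivation
# ---------------------------------------------------------------------------

PREDICTORS = ("nihss_initial", "plateau_min")


def predictor_values(cohort: Sequence[PatientRecord],
                     predictor: str) -> np.ndarray:
    """Predictor vector for a cohort: the initial (prehospital, imputed)
    NIHSS total or the plateau duration in minutes."""
    if predictor == "nihss_initial":
        vals = []
        for r in cohort:
            gp = r.nihss("gp")
            if gp is None:
                raise ValueError(f"patient {r.id}: no prehospital NIHSS")
            imputed, _ = impute_gp_items(gp, r.nihss("admission"),
                                         nds_interval_stable(r))
            vals.append(score_total(imputed).total)
        return np.asarray(vals, dtype=float)
    if predictor == "plateau_min":
        return np.asarray([classify_course(r).plateau_min for r in cohort],
                          dtype=float)
    raise ValueError(f"unknown predictor {predictor!r}; expected one of {PREDICTORS}")


def derive_thresholds(cohort: Sequence[PatientRecord],
                      dichotomy: OutcomeDichotomy,
                      predictor: str = "nihss_initial",
                      costs: Optional[CostSpec] = None,
                      delta: float = 2.0,
                      prevalence: Optional[float] = None) -> ThresholdResult:
    """Derive the cost-weighted operating cutoff for a predictor.

    Orientation is positive-if-below for good-outcome dichotomies (a mild
    or short deficit predicts recovery) and positive-if-above otherwise.
    Prevalence defaults to the cohort-empirical rate of the positive
    outcome; pass ``prevalence`` to override (e.g. a registry value).
    """
    if costs is not None:
        delta = delta_ratio(costs)
    scores = predictor_values(cohort, predictor)
    labels = np.array([dichotomize(r.mrs_discharge, dichotomy) for r in cohort])
    p = float(labels.mean()) if prevalence is None else float(prevalence)
    orientation = (POSITIVE_IF_BELOW if dichotomy.name == GOOD_VS_REST.name
                   else POSITIVE_IF_ABOVE)
    criterion = ThresholdCriterion.from_prevalence(p, delta)
    roc = build_roc(scores, labels, orientation)
    return select_cutoff(roc, criterion, orientation)
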