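"""External validation, score coherence and association testing; the
two-cohort derive/validate pipeline.

A threshold frozen on the derivation cohort is applied unchanged to an
independent validation cohort; sensitivity and specificity are
recomputed from the resulting confusion counts.  Score coherence between
instruments is the squared Pearson correlation of paired totals, and
categorical associations (e.g. regression within 24 h vs good outcome)
use the Pearson chi-square on the 2x2 table without continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort_model import (
    DEPENDENT_OR_DEAD_VS_REST,
    GOOD_VS_REST,
    POOR_VS_REST,
    OutcomeDichotomy,
    PatientRecord,
    dichotomize,
    score_total,
)
from .course_dynamics import classify_course
from .synthetic_cohort import (
    GeneratorConfig,
    generate_cohort,
    published_screening_registry,
)
from .screening import apply_exclusion_cascade
from .threshold_engine import (
    POSITIVE_IF_ABOVE,
    ThresholdResult,
    derive_thresholds,
    predictor_values,
)

__all__ = [
    "ValidationReport",
    "evaluate_threshold",
    "coherence_r2",
    "association_chi2",
    "run_all",
]


@dataclass(frozen=True)
class ValidationReport:
    """Confusion counts and rates of a frozen threshold on a new cohort.

    ``sensitivity``/``specificity`` are None when the corresponding
    outcome class is empty in the validation cohort."""

    threshold: ThresholdResult
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    cohort_n: int

    def __post_init__(self) -> None:
        if self.tp + self.fp + self.tn + self.fn != self.cohort_n:
            raise ValueError("confusion counts do not sum to cohort_n")

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold.to_dict(),
            "confusion": {"TP": self.tp, "FP": self.fp,
                          "TN": self.tn, "FN": self.fn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "cohort_n": self.cohort_n,
        }


def evaluate_threshold(cohort2: Sequence[PatientRecord],
                       threshold: ThresholdResult,
                       dichotomy: OutcomeDichotomy,
                       predictor: str = "nihss_initial") -> ValidationReport:
    """Apply a frozen cutoff/orientation to an independent cohort."""
    scores = predictor_values(cohort2, predictor)
    labels = np.array([dichotomize(r.mrs_discharge, dichotomy) for r in cohort2])
    if threshold.orientation == POSITIVE_IF_ABOVE:
        pred = scores > threshold.cutoff
    else:
        pred = scores < threshold.cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    se = tp / (tp + fn) if tp + fn > 0 else None
    sp = tn / (tn + fp) if tn + fp > 0 else None
    return ValidationReport(threshold=threshold, tp=tp, fp=fp, tn=tn, fn=fn,
                            sensitivity=se, specificity=sp,
                            cohort_n=len(cohort2))


def coherence_r2(series_a: Sequence[float], series_b: Sequence[float]) -> Optional[float]:
    """Squared Pearson correlation of paired score totals; None when a
    series is constant (correlation undefined)."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    r = stats.pearsonr(a, b).statistic
    return float(r * r)


def association_chi2(table: Sequence[Sequence[float]]) -> tuple[float, int]:
    """Pearson chi-square (no continuity correction) on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    chi2 = stats.chi2_contingency(t, correction=False).statistic
    return float(chi2), 1


# ---------------------------------------------------------------------------
# Full two-cohort pipeline
# ---------------------------------------------------------------------------

def _regressed_within_24h(summary) -> bool:
    return summary.label in ("total_regression", "partial_regression")


def run_all(seed: int = 0,
            n_derivation: int = 154,
            n_validation: int = 157,
            delta: float = 2.0,
            config: Optional[GeneratorConfig] = None) -> dict:
    """simulate -> screen -> classify -> derive thresholds -> validate.

    Generates a screening registry with the published exclusion counts, a
    derivation cohort and an independent validation cohort (distinct seed
    stream), derives cost-weighted NIHSS and plateau thresholds for the
    good- and poor-outcome dichotomies, freezes them, and re-evaluates
    them on the validation cohort.  Returns a JSON-serialisable manifest
    of every count, threshold and validation report.
    """
    base = config if config is not None else GeneratorConfig()
    cfg_a = replace(base, n_patients=n_derivation, seed=seed)
    cfg_b = replace(base, n_patients=n_validation, seed=seed + 10_000)

    registry = published_screening_registry(seed=seed)
    _, audit = apply_exclusion_cascade(registry)

    cohort_a = generate_cohort(cfg_a)
    cohort_b = generate_cohort(cfg_b)
    summaries = [classify_course(r) for r in cohort_a]

    course_counts: dict[str, int] = {}
    for s in summaries:
        course_counts[s.label] = course_counts.get(s.label, 0) + 1
    monophasic = sum(1 for s in summaries if s.phase == "monophasic")

    # admission-score coherence (NDS-1 vs NIHSS-1 totals)
    pairs = [(score_total(r.nds_1).total, score_total(r.nihss("admission")).total)
             for r in cohort_a if r.nds_1 is not None and r.nihss("admission")]
    r2 = coherence_r2([p[0] for p in pairs], [p[1] for p in pairs]) if len(pairs) >= 3 else None

    # regression within 24 h vs good prognosis (mRS 0-3)
    good03 = np.array([1 - dichotomize(r.mrs_discharge, DEPENDENT_OR_DEAD_VS_REST)
                       for r in cohort_a])
    regressed = np.array([int(_regressed_within_24h(s)) for s in summaries])
    table = [[int(np.sum((regressed == 1) & (good03 == 1))),
              int(np.sum((regressed == 1) & (good03 == 0)))],
             [int(np.sum((regressed == 0) & (good03 == 1))),
              int(np.sum((regressed == 0) & (good03 == 0)))]]
    chi2, df = association_chi2(table)

    analyses = {}
    for dname, dichotomy in (("good", GOOD_VS_REST), ("poor", POOR_VS_REST)):
        for predictor in ("nihss_initial", "plateau_min"):
            thr = derive_thresholds(cohort_a, dichotomy, predictor=predictor,
                                    delta=delta)
            report = evaluate_threshold(cohort_b, thr, dichotomy,
                                        predictor=predictor)
            analyses[f"{dname}_{predictor}"] = {
                "derivation": thr.to_dict(),
                "validation": report.to_dict(),
            }

    return {
        "seed": seed,
        "delta": delta,
        "screening_audit": audit.to_dict(),
        "derivation_n": len(cohort_a),
        "validation_n": len(cohort_b),
        "course_counts": course_counts,
        "monophasic_n": monophasic,
        "admission_score_coherence_r2": r2,
        "regression_vs_good_outcome": {
            "table": table, "chi2": chi2, "df": df,
            "p_value": float(stats.chi2.sf(chi2, df)),
        },
        "thresholds": analyses,
    }
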