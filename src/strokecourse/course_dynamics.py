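"""First-24-hour course classification and end-point extraction.

End points derived per patient:

* **NIHSS-max / NDS-max** — maxima of the serial totals over the first
  day (prehospital GP score, admission, 8 h, 16 h and 24 h
  examinations; the discharge score is not part of the first-day set);
* **plateau** — minutes spent at maximal deficit before regression
  begins, taken from the patient/family anamnesis when available and
  otherwise from the serial scores;
* **course** — monophasic (stable / total regression / partial
  regression) or polyphasic (fluctuating / progressive), built from
  step-wise change classification.

A step counts as *worsening* when the NIHSS rises by >= 4 points and the
NDS by >= 2 (conjunctively, when both instruments were observed over the
interval), as *regression* for the mirror-image decreases, and as
*stable* otherwise.  When only one instrument covers an interval its
criterion decides alone.

Unknown prehospital (GP) NIHSS items are completed from the admission
examination when the NDS was stable over the same interval; when the NDS
was unstable the item is disregarded and stays out of the GP total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .cohort_model import (
    IncompleteAssessmentError,
    NIHSSAssessment,
    PatientRecord,
    score_total,
)

__all__ = [
    "CourseSummary",
    "InsufficientDataError",
    "MissingPlateauError",
    "impute_gp_items",
    "classify_change",
    "classify_course",
    "plateau_duration",
    "nds_interval_stable",
]

NIHSS_DELTA = 4  # minimum NIHSS change for a worsening/regression step
NDS_DELTA = 2    # minimum NDS change for a worsening/regression step

FIRST_DAY_SOURCES = ("gp", "admission", "h8", "h16", "h24")

MONOPHASIC_LABELS = ("stable", "total_regression", "partial_regression")
POLYPHASIC_LABELS = ("fluctuating", "progressive")


class InsufficientDataError(ValueError):
    """Raised when a patient lacks the assessments an end point needs."""


class MissingPlateauError(ValueError):
    """Raised when no usable plateau information exists."""


@dataclass(frozen=True)
class CourseSummary:
    """Derived first-day course label, phase, score maxima and plateau."""

    phase: str            # monophasic | polyphasic
    label: str            # stable | total_regression | partial_regression |
                          # fluctuating | progressive
    nihss_max: int
    nds_max: int
    plateau_min: int
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = MONOPHASIC_LABELS if self.phase == "monophasic" else POLYPHASIC_LABELS
        if self.phase not in ("monophasic", "polyphasic") or self.label not in expected:
            raise ValueError(f"inconsistent phase/label {self.phase}/{self.label}")
        if not 0 <= self.plateau_min <= 1440:
            raise ValueError("plateau must lie within the 24 h window")


def nds_interval_stable(patient: PatientRecord) -> Optional[bool]:
    """Whether the NDS was stable (|change| < 2) between the prehospital
    evaluation and admission; None when either evaluation is missing."""
    if patient.nds_0 is None or patient.nds_1 is None:
        return None
    try:
        d = score_total(patient.nds_1).total - score_total(patient.nds_0).total
    except IncompleteAssessmentError:
        return None
    return abs(d) < NDS_DELTA


def impute_gp_items(nihss_gp: NIHSSAssessment,
                    nihss_1: Optional[NIHSSAssessment],
                    nds_stable: Optional[bool],
                    ) -> tuple[NIHSSAssessment, list[str]]:
    """Complete unknown GP items from the admission examination.

    Each unknown GP item takes the admission (NIHSS-1) value when the NDS
    was stable over the prehospital-to-admission interval; otherwise the
    item is *disregarded*: it stays unknown, is excluded from the GP
    total, and is returned in the disregarded list.

    Returns the (possibly identical) assessment and the names of the
    disregarded items.  Never decreases the number of known items.
    """
    unknown = [name for name, v in nihss_gp.items.items() if v is None]
    if not unknown:
        return nihss_gp, []
    disregarded: list[str] = []
    items = dict(nihss_gp.items)
    for name in unknown:
        ref = nihss_1.items.get(name) if nihss_1 is not None else None
        if nds_stable and ref is not None:
            items[name] = ref
        else:
            disregarded.append(name)
    if items == dict(nihss_gp.items):
        return nihss_gp, disregarded
    return NIHSSAssessment(timestamp=nihss_gp.timestamp, items=items,
                           source=nihss_gp.source), disregarded


def classify_change(delta_nihss: Optional[int],
                    delta_nds: Optional[int]) -> str:
    """Classify one interval as ``worsening``, ``regression`` or ``stable``.

    With both deltas observed the criteria are conjunctive (NIHSS moves
    by >= 4 *and* NDS by >= 2, in the same direction); with one score
    missing the available score's criterion decides alone.
    """
    if delta_nihss is None and delta_nds is None:
        raise InsufficientDataError("both score changes missing")
    crit = []
    if delta_nihss is not None:
        crit.append((delta_nihss >= NIHSS_DELTA, delta_nihss <= -NIHSS_DELTA))
    if delta_nds is not None:
        crit.append((delta_nds >= NDS_DELTA, delta_nds <= -NDS_DELTA))
    if all(up for up, _ in crit):
        return "worsening"
    if all(down for _, down in crit):
        return "regression"
    return "stable"


def _first_day_points(patient: PatientRecord
                      ) -> list[tuple[int, int, Optional[int]]]:
    """(timestamp, NIHSS total, NDS total or None) for the first-day
    examinations, with GP items imputed."""
    stable = nds_interval_stable(patient)
    nds0 = patient.nds_0
    nds1 = patient.nds_1
    points: list[tuple[int, int, Optional[int]]] = []
    for src in FIRST_DAY_SOURCES:
        a = patient.nihss(src)
        if a is None:
            continue
        if src == "gp":
            a, _ = impute_gp_items(a, patient.nihss("admission"), stable)
        try:
            tot = score_total(a).total
        except IncompleteAssessmentError:
            continue
        nds_tot: Optional[int] = None
        if src == "gp" and nds0 is not None and not nds0.incomplete:
            nds_tot = score_total(nds0).total
        elif src == "admission" and nds1 is not None and not nds1.incomplete:
            nds_tot = score_total(nds1).total
        points.append((a.timestamp, tot, nds_tot))
    return points


def _step_labels(points: Sequence[tuple[int, int, Optional[int]]]) -> list[str]:
    labels = []
    for (t0, n0, d0), (t1, n1, d1) in zip(points, points[1:]):
        d_nds = (d1 - d0) if (d0 is not None and d1 is not None) else None
        labels.append(classify_change(n1 - n0, d_nds))
    return labels


def classify_course(patient: PatientRecord) -> CourseSummary:
    """Classify the first-24-hour course and extract the end points.

    Direction changes are counted over consecutive step classifications:
    two or more alternations between worsening and regression make the
    course fluctuating; two or more consecutive worsening steps with no
    regression make it progressive (both polyphasic).  Otherwise the
    course is monophasic: a regression step present makes it a total
    regression when the final first-day NIHSS total is 0 and a partial
    regression when it is positive; with no qualifying step (including a
    single isolated worsening step) the deficit is stable.
    """
    points = _first_day_points(patient)
    if len(points) < 2:
        raise InsufficientDataError(
            f"patient {patient.id}: need >= 2 scored assessments in the first day")
    steps = _step_labels(points)
    moves = [s for s in steps if s != "stable"]
    alternations = sum(1 for a, b in zip(moves, moves[1:]) if a != b)

    consec_worsening = 0
    max_consec_worsening = 0
    for s in steps:
        consec_worsening = consec_worsening + 1 if s == "worsening" else 0
        max_consec_worsening = max(max_consec_worsening, consec_worsening)

    if alternations >= 2:
        phase, label = "polyphasic", "fluctuating"
    elif max_consec_worsening >= 2 and "regression" not in steps:
        phase, label = "polyphasic", "progressive"
    elif "regression" in steps:
        phase = "monophasic"
        label = "total_regression" if points[-1][1] == 0 else "partial_regression"
    else:
        phase, label = "monophasic", "stable"

    nihss_max = max(p[1] for p in points)
    nds_max = max((p[2] for p in points if p[2] is not None), default=0)

    warnings: list[str] = []
    plateau = plateau_duration(patient)
    if patient.plateau_anamnesis_min is not None:
        derived = _series_plateau(points, steps)
        if derived is not None and abs(derived - plateau) > 120:
            warnings.append(
                f"anamnesis plateau {plateau} min differs from series-derived "
                f"{derived} min by > 120 min")

    return CourseSummary(phase=phase, label=label, nihss_max=nihss_max,
                         nds_max=nds_max, plateau_min=int(min(plateau, 1440)),
                         warnings=tuple(warnings))


def _series_plateau(points: Sequence[tuple[int, int, Optional[int]]],
                    steps: Sequence[str]) -> Optional[int]:
    """Time from reaching the maximal NIHSS to the first subsequent
    regression step; the (capped) last observation time when the deficit
    never regresses."""
    if not points:
        return None
    nihss_max = max(p[1] for p in points)
    t_max = next(t for t, tot, _ in points if tot == nihss_max)
    # steps[i] spans points[i] -> points[i+1]
    for i, label in enumerate(steps):
        t_end = points[i + 1][0]
        if label == "regression" and t_end > t_max:
            return t_end - t_max
    return min(points[-1][0], 1440)


def plateau_duration(patient: PatientRecord) -> int:
    """Plateau duration in minutes.

    The anamnesis value takes precedence; otherwise the duration is
    derived from the serial scores (time at maximal NIHSS until the
    first regression step, or the capped last observation time when the
    deficit never regresses within the first day).
    """
    if patient.plateau_anamnesis_min is not None:
        return int(patient.plateau_anamnesis_min)
    points = _first_day_points(patient)
    if len(points) >= 2:
        derived = _series_plateau(points, _step_labels(points))
        if derived is not None:
            return int(derived)
    raise MissingPlateauError(
        f"patient {patient.id}: no anamnesis and no usable serial scores")
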