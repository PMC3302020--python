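"""Synthetic derivation / validation cohorts and a screening registry.

No patient-level data from the source study are available, so every
downstream stage is exercised on simulated cohorts that reproduce the
published *marginal* structure:

* discharge mRS drawn from the published discharge distribution
  (73 / 27 / 10 / 15 / 12 / 17 over mRS 0-1 / 2 / 3 / 4 / 5 / death,
  n = 154);
* given the outcome group (mRS 0-3, mRS 4-5, death), the initial NDS
  total (NDS-0), the prehospital NIHSS total (NIHSS-GP) and the plateau
  duration are drawn from truncated normals whose *truncated* mean is
  moment-matched to the published group mean; the spread targets the SD
  back-solved from the printed 95% CI and group size;
* the first-24-hour course type is drawn from the published mixture
  (stable 62, total regression 36, partial regression 36, fluctuating
  10, progressive 10 of 154) and realised as a serial NIHSS trajectory
  whose steps satisfy the +/-4-point change rule the course classifier
  uses;
* NIHSS-GP items are masked "unknown" at the published per-item rates
  (dysarthria 21/154, neglect 11/154, visual loss 9/154, ataxia 8/154).

Outcome group, course type and ischaemia category are treated as
independent marginals (their joint distribution is not published);
course labels are randomly assigned among patients whose drawn severity
makes the label realisable under the step rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort_model import (
    CATEGORIES,
    DEATH,
    NDS_ITEMS,
    NIHSS_ITEMS,
    NDSAssessment,
    NIHSSAssessment,
    PatientRecord,
)

__all__ = [
    "GroupParams",
    "GeneratorConfig",
    "GenerationError",
    "generate_cohort",
    "generate_registry",
    "published_screening_registry",
    "PUBLISHED_EXCLUSION_COUNTS",
    "matched_truncnorm",
]

COURSE_TYPES = ("stable", "total_regression", "partial_regression",
                "fluctuating", "progressive")

#: Screening-registry exclusion counts from the published selection cascade
#: (361 screened -> 206 admitted ischaemic within 24 h -> 154 eligible).
PUBLISHED_EXCLUSION_COUNTS: dict[str, int] = {
    "no_GP": 98,
    "haematoma": 27,
    "venous_thrombosis": 4,
    "late_admission": 24,
    "thrombolysis": 2,
    "imprecise_course": 32,
    "insufficient_GP_data": 18,
    "mimic_doubt": 2,
    "prior_dependent": 0,
}


class GenerationError(RuntimeError):
    """Raised when a drawn configuration cannot be realised."""


def _ci_sd(lo: float, hi: float, n: int) -> float:
    """SD back-solved from a printed 95% CI half-width and group size."""
    return (hi - lo) / 2.0 / 1.959964 * math.sqrt(n)


@dataclass(frozen=True)
class GroupParams:
    """Per outcome-group (mean, sd) targets for the three continuous draws."""

    nds0: tuple[float, float]
    nihss_gp: tuple[float, float]
    plateau: tuple[float, float]


def _default_group_params() -> dict[str, GroupParams]:
    # Published group means with SDs back-solved from the 95% CIs:
    #   mRS 0-3 (n=110): NDS-0 8.0 (6.8-9.2), NIHSS-GP 5.5 (4.3-6.6),
    #                    plateau 399.1 (296.6-501.6)
    #   mRS 4-5 (n=27):  19.3 (14.2-24.4), 17.0 (12.8-21.2),
    #                    931.5 (684.7-1178.2)
    #   death  (n=17):   31.5 (28.2-34.8), 24.1 (20.9-27.3),
    #                    1320 (1129.8-1510.2)
    return {
        "mrs_0_3": GroupParams(
            nds0=(8.0, _ci_sd(6.8, 9.2, 110)),
            nihss_gp=(5.5, _ci_sd(4.3, 6.6, 110)),
            plateau=(399.1, _ci_sd(296.6, 501.6, 110)),
        ),
        "mrs_4_5": GroupParams(
            nds0=(19.3, _ci_sd(14.2, 24.4, 27)),
            nihss_gp=(17.0, _ci_sd(12.8, 21.2, 27)),
            plateau=(931.5, _ci_sd(684.7, 1178.2, 27)),
        ),
        "death": GroupParams(
            nds0=(31.5, _ci_sd(28.2, 34.8, 17)),
            nihss_gp=(24.1, _ci_sd(20.9, 27.3, 17)),
            plateau=(1320.0, _ci_sd(1129.8, 1510.2, 17)),
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the cohort generator needs; defaults are the published
    cohort-level distributions (n = 154 derivation cohort)."""

    n_patients: int = 154
    seed: int = 0
    #: probabilities over mRS levels 0..5 and death (level 6); the published
    #: table bins mRS 0-1 together (73/154), split evenly here.
    outcome_mixture: Mapping[int, float] = field(default_factory=lambda: {
        0: 36.5 / 154, 1: 36.5 / 154, 2: 27 / 154, 3: 10 / 154,
        4: 15 / 154, 5: 12 / 154, DEATH: 17 / 154,
    })
    group_params: Mapping[str, GroupParams] = field(
        default_factory=_default_group_params)
    course_mixture: Mapping[str, float] = field(default_factory=lambda: {
        "stable": 62 / 154, "total_regression": 36 / 154,
        "partial_regression": 36 / 154, "fluctuating": 10 / 154,
        "progressive": 10 / 154,
    })
    #: per-item probability that the GP could not assess the NIHSS item.
    missingness: Mapping[str, float] = field(default_factory=lambda: {
        "dysarthria": 21 / 154, "neglect": 11 / 154,
        "visual": 9 / 154, "ataxia": 8 / 154,
    })
    category_mixture: Mapping[str, float] = field(default_factory=lambda: {
        "lesion_free_TIA": 28 / 154, "TIA_with_lesion": 8 / 154,
        "infarction": 118 / 154,
    })
    onset_type_mixture: Mapping[str, float] = field(default_factory=lambda: {
        "sudden": 116 / 154, "progressive": 14 / 154, "unknown": 24 / 154,
    })
    #: NDS-1 is generated as slope * NIHSS-1 + noise so that the two
    #: admission instruments cohere (the study reports r^2 ~ 0.87).
    nds_coherence_slope: float = 33 / 42
    nds_coherence_noise_sd: float = 2.5

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise GenerationError("n_patients must be >= 0")
        for name, mix in (("outcome_mixture", self.outcome_mixture),
                          ("course_mixture", self.course_mixture),
                          ("category_mixture", self.category_mixture),
                          ("onset_type_mixture", self.onset_type_mixture)):
            total = float(sum(mix.values()))
            if abs(total - 1.0) > 1e-9:
                raise GenerationError(f"{name} sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise GenerationError(f"{name} has negative probabilities")
        for g, gp in self.group_params.items():
            for attr in ("nds0", "nihss_gp", "plateau"):
                if getattr(gp, attr)[1] <= 0:
                    raise GenerationError(f"group {g}: {attr} sd must be > 0")
        bad = set(self.missingness) - set(NIHSS_ITEMS)
        if bad:
            raise GenerationError(f"missingness names unknown items: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Truncated-normal moment matching
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def matched_truncnorm(target_mean: float, target_sd: float,
                      lo: float, hi: float):
    """Truncated normal on [lo, hi] whose truncated mean equals
    ``target_mean`` exactly, with truncated SD as close to ``target_sd``
    as the family allows.

    The parent mean is found by a monotone 1-D root solve for each
    candidate scale; the scale is then chosen by bounded minimisation of
    the squared SD error.  Near a bound of the support the requested SD
    can exceed what any truncated normal with that mean can attain; the
    mean match is exact regardless.
    """
    if not lo < target_mean < hi:
        raise GenerationError(
            f"target mean {target_mean} outside support ({lo}, {hi})")

    def frozen(mu: float, sigma: float):
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        return stats.truncnorm(a, b, loc=mu, scale=sigma)

    def trunc_mean(mu: float, sigma: float) -> float:
        m = frozen(mu, sigma).mean()
        if not math.isfinite(m):  # parent pushed deep into a tail
            return lo if mu < (lo + hi) / 2 else hi
        return float(m)

    def mu_for(sigma: float) -> float:
        f = lambda mu: trunc_mean(mu, sigma) - target_mean
        lo_mu, hi_mu = lo - sigma, hi + sigma
        for _ in range(60):  # expand until the bracket straddles the root
            if f(lo_mu) < 0 < f(hi_mu):
                break
            if f(lo_mu) >= 0:
                lo_mu -= 2 * sigma
            if f(hi_mu) <= 0:
                hi_mu += 2 * sigma
        return optimize.brentq(f, lo_mu, hi_mu,
                               xtol=1e-10 * max(1.0, abs(target_mean)))

    def sd_err(log_sigma: float) -> float:
        sigma = math.exp(log_sigma)
        return (frozen(mu_for(sigma), sigma).std() - target_sd) ** 2

    res = optimize.minimize_scalar(
        sd_err, bounds=(math.log(target_sd / 20), math.log(target_sd * 20)),
        method="bounded", options={"xatol": 1e-6})
    sigma = math.exp(res.x)
    return frozen(mu_for(sigma), sigma)


# ---------------------------------------------------------------------------
# Item allocation
# ---------------------------------------------------------------------------

def allocate_items(total: int, template: Mapping[str, int],
                   rng: np.random.Generator) -> dict[str, int]:
    """Distribute an integer total over items by greedy round-robin,
    respecting per-item maxima; the visiting order is randomised so that
    low totals do not always land on the same items."""
    maxima = dict(template)
    if total < 0 or total > sum(maxima.values()):
        raise GenerationError(
            f"total {total} cannot be allocated over items (max {sum(maxima.values())})")
    names = list(maxima)
    order = [names[i] for i in rng.permutation(len(names))]
    items = {name: 0 for name in names}
    remaining = int(total)
    while remaining > 0:
        progressed = False
        for name in order:
            if remaining == 0:
                break
            if items[name] < maxima[name]:
                items[name] += 1
                remaining -= 1
                progressed = True
        if not progressed:  # pragma: no cover - guarded by the range check
            raise GenerationError("allocation stalled")
    return items


# ---------------------------------------------------------------------------
# Course planning
# ---------------------------------------------------------------------------

# Minimum / maximum NIHSS-GP total for which a course label is realisable
# under the +/-4-point step rule on the in-hospital series.
_COURSE_BOUNDS: dict[str, tuple[int, int]] = {
    "stable": (0, 42),
    "total_regression": (4, 42),
    "partial_regression": (5, 42),
    "fluctuating": (0, 38),
    "progressive": (0, 34),
}


def _assign_courses(totals: np.ndarray, labels: list[str],
                    rng: np.random.Generator) -> list[str]:
    """Randomly assign the drawn course labels to patients whose NIHSS-GP
    total makes each label realisable; both marginals are preserved."""
    n = len(totals)
    assigned: list[Optional[str]] = [None] * n
    unassigned = np.ones(n, dtype=bool)
    counts = {c: labels.count(c) for c in COURSE_TYPES}
    # Tightest constraints first; 'stable' (unconstrained) takes the rest.
    for course in ("partial_regression", "total_regression",
                   "progressive", "fluctuating", "stable"):
        k = counts.get(course, 0)
        if k == 0:
            continue
        lo, hi = _COURSE_BOUNDS[course]
        eligible = np.flatnonzero(unassigned & (totals >= lo) & (totals <= hi))
        if len(eligible) < k:
            raise GenerationError(
                f"cannot place {k} '{course}' courses: only {len(eligible)} "
                f"patients with NIHSS-GP in [{lo}, {hi}] remain")
        chosen = rng.choice(eligible, size=k, replace=False)
        for i in chosen:
            assigned[i] = course
            unassigned[i] = False
    return [a if a is not None else "stable" for a in assigned]


def _plan_series(course: str, t_gp: int, rng: np.random.Generator) -> list[int]:
    """Latent NIHSS totals at [gp, admission, h8, h16, h24] realising the
    course label: stable steps jitter by at most 1 point; course-defining
    steps move by >= 4 points."""
    def clip(v: int, lo: int = 0, hi: int = 42) -> int:
        return max(lo, min(hi, v))

    j = lambda: int(rng.integers(-1, 2))
    if course == "stable":
        base = t_gp
        out = [t_gp]
        for _ in range(4):
            out.append(clip(base + j()))
        return out
    if course == "total_regression":
        a0 = clip(max(t_gp + j(), 4))
        k = int(rng.integers(2, 5))  # drop at h8, h16 or h24
        out = [t_gp, a0]
        level = a0
        for idx in (2, 3, 4):
            if idx < k:
                level = clip(max(level + j(), 4))
                out.append(level)
            else:
                out.append(0)
        return out
    if course == "partial_regression":
        a0 = clip(max(t_gp + j(), 5))
        k = int(rng.integers(2, 5))  # index of the regression step
        out = [t_gp, a0]
        level = a0
        for idx in range(2, k):
            level = clip(max(level + j(), 5))
            out.append(level)
        drop = int(rng.integers(4, level))  # residual level-drop in [1, level-4]
        final = level - drop
        out.append(final)
        for idx in range(k + 1, 5):
            out.append(max(1, clip(final + j())))
        return out
    if course == "fluctuating":
        a0 = min(clip(t_gp + j()), 38)
        return [t_gp, a0, clip(a0 + 4), a0, clip(a0 + 4)]
    if course == "progressive":
        a0 = min(clip(t_gp + j()), 34)
        top = clip(a0 + 8)
        return [t_gp, a0, clip(a0 + 4), top, clip(top + int(rng.integers(0, 2)))]
    raise GenerationError(f"unknown course type {course!r}")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _outcome_group(mrs: int) -> str:
    if mrs <= 3:
        return "mrs_0_3"
    if mrs <= 5:
        return "mrs_4_5"
    return "death"


def _draw_admission_delay(rng: np.random.Generator, n: int) -> np.ndarray:
    # Onset-to-admission mixture: 29.4% < 3 h, 57.5% < 6 h, all < 24 h.
    seg = rng.choice(3, size=n, p=[0.294, 0.281, 0.425])
    lo = np.array([130, 180, 360])[seg]
    hi = np.array([180, 360, 1440])[seg]
    return np.floor(rng.uniform(lo, hi)).astype(int)


def generate_cohort(config: GeneratorConfig) -> list[PatientRecord]:
    """Draw a cohort of :class:`PatientRecord` with the configured
    outcome, severity, plateau, course and missingness structure.

    Same config (including seed) gives a field-for-field identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return []

    mrs_levels = np.array(sorted(config.outcome_mixture))
    mrs_p = np.array([config.outcome_mixture[k] for k in mrs_levels], dtype=float)
    mrs = rng.choice(mrs_levels, size=n, p=mrs_p / mrs_p.sum())

    groups = [_outcome_group(int(m)) for m in mrs]
    nds0_tot = np.empty(n, dtype=int)
    nihss_gp_tot = np.empty(n, dtype=int)
    plateau = np.empty(n, dtype=int)
    for g in sorted(set(groups)):  # fixed order keeps draws seed-reproducible
        idx = np.array([i for i, gi in enumerate(groups) if gi == g])
        gp = config.group_params[g]
        dist_nds = matched_truncnorm(gp.nds0[0], gp.nds0[1], 0.0, 33.0)
        dist_nih = matched_truncnorm(gp.nihss_gp[0], gp.nihss_gp[1], 0.0, 42.0)
        dist_pla = matched_truncnorm(gp.plateau[0], gp.plateau[1], 1.0, 1440.0)
        nds0_tot[idx] = np.rint(dist_nds.rvs(len(idx), random_state=rng)).astype(int)
        nihss_gp_tot[idx] = np.rint(dist_nih.rvs(len(idx), random_state=rng)).astype(int)
        plateau[idx] = np.rint(dist_pla.rvs(len(idx), random_state=rng)).astype(int)

    course_names = list(COURSE_TYPES)
    course_p = np.array([config.course_mixture.get(c, 0.0) for c in course_names])
    drawn = list(rng.choice(course_names, size=n, p=course_p / course_p.sum()))
    courses = _assign_courses(nihss_gp_tot, drawn, rng)

    categories = rng.choice(
        list(config.category_mixture),
        size=n, p=np.array(list(config.category_mixture.values())) /
        sum(config.category_mixture.values()))
    onset_types = rng.choice(
        list(config.onset_type_mixture),
        size=n, p=np.array(list(config.onset_type_mixture.values())) /
        sum(config.onset_type_mixture.values()))

    gp_times = rng.integers(15, 121, size=n)
    adm_times = np.maximum(_draw_admission_delay(rng, n), gp_times + 10)

    miss_items = list(config.missingness)
    miss_p = np.array([config.missingness[i] for i in miss_items])

    records: list[PatientRecord] = []
    for i in range(n):
        totals = _plan_series(courses[i], int(nihss_gp_tot[i]), rng)
        t_adm = int(adm_times[i])
        times = [int(gp_times[i]), t_adm, t_adm + 480, t_adm + 960, t_adm + 1440]
        sources = ("gp", "admission", "h8", "h16", "h24")
        nihss_series = []
        for src, ts, tot in zip(sources, times, totals):
            items = allocate_items(tot, NIHSS_ITEMS, rng)
            if src == "gp":
                mask = rng.random(len(miss_items)) < miss_p
                for name, m in zip(miss_items, mask):
                    if m:
                        items[name] = None
            nihss_series.append(NIHSSAssessment(timestamp=ts, items=items, source=src))
        # discharge NIHSS loosely follows the final 24 h total and outcome
        final24 = totals[-1]
        if mrs[i] == DEATH:
            tot_dis = min(42, final24 + int(rng.integers(0, 3)))
        else:
            tot_dis = max(0, min(42, final24 - int(rng.integers(0, 3))))
        nihss_series.append(NIHSSAssessment(
            timestamp=times[-1] + 2880,
            items=allocate_items(tot_dis, NIHSS_ITEMS, rng), source="discharge"))

        nihss1_tot = totals[1]
        nds1_tot = int(np.clip(round(
            config.nds_coherence_slope * nihss1_tot +
            rng.normal(0, config.nds_coherence_noise_sd)), 0, 33))
        nds_series = [
            NDSAssessment(timestamp=max(1, int(gp_times[i]) - 10),
                          items=allocate_items(int(nds0_tot[i]), NDS_ITEMS, rng)),
            NDSAssessment(timestamp=t_adm,
                          items=allocate_items(nds1_tot, NDS_ITEMS, rng)),
        ]
        records.append(PatientRecord(
            id=f"P{i:05d}",
            onset_type=str(onset_types[i]),
            onset_time=0,
            admission_time=t_adm,
            nds_series=nds_series,
            nihss_series=nihss_series,
            plateau_anamnesis_min=int(plateau[i]),
            category=str(categories[i]),
            mrs_discharge=int(mrs[i]),
        ))
    return records


# ---------------------------------------------------------------------------
# Screening registry
# ---------------------------------------------------------------------------

def generate_registry(n_eligible: int,
                      exclusion_counts: Mapping[str, int],
                      seed: int = 0) -> pd.DataFrame:
    """A screening-registry fixture: one row per screened patient with at
    most one ``exclusion_reason`` flag; marginal counts equal the request.
    """
    if n_eligible < 0 or any(c < 0 for c in exclusion_counts.values()):
        raise GenerationError("counts must be non-negative")
    reasons: list[str] = [""] * n_eligible
    for reason, count in exclusion_counts.items():
        reasons.extend([reason] * int(count))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reasons))
    return pd.DataFrame({
        "id": [f"S{k:05d}" for k in range(len(reasons))],
        "exclusion_reason": [reasons[i] for i in order],
    })


def published_screening_registry(seed: int = 0) -> pd.DataFrame:
    """The 361-patient registry fixture with the published exclusion
    category counts (154 eligible)."""
    return generate_registry(154, PUBLISHED_EXCLUSION_COUNTS, seed=seed)
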