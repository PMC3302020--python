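"""Patient-selection cascade over a screening registry.

The screening registry holds one row per screened patient with at most
one exclusion flag.  Exclusions are applied in two stages, in listing
order with first-match-wins attribution so every record is counted
exactly once:

stage 1 (screened -> ischaemic admissions within 24 h):
    no_GP, haematoma, venous_thrombosis, late_admission, thrombolysis
stage 2 (ischaemic admissions -> eligible):
    imprecise_course, insufficient_GP_data, mimic_doubt
plus the prior-dependent criterion (previous stroke with mRS >= 3),
carried as its own flag.

The audit object reconciles exactly: input size minus all exclusion
counts equals the eligible count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .cohort_model import CohortValidationError

__all__ = [
    "STAGE1_REASONS",
    "STAGE2_REASONS",
    "PRIOR_DEPENDENT",
    "ExclusionAudit",
    "apply_exclusion_cascade",
]

STAGE1_REASONS = ("no_GP", "haematoma", "venous_thrombosis",
                  "late_admission", "thrombolysis")
STAGE2_REASONS = ("imprecise_course", "insufficient_GP_data", "mimic_doubt")
PRIOR_DEPENDENT = "prior_dependent"

_ALL_REASONS = frozenset(STAGE1_REASONS) | frozenset(STAGE2_REASONS) | {PRIOR_DEPENDENT}


@dataclass(frozen=True)
class ExclusionAudit:
    """Reconciled counts of the selection cascade."""

    stage1_counts: Mapping[str, int]
    stage2_counts: Mapping[str, int]
    prior_dependent_count: int
    n_input: int
    n_after_stage1: int
    n_eligible: int

    def __post_init__(self) -> None:
        counts = list(self.stage1_counts.values()) + \
            list(self.stage2_counts.values()) + \
            [self.prior_dependent_count, self.n_input,
             self.n_after_stage1, self.n_eligible]
        if any(c < 0 for c in counts):
            raise CohortValidationError("audit counts must be non-negative")
        if self.n_input - sum(self.stage1_counts.values()) != self.n_after_stage1:
            raise CohortValidationError("stage-1 counts do not reconcile")
        if (self.n_after_stage1 - sum(self.stage2_counts.values())
                - self.prior_dependent_count != self.n_eligible):
            raise CohortValidationError("stage-2 counts do not reconcile")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "stage1_counts": dict(self.stage1_counts),
            "n_after_stage1": self.n_after_stage1,
            "stage2_counts": dict(self.stage2_counts),
            "prior_dependent_count": self.prior_dependent_count,
            "n_eligible": self.n_eligible,
        }


def apply_exclusion_cascade(registry: pd.DataFrame
                            ) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Apply the ordered exclusion filters to a screening registry.

    Parameters
    ----------
    registry
        DataFrame with an ``exclusion_reason`` column; the empty string
        (or missing value) marks a record with no exclusion flag.

    Returns
    -------
    (eligible, audit)
        The eligible rows (in input order) and the reconciled
        :class:`ExclusionAudit`.
    """
    if "exclusion_reason" not in registry.columns:
        raise CohortValidationError("registry lacks an 'exclusion_reason' column")
    reasons = registry["exclusion_reason"].fillna("").astype(str)
    unknown = set(reasons.unique()) - _ALL_REASONS - {""}
    if unknown:
        raise CohortValidationError(f"unknown exclusion codes: {sorted(unknown)}")

    n_input = len(registry)
    stage1 = {r: int((reasons == r).sum()) for r in STAGE1_REASONS}
    n_after_stage1 = n_input - sum(stage1.values())
    stage2 = {r: int((reasons == r).sum()) for r in STAGE2_REASONS}
    prior = int((reasons == PRIOR_DEPENDENT).sum())
    eligible = registry.loc[reasons == ""].copy()
    audit = ExclusionAudit(
        stage1_counts=stage1,
        stage2_counts=stage2,
        prior_dependent_count=prior,
        n_input=n_input,
        n_after_stage1=n_after_stage1,
        n_eligible=len(eligible),
    )
    return eligible, audit
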