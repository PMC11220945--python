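"""Outcome derivation and the consort-style inclusion filter.

Neurological outcome is graded on the cerebral performance category (CPC)
scale, 1 (good recovery) to 5 (brain death), assessed at day 30 and day
180 after arrest.  The *best* (numerically lowest) CPC over the two
assessments is used, so a patient who recovers and later dies of an
unrelated cause keeps the recovered grade.  CPC 1–2 is a favourable
outcome (FO), CPC 3–5 unfavourable (UO).

The consort filter reduces an admission cohort to the validation cohort in
three stages: admission-stage exclusions (recorded reason), pre-MRI
dropouts (regained consciousness before MRI, or prognosticated without
MRI), and other intracranial pathology found on MRI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingOutcomeError, ValidationError

__all__ = [
    "EXCLUSION_REASONS",
    "OutcomeClass",
    "best_cpc",
    "dichotomize_outcome",
    "derive_outcomes",
    "consort_filter",
]

EXCLUSION_REASONS = (
    "regained_consciousness_24h",
    "circulatory_failure_death",
    "brain_death",
    "no_consent",
    "advanced_directives",
)


@dataclass(frozen=True)
class OutcomeClass:
    best_cpc: int
    favourable: bool

    def __post_init__(self) -> None:
        if self.favourable != (self.best_cpc <= 2):
            raise ValidationError("favourable flag inconsistent with best CPC")

    @property
    def label(self) -> str:
        return "FO" if self.favourable else "UO"


def _is_missing(value) -> bool:
    return value is None or value is pd.NA or (
        isinstance(value, float) and np.isnan(value)
    )


def _check_cpc(value: int) -> int:
    value = int(value)
    if not 1 <= value <= 5:
        raise ValidationError(f"CPC must be in 1..5, got {value}")
    return value


def best_cpc(cpc_d30, cpc_d180) -> int:
    """Best (numerically lowest) CPC over the day-30 and day-180 assessments.

    A single missing assessment is tolerated; both missing raises
    MissingOutcomeError.
    """
    present = [_check_cpc(v) for v in (cpc_d30, cpc_d180) if not _is_missing(v)]
    if not present:
        raise MissingOutcomeError("no CPC assessment available")
    return min(present)


def dichotomize_outcome(best: int) -> OutcomeClass:
    """Favourable iff best CPC ≤ 2 (CPC 1–2 = FO, CPC 3–5 = UO)."""
    best = _check_cpc(best)
    return OutcomeClass(best_cpc=best, favourable=best <= 2)


def derive_outcomes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append ``best_cpc`` and ``favourable`` columns to a patient table.

    Raises MissingOutcomeError naming the first subject with no CPC at all.
    """
    out = cohort.copy()
    bests = []
    for row in out.itertuples():
        try:
            bests.append(best_cpc(row.cpc_d30, row.cpc_d180))
        except MissingOutcomeError as err:
            raise MissingOutcomeError(
                f"subject {row.subject_id}: {err}"
            ) from None
    out["best_cpc"] = pd.array(bests, dtype="Int64")
    out["favourable"] = out["best_cpc"] <= 2
    return out


def consort_filter(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the three-stage inclusion filter and summarise the flow.

    Stage 1 removes records with an admission-stage ``exclusion_reason``;
    stage 2 removes pre-MRI dropouts (``regained_consciousness_before_mri``
    or ``prognosticated_without_mri``); stage 3 removes records flagged
    ``other_pathology``.  Each record is counted under exactly one reason,
    in that order.  Returns the surviving validation table and a flow
    summary with one entry per stage (stage, removed, remaining, reasons).
    """
    df = cohort
    stages = []

    excluded = df["exclusion_reason"].notna()
    reasons = (
        df.loc[excluded, "exclusion_reason"].value_counts().to_dict()
        if excluded.any()
        else {}
    )
    df = df[~excluded]
    stages.append(
        {
            "stage": "admission_exclusion",
            "removed": int(excluded.sum()),
            "remaining": int(len(df)),
            "reasons": {str(k): int(v) for k, v in reasons.items()},
        }
    )

    regained = df["regained_consciousness_before_mri"].astype(bool)
    no_mri = df["prognosticated_without_mri"].astype(bool) & ~regained
    stages.append(
        {
            "stage": "pre_mri_dropout",
            "removed": int((regained | no_mri).sum()),
            "remaining": int(len(df) - (regained | no_mri).sum()),
            "reasons": {
                "regained_consciousness_before_mri": int(regained.sum()),
                "prognosticated_without_mri": int(no_mri.sum()),
            },
        }
    )
    df = df[~(regained | no_mri)]

    other = df["other_pathology"].astype(bool)
    stages.append(
        {
            "stage": "other_pathology",
            "removed": int(other.sum()),
            "remaining": int(len(df) - other.sum()),
            "reasons": {"other_pathology": int(other.sum())},
        }
    )
    df = df[~other]

    summary = {
        "admitted": int(len(cohort)),
        "validated": int(len(df)),
        "stages": stages,
    }
    return df.reset_index(drop=True), summary
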