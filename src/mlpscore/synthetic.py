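"""Synthetic ADC volumes and cohorts with known ground truth.

Two generators make every downstream stage testable without patient data:

* ``simulate_adc_volume`` paints a toy atlas with Gaussian ADC values —
  normal grey matter around 800 × 10⁻⁶ mm²/s, cytotoxic-oedema lesions
  around 450 — so the 650 restriction threshold separates them with a wide
  margin and the intended lesion topography is recoverable by the scorer.

* ``simulate_cohort`` / ``consort_fixture`` emit patient tables whose joint
  lesion-pattern × outcome distribution reproduces the published validation
  cohort (47 patients) and its consort flow (137 admitted, 85 excluded at
  admission, then 3 + 1 pre-MRI dropouts and 1 other-pathology exclusion).

All randomness derives from one integer seed via named sub-streams, so a
fixed seed reproduces every artefact bit-for-bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .atlas import (
    CORTICAL_CLASSES,
    DEEP_CLASSES,
    RegionClass,
    ToyBrainAtlas,
)
from .errors import UnknownRoiError, ValidationError

__all__ = [
    "AdcVolume",
    "LesionSpec",
    "CohortSpec",
    "VALIDATION_COHORT_COUNTS",
    "ADMISSION_EXCLUSION_COUNTS",
    "simulate_adc_volume",
    "simulate_cohort",
    "consort_fixture",
    "lesion_targets_for_mlp",
]

COHORT_COLUMNS = [
    "subject_id",
    "exclusion_reason",
    "regained_consciousness_before_mri",
    "prognosticated_without_mri",
    "other_pathology",
    "mlp",
    "cpc_d30",
    "cpc_d180",
]

#: Joint lesion-pattern × outcome counts of the published validation cohort
#: (47 patients): rows UO (CPC 3–5) / FO (CPC 1–2), keyed by MLP 1..4.
VALIDATION_COHORT_COUNTS: dict[str, dict[int, int]] = {
    "UO": {1: 2, 2: 0, 3: 4, 4: 29},
    "FO": {1: 8, 2: 2, 3: 0, 4: 2},
}

#: Admission-stage exclusions of the consort flow, by reason.
ADMISSION_EXCLUSION_COUNTS: dict[str, int] = {
    "regained_consciousness_24h": 44,
    "circulatory_failure_death": 19,
    "brain_death": 11,
    "no_consent": 7,
    "advanced_directives": 4,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named sub-stream of the global seed (independent per operation)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())])
    )


@dataclass
class AdcVolume:
    """A 3-D ADC map in units of 10⁻⁶ mm²/s with voxel geometry."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.data).all() or (self.data <= 0).any():
            raise ValidationError("ADC values must be finite and positive")


@dataclass(frozen=True)
class LesionSpec:
    """Which ROIs carry a lesion, and the ADC levels of lesion/background.

    Defaults put lesions at 450 ± 25 and normal tissue at 800 ± 25
    (× 10⁻⁶ mm²/s), straddling the 650 restriction threshold by 8 lesion
    standard deviations on either side.
    """

    target_rois: frozenset[str] = frozenset()
    lesion_mean: float = 450.0
    lesion_sd: float = 25.0
    background_mean: float = 800.0
    background_sd: float = 25.0

    def __post_init__(self) -> None:
        if self.lesion_sd < 0 or self.background_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if not (self.lesion_mean < 650.0 < self.background_mean):
            raise ValidationError(
                "ground truth requires lesion_mean < 650 < background_mean"
            )
        object.__setattr__(self, "target_rois", frozenset(self.target_rois))


def simulate_adc_volume(
    atlas: ToyBrainAtlas,
    lesion: LesionSpec,
    seed: int,
    subject_id: str = "sim",
) -> tuple[AdcVolume, frozenset[str]]:
    """Simulate an ADC volume on the atlas grid.

    Voxels inside the target ROIs are drawn from N(lesion_mean, lesion_sd²),
    every other voxel from N(background_mean, background_sd²).  Returns the
    volume together with the ground-truth set of lesioned roi_ids.

    Raises UnknownRoiError if a target roi_id is absent from the atlas.
    """
    known = set(atlas.roi_ids())
    unknown = set(lesion.target_rois) - known
    if unknown:
        raise UnknownRoiError(f"unknown target ROIs: {sorted(unknown)}")

    rng = _rng(seed, "adc_volume")
    data = rng.normal(lesion.background_mean, lesion.background_sd,
                      size=atlas.label_volume.shape)
    for roi_id in sorted(lesion.target_rois):
        mask = atlas.mask_for(roi_id)
        data[mask] = rng.normal(lesion.lesion_mean, lesion.lesion_sd,
                                size=int(mask.sum()))
    np.maximum(data, 1e-3, out=data)  # ADC is physically positive
    volume = AdcVolume(data, atlas.voxel_size_mm, subject_id)
    return volume, frozenset(lesion.target_rois)


def lesion_targets_for_mlp(
    mlp: int, atlas: ToyBrainAtlas, rng: np.random.Generator
) -> frozenset[str]:
    """Draw a random ROI set whose topography realises the requested MLP.

    MLP 1: empty; MLP 2: ≥1 cortical ROI only; MLP 3: ≥1 basal-ganglia ROI
    plus optional cortex; MLP 4: ≥1 deep ROI (thalamus/hippocampus/
    brainstem) plus optionally anything else.
    """
    if mlp not in (1, 2, 3, 4):
        raise ValidationError(f"MLP must be 1..4, got {mlp}")
    by_class: dict[RegionClass, list[str]] = {}
    for spec in atlas.roi_table:
        by_class.setdefault(spec.region_class, []).append(spec.roi_id)
    cortical = sorted(r for c in CORTICAL_CLASSES for r in by_class.get(c, []))
    basal = sorted(by_class.get(RegionClass.BASAL_GANGLIA, []))
    deep = sorted(r for c in DEEP_CLASSES for r in by_class.get(c, []))

    def some(pool: list[str], at_least_one: bool) -> set[str]:
        k_min = 1 if at_least_one else 0
        k = int(rng.integers(k_min, len(pool) + 1))
        return set(rng.choice(pool, size=k, replace=False)) if k else set()

    if mlp == 1:
        return frozenset()
    if mlp == 2:
        return frozenset(some(cortical, True))
    if mlp == 3:
        return frozenset(some(basal, True) | some(cortical, False))
    return frozenset(some(deep, True) | some(basal, False) | some(cortical, False))


@dataclass(frozen=True)
class CohortSpec:
    """Target joint outcome × MLP distribution for a simulated cohort."""

    joint_counts: Mapping[str, Mapping[int, int]] = field(
        default_factory=lambda: VALIDATION_COHORT_COUNTS
    )
    mode: str = "exact_counts"
    n: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.joint_counts) != {"UO", "FO"}:
            raise ValidationError("joint_counts must have rows 'UO' and 'FO'")
        for row in self.joint_counts.values():
            if set(row) != {1, 2, 3, 4}:
                raise ValidationError("joint_counts columns must be MLP 1..4")
            if any(v < 0 for v in row.values()):
                raise ValidationError("joint counts must be non-negative")
        if self.mode not in ("exact_counts", "multinomial"):
            raise ValidationError(f"unknown cohort mode {self.mode!r}")
        if self.mode == "multinomial" and (self.n is None or self.n <= 0):
            raise ValidationError("multinomial mode requires n > 0")


def _cpc_pair(outcome: str, rng: np.random.Generator) -> tuple[int, int]:
    """Draw (cpc_d30, cpc_d180) whose minimum realises the outcome class.

    UO means best CPC in {3,4,5}; FO best CPC in {1,2}.  The best value is
    uniform on its class; the other assessment never improves on it.
    """
    best = int(rng.choice([3, 4, 5] if outcome == "UO" else [1, 2]))
    other = int(rng.integers(best, 6))
    if rng.random() < 0.5:
        return best, other
    return other, best


def _blank_record(subject_id: str) -> dict:
    return {
        "subject_id": subject_id,
        "exclusion_reason": pd.NA,
        "regained_consciousness_before_mri": False,
        "prognosticated_without_mri": False,
        "other_pathology": False,
        "mlp": pd.NA,
        "cpc_d30": pd.NA,
        "cpc_d180": pd.NA,
    }


def _as_cohort_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    for col in ("mlp", "cpc_d30", "cpc_d180"):
        df[col] = df[col].astype("Int64")
    for col in ("regained_consciousness_before_mri", "prognosticated_without_mri",
                "other_pathology"):
        df[col] = df[col].astype(bool)
    return df


def simulate_cohort(spec: CohortSpec, id_prefix: str = "sub") -> pd.DataFrame:
    """Emit a patient table with the requested MLP × outcome structure.

    ``exact_counts`` mode reproduces the joint counts cell by cell;
    ``multinomial`` mode draws ``n`` patients from the normalised cell
    probabilities.  CPC values are sampled consistently with each record's
    outcome class.  Deterministic for a fixed spec seed.
    """
    rng = _rng(spec.seed, "cohort")
    cells = [(outcome, mlp) for outcome in ("UO", "FO") for mlp in (1, 2, 3, 4)]
    counts = {cell: int(spec.joint_counts[cell[0]][cell[1]]) for cell in cells}

    if spec.mode == "multinomial":
        total = sum(counts.values())
        if total == 0:
            raise ValidationError("multinomial mode needs a non-degenerate table")
        probs = np.array([counts[c] for c in cells], dtype=float) / total
        draw = rng.multinomial(spec.n, probs)
        counts = dict(zip(cells, (int(k) for k in draw)))

    rows = []
    idx = 1
    for outcome, mlp in cells:
        for _ in range(counts[(outcome, mlp)]):
            rec = _blank_record(f"{id_prefix}-{idx:03d}")
            rec["mlp"] = mlp
            rec["cpc_d30"], rec["cpc_d180"] = _cpc_pair(outcome, rng)
            rows.append(rec)
            idx += 1
    return _as_cohort_frame(rows)


def consort_fixture(seed: int = 0) -> pd.DataFrame:
    """Full 137-patient admission cohort mirroring the published flow.

    85 records carry an admission-stage exclusion reason (44 regained
    consciousness within 24 h, 19 circulatory-failure deaths, 11 brain
    deaths, 7 without consent, 4 with advanced directives).  Of the 52
    entering neuroprognostication, 3 regained consciousness before MRI,
    1 was prognosticated without MRI, 1 had another pathology (malignant
    middle-cerebral-artery infarction) and 47 carry an MLP and CPC values
    distributed per the validation-cohort table.
    """
    rng = _rng(seed, "consort")
    rows: list[dict] = []
    idx = 1
    for reason, count in ADMISSION_EXCLUSION_COUNTS.items():
        for _ in range(count):
            rec = _blank_record(f"sub-{idx:03d}")
            rec["exclusion_reason"] = reason
            rows.append(rec)
            idx += 1

    for _ in range(3):
        rec = _blank_record(f"sub-{idx:03d}")
        rec["regained_consciousness_before_mri"] = True
        rec["cpc_d30"], rec["cpc_d180"] = _cpc_pair("FO", rng)
        rows.append(rec)
        idx += 1

    rec = _blank_record(f"sub-{idx:03d}")  # UO called on EEG/NSE/exam, no MRI
    rec["prognosticated_without_mri"] = True
    rec["cpc_d30"], rec["cpc_d180"] = _cpc_pair("UO", rng)
    rows.append(rec)
    idx += 1

    rec = _blank_record(f"sub-{idx:03d}")  # MCA infarction on MRI
    rec["other_pathology"] = True
    rec["cpc_d30"], rec["cpc_d180"] = _cpc_pair("UO", rng)
    rows.append(rec)
    idx += 1

    head = _as_cohort_frame(rows)
    validated = simulate_cohort(
        CohortSpec(joint_counts=VALIDATION_COHORT_COUNTS, mode="exact_counts",
                   seed=seed)
    )
    validated = validated.copy()
    validated["subject_id"] = [f"sub-{idx + i:03d}" for i in range(len(validated))]
    return pd.concat([head, validated], ignore_index=True)
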