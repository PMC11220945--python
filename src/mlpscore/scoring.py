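"""ROI restriction calls and MR lesion-pattern (MLP) assignment.

Hypoxic-ischemic injury after cardiac arrest produces cytotoxic oedema that
lowers the apparent diffusion coefficient.  An ROI is called *restricted*
when its ADC summary statistic falls strictly below a threshold (default
650 × 10⁻⁶ mm²/s).  The topography of restricted ROIs then maps to a
four-level lesion-pattern score:

MLP 1  no grey-matter lesion
MLP 2  purely cortical lesions (cerebral or cerebellar cortex)
MLP 3  basal-ganglia lesions, no other deep grey matter (± cortex)
MLP 4  thalamic, hippocampal or brainstem lesions (± anything else)

MLP 3–4 constitutes "severe" hypoxic brain injury in the downstream
dichotomy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .atlas import (
    CORTICAL_CLASSES,
    DEEP_CLASSES,
    RegionClass,
    RoiSpec,
    ToyBrainAtlas,
    standard_roi_set,
)
from .errors import ConsistencyError, GeometryError, ValidationError
from .synthetic import AdcVolume

__all__ = [
    "DEFAULT_ADC_THRESHOLD",
    "RoiMeasurement",
    "MlpScore",
    "extract_roi_values",
    "call_restriction",
    "assign_mlp",
    "mlp_from_restricted_classes",
    "dichotomize_mlp",
]

#: ADC restriction threshold, 10⁻⁶ mm²/s; values strictly below are lesional.
DEFAULT_ADC_THRESHOLD = 650.0

MEASUREMENT_COLUMNS = ["subject_id", "roi_id", "adc_statistic", "restricted", "excluded"]


@dataclass(frozen=True)
class RoiMeasurement:
    """One ROI's ADC summary and its restriction/exclusion status."""

    roi_id: str
    adc_statistic: float
    restricted: bool = False
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.restricted and self.excluded:
            raise ValidationError(f"{self.roi_id}: restricted implies not excluded")
        if not np.isfinite(self.adc_statistic):
            raise ValidationError(f"{self.roi_id}: non-finite adc_statistic")


@dataclass(frozen=True)
class MlpScore:
    """MR lesion pattern 1–4 plus the severe (MLP 3–4) dichotomy."""

    value: int
    severe: bool

    def __post_init__(self) -> None:
        if self.value not in (1, 2, 3, 4):
            raise ValidationError(f"MLP value must be 1..4, got {self.value}")
        if self.severe != (self.value >= 3):
            raise ValidationError("severe flag inconsistent with MLP value")

    @classmethod
    def from_value(cls, value: int) -> "MlpScore":
        return cls(value=value, severe=value >= 3)


def extract_roi_values(
    volume: AdcVolume,
    atlas: ToyBrainAtlas,
    statistic: Literal["mean", "median"] = "mean",
    subject_id: str | None = None,
) -> pd.DataFrame:
    """Summarise the ADC value of every atlas ROI.

    Returns a measurement table (one row per ROI in atlas order) with the
    configured summary statistic over each ROI's voxels; ``restricted`` is
    left unset (NA) and ``excluded`` defaults to False.

    Raises GeometryError on shape or voxel-size mismatch and
    ConsistencyError if an ROI has no voxels in the label volume.
    """
    if volume.data.shape != atlas.label_volume.shape:
        raise GeometryError(
            f"volume shape {volume.data.shape} != atlas shape "
            f"{atlas.label_volume.shape}"
        )
    if tuple(volume.voxel_size_mm) != tuple(atlas.voxel_size_mm):
        raise GeometryError("volume and atlas voxel sizes differ")
    if statistic not in ("mean", "median"):
        raise ValidationError(f"unknown statistic {statistic!r}")

    reduce = np.mean if statistic == "mean" else np.median
    sid = subject_id if subject_id is not None else volume.subject_id
    rows = []
    for spec in atlas.roi_table:
        voxels = volume.data[atlas.label_volume == spec.label_value]
        if voxels.size == 0:
            raise ConsistencyError(f"ROI {spec.roi_id} has zero voxels in atlas")
        rows.append(
            {
                "subject_id": sid,
                "roi_id": spec.roi_id,
                "adc_statistic": float(reduce(voxels)),
                "restricted": pd.NA,
                "excluded": False,
            }
        )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def call_restriction(
    measurements: pd.DataFrame,
    threshold: float = DEFAULT_ADC_THRESHOLD,
) -> pd.DataFrame:
    """Call each ROI restricted iff its ADC statistic is strictly below
    ``threshold`` and the ROI is not excluded (chronic lesion / artefact).

    The inequality is strict: a statistic exactly at the threshold is not
    restricted.  Returns a copy with the ``restricted`` column filled.
    """
    out = measurements.copy()
    adc = out["adc_statistic"].astype(float)
    if not np.isfinite(adc).all():
        raise ValidationError("adc_statistic contains non-finite values")
    excluded = out["excluded"].fillna(False).astype(bool)
    out["restricted"] = ((adc < threshold) & ~excluded).astype(bool)
    return out


def mlp_from_restricted_classes(classes: Iterable[RegionClass]) -> int:
    """Map the set of restricted region classes to the MLP 1–4 score.

    Precedence: any deep grey matter (thalamus/hippocampus/brainstem) → 4;
    else basal ganglia → 3; else any cortical class → 2; else 1.
    """
    cs = set(classes)
    if cs & DEEP_CLASSES:
        return 4
    if RegionClass.BASAL_GANGLIA in cs:
        return 3
    if cs & CORTICAL_CLASSES:
        return 2
    return 1


def assign_mlp(
    measurements: pd.DataFrame,
    rois: Sequence[RoiSpec] | None = None,
) -> MlpScore:
    """Assign the MLP score from a complete per-ROI restriction table.

    ``measurements`` must contain exactly one row per ROI of the standard
    set (or of ``rois`` if given) with ``restricted`` populated; otherwise
    a ValidationError is raised.  The score depends only on which region
    classes contain a restricted ROI, never on ADC magnitudes.
    """
    if rois is None:
        rois = standard_roi_set()
    by_id = {r.roi_id: r for r in rois}

    ids = measurements["roi_id"].tolist()
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate roi_id rows in measurement table")
    missing = set(by_id) - set(ids)
    if missing:
        raise ValidationError(f"missing measurements for ROIs: {sorted(missing)}")
    extra = set(ids) - set(by_id)
    if extra:
        raise ValidationError(f"measurements for unknown ROIs: {sorted(extra)}")
    if measurements["restricted"].isna().any():
        raise ValidationError("restricted column not populated; run call_restriction")

    restricted_classes = [
        by_id[row.roi_id].region_class
        for row in measurements.itertuples()
        if bool(row.restricted)
    ]
    return MlpScore.from_value(mlp_from_restricted_classes(restricted_classes))


def dichotomize_mlp(score: MlpScore | int) -> Literal["severe", "non_severe"]:
    """Collapse MLP 1–4 into the severe (3–4) / non-severe (1–2) dichotomy."""
    value = score.value if isinstance(score, MlpScore) else int(score)
    if value not in (1, 2, 3, 4):
        raise ValidationError(f"MLP value must be 1..4, got {value}")
    return "severe" if value >= 3 else "non_severe"
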