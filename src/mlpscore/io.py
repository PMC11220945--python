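"""File formats: cohort CSV, ADC volumes as NIfTI, measurement CSV, JSON.

Cohort tables use a fixed RFC-4180 CSV layout with header
``subject_id,exclusion_reason,regained_consciousness_before_mri,
prognosticated_without_mri,other_pathology,mlp,cpc_d30,cpc_d180``;
boolean flags are stored as 0/1 and missing integers as empty fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ValidationError
from .synthetic import COHORT_COLUMNS, AdcVolume

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_adc_volume",
    "write_adc_volume",
    "write_json",
]

_BOOL_COLUMNS = (
    "regained_consciousness_before_mri",
    "prognosticated_without_mri",
    "other_pathology",
)
_INT_COLUMNS = ("mlp", "cpc_d30", "cpc_d180")


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = cohort.loc[:, COHORT_COLUMNS].copy()
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype(bool).astype(int)
    out.to_csv(path, index=False, lineterminator="\r\n")
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "exclusion_reason": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"cohort CSV missing columns: {sorted(missing)}")
    for col in _BOOL_COLUMNS:
        df[col] = df[col].fillna(0).astype(int).astype(bool)
    for col in _INT_COLUMNS:
        df[col] = pd.array(df[col], dtype="Int64")
    return df.loc[:, list(df.columns)]


def write_adc_volume(volume: AdcVolume, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag([*volume.voxel_size_mm, 1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, path)
    return path


def read_adc_volume(path: str | Path, subject_id: str | None = None) -> AdcVolume:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if subject_id is None:
        subject_id = path.name.split(".")[0].removesuffix("_adc")
    return AdcVolume(data, voxel_size, subject_id)


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    return path
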