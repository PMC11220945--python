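"""Grey-matter ROI scheme and a deterministic toy label atlas.

The scoring scheme reads apparent-diffusion-coefficient (ADC) values in 17
pre-defined grey-matter regions of interest: eight cerebral cortical ROIs
(frontal, parietal, temporal and occipital lobe, left and right), two
cerebellar cortical ROIs, two hippocampal, two basal-ganglia, two thalamic
and one midline brainstem ROI.  Cortical and hippocampal ROIs cover 4 mm²
in plane, the deeper structures 10 mm².

Real studies place these ROIs manually on clinical scans.  For testing and
simulation this module also builds a *toy* 3-D label atlas: a small volume
in which every ROI is realised as a single-slice rectangular patch of
exactly the prescribed in-plane area, left/right pairs mirrored about the
mid-sagittal plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConsistencyError, GeometryError, UnknownRoiError

__all__ = [
    "RegionClass",
    "RoiSpec",
    "ToyBrainAtlas",
    "CORTICAL_CLASSES",
    "DEEP_CLASSES",
    "standard_roi_set",
    "build_toy_atlas",
    "read_atlas",
    "write_atlas",
]


class RegionClass(str, Enum):
    """The six anatomical classes of measured grey matter."""

    CEREBRAL_CORTEX = "CEREBRAL_CORTEX"
    CEREBELLAR_CORTEX = "CEREBELLAR_CORTEX"
    HIPPOCAMPUS = "HIPPOCAMPUS"
    BASAL_GANGLIA = "BASAL_GANGLIA"
    THALAMUS = "THALAMUS"
    BRAINSTEM = "BRAINSTEM"


#: Classes whose involvement alone yields a "purely cortical" pattern (MLP 2).
CORTICAL_CLASSES = frozenset(
    {RegionClass.CEREBRAL_CORTEX, RegionClass.CEREBELLAR_CORTEX}
)
#: Deep grey-matter classes whose involvement defines the most severe pattern
#: (MLP 4): thalami, hippocampi, brainstem.
DEEP_CLASSES = frozenset(
    {RegionClass.THALAMUS, RegionClass.HIPPOCAMPUS, RegionClass.BRAINSTEM}
)

#: In-plane ROI area per region class, mm².
ROI_AREA_MM2 = {
    RegionClass.CEREBRAL_CORTEX: 4.0,
    RegionClass.CEREBELLAR_CORTEX: 4.0,
    RegionClass.HIPPOCAMPUS: 4.0,
    RegionClass.BASAL_GANGLIA: 10.0,
    RegionClass.THALAMUS: 10.0,
    RegionClass.BRAINSTEM: 10.0,
}

Hemisphere = Literal["L", "R", "midline"]


@dataclass(frozen=True)
class RoiSpec:
    """One region of interest: identity, class, side, area and atlas label."""

    roi_id: str
    region_class: RegionClass
    hemisphere: Hemisphere
    area_mm2: float
    label_value: int

    def __post_init__(self) -> None:
        if self.label_value <= 0:
            raise ValueError("label_value must be a positive integer")
        if self.area_mm2 != ROI_AREA_MM2[self.region_class]:
            raise ValueError(
                f"{self.roi_id}: area {self.area_mm2} mm² inconsistent with "
                f"class {self.region_class.value}"
            )


# (group, class, lateralised?) in a fixed order; label values are assigned
# sequentially from 1 so the standard set is stable across calls.
_STANDARD_GROUPS: tuple[tuple[str, RegionClass, bool], ...] = (
    ("frontal", RegionClass.CEREBRAL_CORTEX, True),
    ("parietal", RegionClass.CEREBRAL_CORTEX, True),
    ("temporal", RegionClass.CEREBRAL_CORTEX, True),
    ("occipital", RegionClass.CEREBRAL_CORTEX, True),
    ("cerebellum", RegionClass.CEREBELLAR_CORTEX, True),
    ("hippocampus", RegionClass.HIPPOCAMPUS, True),
    ("basal_ganglia", RegionClass.BASAL_GANGLIA, True),
    ("thalamus", RegionClass.THALAMUS, True),
    ("brainstem", RegionClass.BRAINSTEM, False),
)


def standard_roi_set() -> list[RoiSpec]:
    """The 17 ROIs of the standard scheme, in a stable order.

    Returns eight cerebral cortical ROIs (4 lobes × L/R), two cerebellar,
    two hippocampal, two basal-ganglia, two thalamic ROIs and one midline
    brainstem ROI, with 4 mm² areas for cortex/hippocampus and 10 mm² for
    the deep structures.
    """
    rois: list[RoiSpec] = []
    label = 1
    for group, region_class, lateralised in _STANDARD_GROUPS:
        area = ROI_AREA_MM2[region_class]
        if lateralised:
            for hemi in ("L", "R"):
                rois.append(RoiSpec(f"{group}_{hemi}", region_class, hemi, area, label))
                label += 1
        else:
            rois.append(RoiSpec(group, region_class, "midline", area, label))
            label += 1
    return rois


@dataclass
class ToyBrainAtlas:
    """A 3-D integer label volume plus the ROI table describing its labels.

    Background voxels are 0.  Each ROI's voxel count times the in-plane
    voxel area equals its nominal area in mm² (single-slice patches).
    """

    label_volume: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    roi_table: list[RoiSpec] = field(default_factory=list)

    @property
    def affine(self) -> np.ndarray:
        return np.diag([*self.voxel_size_mm, 1.0])

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.label_volume.shape)

    def roi_ids(self) -> list[str]:
        return [r.roi_id for r in self.roi_table]

    def spec_for(self, roi_id: str) -> RoiSpec:
        for r in self.roi_table:
            if r.roi_id == roi_id:
                return r
        raise UnknownRoiError(f"roi_id {roi_id!r} not in atlas")

    def mask_for(self, roi_id: str) -> np.ndarray:
        return self.label_volume == self.spec_for(roi_id).label_value

    def voxel_count(self, roi_id: str) -> int:
        return int(self.mask_for(roi_id).sum())

    def validate(self) -> None:
        """Raise ConsistencyError if any atlas invariant is violated."""
        dx, dy, _ = self.voxel_size_mm
        labels = [r.label_value for r in self.roi_table]
        if len(set(labels)) != len(labels):
            raise ConsistencyError("duplicate label values in roi_table")
        present = set(np.unique(self.label_volume)) - {0}
        missing = present - set(labels)
        if missing:
            raise ConsistencyError(
                f"labels {sorted(missing)} in volume but absent from roi_table"
            )
        for r in self.roi_table:
            count = int((self.label_volume == r.label_value).sum())
            if not math.isclose(count * dx * dy, r.area_mm2, rel_tol=1e-9):
                raise ConsistencyError(
                    f"{r.roi_id}: {count} voxels × {dx * dy} mm² ≠ {r.area_mm2} mm²"
                )


def _patch_shape(n_voxels: int) -> tuple[int, int]:
    """Near-square r×c factorisation of a voxel count (r ≤ c)."""
    r = max(d for d in range(1, int(math.isqrt(n_voxels)) + 1) if n_voxels % d == 0)
    return r, n_voxels // r


# Nominal patch centres in mm: (lateral offset from midline, anterior y, slice z).
_CENTRES_MM = {
    "frontal": (18.0, 58.0, 18.0),
    "parietal": (18.0, 22.0, 20.0),
    "temporal": (24.0, 44.0, 10.0),
    "occipital": (14.0, 8.0, 16.0),
    "cerebellum": (16.0, 12.0, 6.0),
    "hippocampus": (14.0, 34.0, 10.0),
    "basal_ganglia": (10.0, 44.0, 14.0),
    "thalamus": (6.0, 34.0, 14.0),
    "brainstem": (0.0, 36.0, 6.0),
}

_FOV_MM = (60.0, 72.0, 30.0)


def _voxels_for_area(area_mm2: float, dx: float, dy: float) -> int:
    n = area_mm2 / (dx * dy)
    if not math.isclose(n, round(n), abs_tol=1e-9):
        raise GeometryError(
            f"in-plane voxel area {dx * dy:g} mm² does not divide "
            f"{area_mm2:g} mm² into an integer voxel count"
        )
    return round(n)


def build_toy_atlas(
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
) -> ToyBrainAtlas:
    """Build the deterministic toy atlas housing the 17 standard ROIs.

    Each ROI is a single-slice rectangular patch whose voxel count times the
    in-plane voxel area equals its nominal area (4 mm² → 2×2 voxels and
    10 mm² → 2×5 voxels at 1 mm isotropic).  Left/right pairs are mirrored
    exactly about the mid-sagittal plane.  The seed jitters patch positions
    by up to one voxel in-plane (shared within an L/R pair so symmetry is
    preserved); the layout is deterministic for a fixed seed.

    Raises GeometryError when the in-plane voxel area does not divide both
    ROI areas into whole voxels.
    """
    dx, dy, dz = voxel_size_mm
    if min(voxel_size_mm) <= 0:
        raise GeometryError("voxel dimensions must be positive")
    for area in (4.0, 10.0):
        _voxels_for_area(area, dx, dy)

    shape = tuple(round(f / s) for f, s in zip(_FOV_MM, voxel_size_mm))
    labels = np.zeros(shape, dtype=np.int16)
    rng = np.random.default_rng(seed)
    rois = standard_roi_set()

    by_group: dict[str, list[RoiSpec]] = {}
    for r in rois:
        group = r.roi_id.rsplit("_", 1)[0] if r.hemisphere != "midline" else r.roi_id
        by_group.setdefault(group, []).append(r)

    for group, members in by_group.items():
        off_mm, y_mm, z_mm = _CENTRES_MM[group]
        n_vox = _voxels_for_area(members[0].area_mm2, dx, dy)
        pr, pc = _patch_shape(n_vox)
        jx, jy = rng.integers(-1, 2, size=2)
        z = round(z_mm / dz)
        y0 = round(y_mm / dy - pc / 2) + jy
        for spec in members:
            if spec.hemisphere == "midline":
                x0 = round(shape[0] / 2 - pr / 2)
            elif spec.hemisphere == "L":
                x0 = round((_FOV_MM[0] / 2 - off_mm) / dx - pr / 2) + jx
            else:  # exact mirror of the left patch
                x0_left = round((_FOV_MM[0] / 2 - off_mm) / dx - pr / 2) + jx
                x0 = shape[0] - x0_left - pr
            block = labels[x0 : x0 + pr, y0 : y0 + pc, z]
            if block.shape != (pr, pc) or np.any(block):
                raise GeometryError(
                    f"ROI {spec.roi_id} does not fit disjointly at "
                    f"voxel ({x0},{y0},{z})"
                )
            labels[x0 : x0 + pr, y0 : y0 + pc, z] = spec.label_value

    atlas = ToyBrainAtlas(labels, tuple(float(v) for v in voxel_size_mm), rois)
    atlas.validate()
    return atlas


_SIDECAR_COLUMNS = ["roi_id", "region_class", "hemisphere", "label_value", "area_mm2"]


def write_atlas(atlas: ToyBrainAtlas, nifti_path: str | Path,
                roi_csv_path: str | Path | None = None) -> tuple[Path, Path]:
    """Write the label volume as NIfTI and the ROI table as a CSV sidecar.

    The sidecar defaults to ``atlas_rois.csv`` next to the NIfTI file.
    Returns the two paths written.
    """
    nifti_path = Path(nifti_path)
    if roi_csv_path is None:
        roi_csv_path = nifti_path.parent / "atlas_rois.csv"
    roi_csv_path = Path(roi_csv_path)

    img = nib.Nifti1Image(atlas.label_volume.astype(np.int16), atlas.affine)
    img.header.set_zooms(atlas.voxel_size_mm)
    nib.save(img, nifti_path)

    pd.DataFrame(
        [
            {
                "roi_id": r.roi_id,
                "region_class": r.region_class.value,
                "hemisphere": r.hemisphere,
                "label_value": r.label_value,
                "area_mm2": r.area_mm2,
            }
            for r in atlas.roi_table
        ],
        columns=_SIDECAR_COLUMNS,
    ).to_csv(roi_csv_path, index=False)
    return nifti_path, roi_csv_path


def read_atlas(nifti_path: str | Path,
               roi_csv_path: str | Path | None = None) -> ToyBrainAtlas:
    """Read a label volume plus ROI-table sidecar back into a ToyBrainAtlas.

    Raises ConsistencyError when the volume contains a label missing from
    the sidecar table or any ROI's footprint disagrees with its area.
    """
    nifti_path = Path(nifti_path)
    if roi_csv_path is None:
        roi_csv_path = nifti_path.parent / "atlas_rois.csv"
    img = nib.load(nifti_path)
    labels = np.asarray(img.dataobj).astype(np.int16)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])

    table = pd.read_csv(roi_csv_path)
    rois = [
        RoiSpec(
            roi_id=str(row.roi_id),
            region_class=RegionClass(row.region_class),
            hemisphere=str(row.hemisphere),
            area_mm2=float(row.area_mm2),
            label_value=int(row.label_value),
        )
        for row in table.itertuples()
    ]
    atlas = ToyBrainAtlas(labels, voxel_size, rois)
    atlas.validate()
    return atlas
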