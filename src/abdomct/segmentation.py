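"""Landmark-bounded abdominal slab VOIs and HU-threshold segmentation.

The abdominal volume of interest is the stack of transverse slices between
two user-supplied landmark slice indices — in the study design, the cranial
margin of T10 and the cranial margin of S1 (T11 is substituted in dogs with
eight lumbar vertebrae).  The slab is half-open ``[cranial, caudal)`` so
adjacent slabs tile without double counting.  Tissue classes are segmented
by Hounsfield-unit intervals using a closed-open ``[lo, hi)`` convention,
except that a range whose upper bound equals the global ceiling (2000 HU by
default) is closed at the top — so the fat / lean / bone classes exactly
tile the all-tissue range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import BoundaryError, GeometryError
from .imaging_io import HU_MAX, HU_MIN, CTVolume, LabelMask

#: upper HU bound above which tissue volume no longer grows; ranges whose
#: upper bound equals this ceiling are closed at the top.
GLOBAL_CEILING = 2000


@dataclass(frozen=True)
class ThresholdRange:
    """A named Hounsfield-unit interval defining one tissue class."""

    label: str
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"{self.label}: require lo < hi, got {self.lo}/{self.hi}")
        if self.lo < HU_MIN or self.hi > HU_MAX:
            raise ValueError(f"{self.label}: bounds {self.lo}/{self.hi} outside [{HU_MIN}, {HU_MAX}]")

    def __str__(self) -> str:
        return f"{self.lo}/{self.hi}"

    def contains(self, hu: np.ndarray | int, ceiling: int = GLOBAL_CEILING) -> np.ndarray | bool:
        """Membership under the closed-open convention (closed at the ceiling)."""
        hu = np.asarray(hu)
        if self.hi == ceiling:
            return (hu >= self.lo) & (hu <= self.hi)
        return (hu >= self.lo) & (hu < self.hi)


@dataclass(frozen=True)
class SlabVOI:
    """A half-open stack of transverse slices, optionally restricted per slice.

    ``slice_masks`` maps a slice index inside the slab to a 2-D boolean
    in-plane inclusion mask recording manual adjustments.
    """

    cranial_index: int
    caudal_index: int
    shape: tuple[int, int, int]
    slice_masks: Mapping[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nz = self.shape[2]
        if not (0 <= self.cranial_index < self.caudal_index <= nz):
            raise BoundaryError(
                f"slab indices ({self.cranial_index}, {self.caudal_index}) invalid for "
                f"z-extent {nz}: require 0 <= cranial < caudal <= {nz}"
            )
        for k, m in self.slice_masks.items():
            if not (self.cranial_index <= k < self.caudal_index):
                raise BoundaryError(f"slice mask at {k} outside slab [{self.cranial_index}, {self.caudal_index})")
            if np.asarray(m).shape != self.shape[:2]:
                raise GeometryError(
                    f"slice mask at {k} has shape {np.asarray(m).shape}, expected {self.shape[:2]}"
                )

    @property
    def n_slices(self) -> int:
        return self.caudal_index - self.cranial_index

    def candidate_mask(self) -> np.ndarray:
        """3-D boolean mask of all candidate voxels in the VOI."""
        mask = np.zeros(self.shape, dtype=bool)
        mask[:, :, self.cranial_index : self.caudal_index] = True
        for k, m in self.slice_masks.items():
            mask[:, :, k] &= np.asarray(m, dtype=bool)
        return mask

    @property
    def candidate_count(self) -> int:
        return int(self.candidate_mask().sum())


@dataclass(frozen=True)
class SegmentationResult:
    """Voxel count, volume and mask for one threshold range inside a VOI."""

    range: ThresholdRange
    voxel_count: int
    volume_litres: float
    mask: LabelMask


def make_slab_voi(volume: CTVolume, cranial_index: int, caudal_index: int) -> SlabVOI:
    """Build the abdominal slab VOI from two landmark slice indices.

    The slab covers all in-plane voxels on slices
    ``[cranial_index, caudal_index)``.
    """
    return SlabVOI(cranial_index=int(cranial_index), caudal_index=int(caudal_index), shape=volume.shape)


def adjust_voi_slice(voi: SlabVOI, slice_index: int, mask2d: np.ndarray) -> SlabVOI:
    """Restrict one slice of the VOI to a 2-D inclusion mask.

    Repeated adjustments on the same slice intersect; adjustments on
    different slices commute.  Returns a new VOI (VOIs are immutable).
    """
    slice_index = int(slice_index)
    if not (voi.cranial_index <= slice_index < voi.caudal_index):
        raise BoundaryError(
            f"slice {slice_index} outside slab [{voi.cranial_index}, {voi.caudal_index})"
        )
    mask2d = np.asarray(mask2d, dtype=bool)
    if mask2d.shape != voi.shape[:2]:
        raise GeometryError(f"mask shape {mask2d.shape} does not match in-plane {voi.shape[:2]}")
    masks = dict(voi.slice_masks)
    masks[slice_index] = masks[slice_index] & mask2d if slice_index in masks else mask2d
    return replace(voi, slice_masks=masks)


def apply_threshold(
    volume: CTVolume,
    voi: SlabVOI,
    range: ThresholdRange,
    *,
    ceiling: int = GLOBAL_CEILING,
) -> SegmentationResult:
    """Segment one tissue class inside the VOI by its HU interval.

    The mask marks exactly the VOI voxels whose HU ``h`` satisfies
    ``lo <= h < hi`` (``<= hi`` when ``hi`` equals the ceiling).  The volume
    in litres is ``voxel_count * voxel_volume_mm3 * 1e-6``, exactly.
    """
    if voi.shape != volume.shape:
        raise GeometryError(f"VOI shape {voi.shape} does not match volume shape {volume.shape}")
    selected = voi.candidate_mask() & range.contains(volume.voxels, ceiling=ceiling)
    count = int(selected.sum())
    mask = LabelMask(
        voxels=selected.astype(np.uint8),
        spacing=volume.spacing,
        origin=volume.origin,
        axis_order=volume.axis_order,
    )
    return SegmentationResult(
        range=range,
        voxel_count=count,
        volume_litres=count * volume.voxel_volume_mm3 * 1e-6,
        mask=mask,
    )
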