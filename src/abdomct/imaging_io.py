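"""Reading and writing CT volumes and label masks.

The in-memory model is :class:`CTVolume`: a 3-D grid of integer Hounsfield
units (HU) plus voxel spacing and origin in millimetres.  The grid axis
convention is fixed and enforced at load time:

* axis 0 — left-right (x)
* axis 1 — dorsal-ventral (y)
* axis 2 — cranial-caudal (z), index increasing cranial → caudal

Volumes are read from a DICOM series (directory of single-slice ``.dcm``
files) or from NIfTI-1; masks are written and read as NIfTI-1.  Stored DICOM
pixel values are converted to HU with the rescale slope/intercept carried in
each file, and the slice spacing is derived from the physical inter-slice
distance rather than the nominal thickness tag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .errors import FormatError, GeometryError

HU_MIN = -1024
HU_MAX = 4000

#: fixed grid-axis convention (axis 0, 1, 2)
AXIS_ORDER = ("left-right", "dorsal-ventral", "cranial-caudal")


def round_half_away(values: np.ndarray) -> np.ndarray:
    """Round to the nearest integer, ties away from zero.

    HU are integer-quantised in practice; this rounding is deterministic
    and symmetric about zero (unlike banker's rounding).
    """
    values = np.asarray(values, dtype=float)
    return np.copysign(np.floor(np.abs(values) + 0.5), values)


def _as_triple(v, name: str) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units with physical geometry.

    ``voxels`` is integer HU, indexed ``[x, y, z]`` per :data:`AXIS_ORDER`;
    ``spacing`` and ``origin`` are millimetres.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: tuple[str, str, str] = AXIS_ORDER
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise TypeError("HU voxel values must be integers (rescale and round first)")
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise GeometryError(f"voxel grid must be 3-D and non-empty, got shape {self.voxels.shape}")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing components must be positive, got {self.spacing}")
        lo, hi = int(self.voxels.min()), int(self.voxels.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(f"HU values outside [{HU_MIN}, {HU_MAX}]: range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        """Number of transverse (cranial-caudal) slices."""
        return self.voxels.shape[2]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff


@dataclass
class LabelMask:
    """Integer class labels (0 = background) on the grid of a source volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: tuple[str, str, str] = AXIS_ORDER

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            self.voxels = self.voxels.astype(np.uint8)
        if self.voxels.ndim != 3:
            raise GeometryError("label mask must be 3-D")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def save_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (int16 HU, geometry in the affine)."""
    img = nib.Nifti1Image(volume.voxels.astype(np.int16), volume.affine())
    nib.save(img, str(path))


def _load_nifti_grid(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = round_half_away(img.get_fdata()).astype(np.int64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    return data, zooms, origin


def save_mask(mask: LabelMask, path: str | Path) -> None:
    """Persist a label mask as NIfTI-1; reload reproduces labels exactly."""
    img = nib.Nifti1Image(mask.voxels.astype(np.int16), mask.affine())
    nib.save(img, str(path))


def load_mask(path: str | Path) -> LabelMask:
    data, zooms, origin = _load_nifti_grid(Path(path))
    return LabelMask(voxels=data.astype(np.int16), spacing=zooms, origin=origin)


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

_REQUIRED_TAGS = ("ImagePositionPatient", "ImageOrientationPatient", "PixelSpacing")


def _slice_files(directory: Path) -> list[Path]:
    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() == ".dcm")
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise FormatError(f"{directory}: no DICOM slice files found")
    return files


def _load_dicom_series(directory: Path) -> CTVolume:
    slices = []
    for f in _slice_files(directory):
        ds = pydicom.dcmread(str(f))
        for tag in _REQUIRED_TAGS:
            if getattr(ds, tag, None) is None:
                raise FormatError(f"{f.name}: missing geometry tag {tag}")
        slices.append((f, ds))

    uids = {str(ds.SeriesInstanceUID) for _, ds in slices if hasattr(ds, "SeriesInstanceUID")}
    if len(uids) != 1:
        raise FormatError(f"{directory}: mixed or missing SeriesInstanceUID ({len(uids)} found)")

    ref_orient = np.asarray(slices[0][1].ImageOrientationPatient, dtype=float)
    ref_ps = np.asarray(slices[0][1].PixelSpacing, dtype=float)
    for f, ds in slices[1:]:
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, dtype=float), ref_orient):
            raise FormatError(f"{f.name}: inconsistent ImageOrientationPatient")
        if not np.allclose(np.asarray(ds.PixelSpacing, dtype=float), ref_ps):
            raise FormatError(f"{f.name}: inconsistent PixelSpacing")

    row_dir, col_dir = ref_orient[:3], ref_orient[3:]
    normal = np.cross(row_dir, col_dir)
    # order slices by physical position along the slice normal (cranial→caudal)
    keyed = sorted(
        slices, key=lambda fd: float(np.dot(np.asarray(fd[1].ImagePositionPatient, dtype=float), normal))
    )
    positions = np.array(
        [float(np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal)) for _, ds in keyed]
    )

    if len(keyed) > 1:
        gaps = np.diff(positions)
        slice_spacing = float(np.median(gaps))
        if slice_spacing <= 0:
            raise FormatError(f"{directory}: non-increasing slice positions")
        if not np.allclose(gaps, slice_spacing, rtol=1e-3, atol=1e-6):
            raise FormatError(f"{directory}: irregular inter-slice spacing {gaps}")
        nominal = getattr(keyed[0][1], "SliceThickness", None)
        if nominal is not None and float(nominal) > 0:
            if abs(slice_spacing - float(nominal)) / float(nominal) > 0.01:
                warnings.warn(
                    f"slice spacing from positions ({slice_spacing:g} mm) disagrees >1% "
                    f"with SliceThickness tag ({float(nominal):g} mm); using positions",
                    stacklevel=3,
                )
    else:
        nominal = getattr(keyed[0][1], "SliceThickness", None)
        slice_spacing = float(nominal) if nominal else 1.0

    planes = []
    for f, ds in keyed:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = round_half_away(ds.pixel_array.astype(float) * slope + intercept)
        planes.append(np.clip(hu, HU_MIN, HU_MAX).astype(np.int16).T)  # (rows, cols) -> (x, y)

    voxels = np.stack(planes, axis=2)
    ipp0 = np.asarray(keyed[0][1].ImagePositionPatient, dtype=float)
    # PixelSpacing is (row spacing, column spacing) = (y, x)
    spacing = (float(ref_ps[1]), float(ref_ps[0]), slice_spacing)
    meta = {
        "series_uid": uids.pop(),
        "n_slices": len(keyed),
        "kvp": getattr(keyed[0][1], "KVP", None),
    }
    return CTVolume(voxels=voxels, spacing=spacing, origin=tuple(ipp0), meta=meta)


def load_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    ``format`` is ``"nifti"`` or ``"dicom-series"``; when omitted it is
    inferred from the path (directory → DICOM series, file → NIfTI).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "dicom-series" if path.is_dir() else "nifti"
    if format == "nifti":
        data, zooms, origin = _load_nifti_grid(path)
        data = np.clip(data, HU_MIN, HU_MAX).astype(np.int16)
        return CTVolume(voxels=data, spacing=zooms, origin=origin, meta={"source": str(path)})
    if format == "dicom-series":
        if not path.is_dir():
            raise FormatError(f"{path}: dicom-series format expects a directory of slices")
        return _load_dicom_series(path)
    raise ValueError(f"unknown format {format!r} (expected 'nifti' or 'dicom-series')")


def write_dicom_series(
    volume: CTVolume,
    directory: str | Path,
    *,
    rescale_slope: float = 1.0,
    rescale_intercept: float = -1024.0,
    series_uid: str | None = None,
    meta: Mapping | None = None,
) -> list[Path]:
    """Write a volume as a directory of single-slice CT DICOM files.

    Stored pixel values are ``(HU - intercept) / slope`` as unsigned 16-bit,
    so a reader applying the rescale tags recovers HU exactly for integral
    slopes/intercepts.  Mainly used to exercise the DICOM reading path on
    synthetic data.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    sx, sy, sz = volume.spacing
    stored = (volume.voxels.astype(float) - rescale_intercept) / rescale_slope
    stored_i = round_half_away(stored)
    if stored_i.min() < 0 or stored_i.max() > 65535:
        raise ValueError("stored values out of uint16 range for the given rescale")
    stored_u16 = stored_i.astype(np.uint16)

    paths = []
    for k in range(volume.n_slices):
        ds = pydicom.Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            volume.origin[0],
            volume.origin[1],
            volume.origin[2] + k * sz,
        ]
        ds.PixelSpacing = [sy, sx]  # (row, col)
        ds.SliceThickness = sz
        ds.Rows, ds.Columns = volume.shape[1], volume.shape[0]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = rescale_slope
        ds.RescaleIntercept = rescale_intercept
        if meta:
            for key, val in meta.items():
                setattr(ds, key, val)
        ds.PixelData = stored_u16[:, :, k].T.tobytes()  # (x, y) -> (rows, cols)

        fm = FileMetaDataset()
        fm.MediaStorageSOPClassUID = ds.SOPClassUID
        fm.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        fm.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = fm

        out = directory / f"slice_{k:04d}.dcm"
        ds.save_as(str(out), enforce_file_format=True)
        paths.append(out)
    return paths
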