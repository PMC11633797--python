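"""Volume data model, standard-format I/O and ROI primitives.

The in-memory convention throughout the package is a ``(z, y, x)`` voxel
array in Hounsfield units with per-axis spacing in millimetres.  ROI
positions are physical millimetres in the volume's frame: the centre of
voxel ``(k, i, j)`` sits at ``origin + (k*dz, i*dy, j*dx)``.  A voxel
belongs to an ROI when its centre falls inside the region (circles are
closed, rectangles are half-open ``[corner, corner + size)``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from .errors import (
    DataError,
    DegenerateInputError,
    DegenerateROIError,
    FormatError,
    GeometryError,
)

__all__ = [
    "Volume3D",
    "CircularROI",
    "RectROI",
    "ROIStats",
    "read_volume",
    "write_volume",
    "extract_roi_values",
    "roi_stats",
]


@dataclass(frozen=True)
class Volume3D:
    """A 3D HU voxel grid with physical geometry.

    Parameters
    ----------
    voxels:
        ``(nz, ny, nx)`` array of finite HU values (stored as float64).
    spacing:
        ``(dz, dy, dx)`` voxel pitch in mm, all strictly positive.
    origin:
        Physical position (mm) of the centre of voxel ``(0, 0, 0)``,
        ordered ``(z, y, x)``.
    slice_axis:
        Index of the through-plane axis; the package convention is 0.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slice_axis: int = 0

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float64)
        if vox.ndim != 3:
            raise DataError(f"expected a 3D voxel grid, got ndim={vox.ndim}")
        if not np.all(np.isfinite(vox)):
            raise DataError("voxel grid contains non-finite HU values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise GeometryError(f"spacing must be 3 positive components, got {self.spacing}")
        origin = tuple(float(o) for o in self.origin)
        if self.slice_axis != 0:
            raise GeometryError("only slice_axis=0 (z, y, x ordering) is supported")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def with_voxels(self, voxels: np.ndarray) -> "Volume3D":
        """New volume on the same grid with replaced voxel values."""
        return Volume3D(voxels, self.spacing, self.origin, self.slice_axis)

    def plane_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical in-plane coordinates (mm) of voxel centres: (y, x)."""
        _, ny, nx = self.shape
        _, dy, dx = self.spacing
        _, oy, ox = self.origin
        return oy + np.arange(ny) * dy, ox + np.arange(nx) * dx

    def z_coords(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.n_slices) * self.spacing[0]

    def same_grid(self, other: "Volume3D", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass(frozen=True)
class CircularROI:
    """Circular in-plane ROI: centre ``(y, x)`` in mm, diameter in mm."""

    center: tuple[float, float]
    diameter: float
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise GeometryError("ROI diameter must be > 0")


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangular ROI: ``corner`` is the (y, x) of the
    minimum corner in mm, ``size`` is (height, width) in mm.  Membership
    is half-open: ``corner <= centre < corner + size``."""

    corner: tuple[float, float]
    size: tuple[float, float]
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.size[0] <= 0 or self.size[1] <= 0:
            raise GeometryError("ROI size components must be > 0")


ROI = Union[CircularROI, RectROI]


@dataclass(frozen=True)
class ROIStats:
    mean: float
    sd: float
    p10: float
    p90: float


def _slice_bounds(vol: Volume3D) -> tuple[float, float, float, float]:
    # physical extent of the slice including the half-voxel skin
    (_, ny, nx), (_, dy, dx) = vol.shape, vol.spacing
    _, oy, ox = vol.origin
    return (oy - dy / 2, oy + (ny - 0.5) * dy, ox - dx / 2, ox + (nx - 0.5) * dx)


def extract_roi_values(vol: Volume3D, roi: ROI) -> np.ndarray:
    """HU values of all voxels whose in-plane centre lies inside ``roi``."""
    if not 0 <= roi.slice_index < vol.n_slices:
        raise GeometryError(f"slice_index {roi.slice_index} outside volume (nz={vol.n_slices})")
    y, x = vol.plane_coords()
    ymin, ymax, xmin, xmax = _slice_bounds(vol)
    plane = vol.voxels[roi.slice_index]
    if isinstance(roi, CircularROI):
        cy, cx = roi.center
        r = roi.diameter / 2.0
        if cy - r < ymin or cy + r > ymax or cx - r < xmin or cx + r > xmax:
            raise GeometryError("circular ROI extends outside the slice bounds")
        yy = (y - cy)[:, None]
        xx = (x - cx)[None, :]
        mask = yy * yy + xx * xx <= r * r
    else:
        y0, x0 = roi.corner
        h, w = roi.size
        if y0 < ymin or y0 + h > ymax or x0 < xmin or x0 + w > xmax:
            raise GeometryError("rectangular ROI extends outside the slice bounds")
        mask = ((y >= y0) & (y < y0 + h))[:, None] & ((x >= x0) & (x < x0 + w))[None, :]
    values = plane[mask]
    if values.size == 0:
        raise DegenerateROIError("ROI contains no voxel centres")
    return values


def roi_stats(values: Iterable[float]) -> ROIStats:
    """Mean, population SD and linearly interpolated 10th/90th percentiles."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=np.float64)
    if arr.size == 0:
        raise DegenerateInputError("roi_stats requires a non-empty value list")
    p10, p90 = np.percentile(arr, [10.0, 90.0])
    return ROIStats(mean=float(arr.mean()), sd=float(arr.std()), p10=float(p10), p90=float(p90))


# ---------------------------------------------------------------------------
# I/O: NIfTI-1 (nibabel) and DICOM series (pydicom, one CT file per slice)
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "dicom-series"
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    raise FormatError(f"cannot infer volume format from {path}")


def read_volume(path: os.PathLike | str, format: str | None = None) -> Volume3D:
    """Read a volume as HU.

    ``format`` is ``"nifti"`` or ``"dicom-series"``; inferred from the path
    (directory -> DICOM series, ``.nii``/``.nii.gz`` -> NIfTI) when omitted.
    DICOM RescaleSlope/Intercept are applied.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "dicom-series":
        return _read_dicom_series(path)
    raise FormatError(f"unknown format {fmt!r}")


def write_volume(vol: Volume3D, path: os.PathLike | str, format: str | None = None) -> None:
    """Write a volume; see :func:`read_volume` for the formats.

    DICOM stores int16 values with slope 1 / intercept -1024, i.e. HU are
    quantized to integers; NIfTI stores float64 losslessly.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        _write_nifti(vol, path)
    elif fmt == "dicom-series":
        _write_dicom_series(vol, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def _read_nifti(path: Path) -> Volume3D:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error variety
        raise FormatError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI volume, got ndim={data.ndim}")
    dx, dy, dz = (float(z) for z in img.header.get_zooms()[:3])
    t = img.affine[:3, 3]
    # nibabel data axes are (x, y, z); package convention is (z, y, x)
    return Volume3D(np.ascontiguousarray(data.T), (dz, dy, dx), (float(t[2]), float(t[1]), float(t[0])))


def _write_nifti(vol: Volume3D, path: Path) -> None:
    import nibabel as nib

    dz, dy, dx = vol.spacing
    oz, oy, ox = vol.origin
    affine = np.array(
        [[dx, 0, 0, ox], [0, dy, 0, oy], [0, 0, dz, oz], [0, 0, 0, 1.0]]
    )
    img = nib.Nifti1Image(np.ascontiguousarray(vol.voxels.T), affine)
    img.header.set_zooms((dx, dy, dz))
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise FormatError(f"could not write {path}: {exc}") from exc


_DICOM_INTERCEPT = -1024.0


def _write_dicom_series(vol: Volume3D, outdir: Path) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    outdir.mkdir(parents=True, exist_ok=True)
    stored = np.rint(vol.voxels - _DICOM_INTERCEPT)
    if stored.min() < np.iinfo(np.int16).min or stored.max() > np.iinfo(np.int16).max:
        raise DataError("HU range not representable as int16 with intercept -1024")
    stored = stored.astype(np.int16)
    dz, dy, dx = vol.spacing
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    for k in range(vol.n_slices):
        ds = Dataset()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.PatientName = "Phantom"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [vol.origin[2], vol.origin[1], vol.origin[0] + k * dz]
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.SpacingBetweenSlices = dz
        ds.Rows, ds.Columns = vol.shape[1], vol.shape[2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = _DICOM_INTERCEPT
        ds.PixelData = stored[k].tobytes()
        try:
            pydicom.dcmwrite(outdir / f"slice_{k:04d}.dcm", ds, enforce_file_format=True)
        except OSError as exc:
            raise FormatError(f"could not write DICOM slice to {outdir}: {exc}") from exc


def _read_dicom_series(indir: Path) -> Volume3D:
    import pydicom

    files = sorted(p for p in indir.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FormatError(f"no .dcm files in {indir}")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception as exc:
            raise FormatError(f"could not parse DICOM file {f}: {exc}") from exc
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    zs = np.array([float(d.ImagePositionPatient[2]) for d in datasets])
    if len(zs) > 1:
        steps = np.diff(zs)
        if steps.min() <= 0 or np.ptp(steps) > 1e-3:
            raise GeometryError("inconsistent slice spacing in DICOM series")
        dz = float(steps.mean())
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))
    d0 = datasets[0]
    dy, dx = (float(v) for v in d0.PixelSpacing)
    slices = []
    for d in datasets:
        arr = d.pixel_array.astype(np.float64)
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    origin = (float(zs[0]), float(d0.ImagePositionPatient[1]), float(d0.ImagePositionPatient[0]))
    return Volume3D(np.stack(slices), (dz, dy, dx), origin)
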