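"""Reading and writing 3D medical volumes and binary masks.

Conventions
-----------
Arrays are indexed ``(i, j, k)`` and treated as ``(x, y, z)``.  All internal
computation is in voxel units; per-axis spacing (mm) is carried purely as
metadata so that files round-trip faithfully.  Intensities are kept exactly as
read -- no implicit normalization -- so that raw thresholds (e.g. a global
lower bound of 200 gray levels) keep their meaning.

Supported formats: NIfTI-1 (``.nii``/``.nii.gz``, via nibabel), NRRD (via
SimpleITK) and single-series DICOM directories (read-only, via pydicom).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import AmbiguousSeriesError, FormatError

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "mip",
    "save_mip",
]


@dataclass
class ImageVolume:
    """A 3D scalar image ``I`` over the voxel domain.

    Parameters
    ----------
    data : ndarray
        3D array of intensities (arbitrary units), axes ``(x, y, z)``.
    spacing : tuple of float
        Per-axis voxel size in mm; strictly positive.
    origin : tuple of float
        Physical offset of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must be a 3D array with nonempty axes")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def intensity_range(self) -> tuple[float, float]:
        """Observed (min, max) of the data."""
        return float(self.data.min()), float(self.data.max())


@dataclass
class BinaryMask:
    """A voxel set (segmentation) stored as a {0,1} array."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("mask must be a 3D array")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def volume_voxels(self) -> int:
        return int(self.data.sum())


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if path.is_dir():
        return "dicom_dir"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".nrrd", ".nhdr")):
        return "nrrd"
    raise FormatError(f"cannot infer volume format from path {path!s}")


def read_volume(
    path: str | os.PathLike,
    format_hint: Literal["dicom_dir", "nifti", "nrrd"] | None = None,
) -> ImageVolume:
    """Read a 3D volume from NIfTI, NRRD, or a single-series DICOM directory.

    Axis order is fixed as ``(x, y, z)``; spacing defaults to (1, 1, 1) when
    the file carries no metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path!s}")
    fmt = format_hint or _detect_format(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "nrrd":
        return _read_nrrd(path)
    if fmt == "dicom_dir":
        return _read_dicom_dir(path)
    raise FormatError(f"unknown format {fmt!r}")


def _read_nifti(path: Path) -> ImageVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise FormatError(f"unreadable NIfTI file {path!s}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(np.asarray(data), tuple(float(z) for z in zooms), origin)


def _read_nrrd(path: Path) -> ImageVolume:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise FormatError(f"unreadable NRRD file {path!s}: {exc}") from exc
    # SimpleITK arrays come back (z, y, x); transpose to our (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def _read_dicom_dir(path: Path) -> ImageVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # skip non-DICOM clutter (DICOMDIR, reports, ...)
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no readable DICOM slices in {path!s}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) > 1:
        raise AmbiguousSeriesError(
            f"directory {path!s} contains {len(uids)} DICOM series; "
            "split it into one directory per series"
        )
    slices = _sort_dicom_slices(slices)
    arrays = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(arr * slope + intercept)
    # pixel_array is (row, col); stack slices on the last axis -> (x, y, z)
    data = np.stack(arrays, axis=-1)
    ds0 = slices[0]
    px = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    dz = _dicom_slice_spacing(slices)
    origin = tuple(float(v) for v in getattr(ds0, "ImagePositionPatient", (0, 0, 0)))
    return ImageVolume(data, (float(px[0]), float(px[1]), dz), origin)


def _sort_dicom_slices(slices: list) -> list:
    """Order slices along the acquisition normal; fall back to InstanceNumber."""
    try:
        ori = np.array(slices[0].ImageOrientationPatient, float)
        normal = np.cross(ori[:3], ori[3:])
        return sorted(
            slices,
            key=lambda ds: float(np.dot(np.array(ds.ImagePositionPatient, float), normal)),
        )
    except Exception:
        return sorted(slices, key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))


def _dicom_slice_spacing(slices: list) -> float:
    if len(slices) >= 2:
        try:
            ori = np.array(slices[0].ImageOrientationPatient, float)
            normal = np.cross(ori[:3], ori[3:])
            p0 = np.dot(np.array(slices[0].ImagePositionPatient, float), normal)
            p1 = np.dot(np.array(slices[1].ImagePositionPatient, float), normal)
            d = abs(p1 - p0)
            if d > 0:
                return float(d)
        except Exception:
            pass
    return float(getattr(slices[0], "SliceThickness", 1.0))


def write_volume(
    volume: ImageVolume,
    path: str | os.PathLike,
    format: Literal["nifti", "nrrd"] | None = None,
) -> None:
    """Write a volume as NIfTI or NRRD (format inferred from the suffix)."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        try:
            nib.save(nib.Nifti1Image(np.asarray(volume.data, np.float64), affine), str(path))
        except Exception as exc:
            raise FormatError(f"cannot write NIfTI file {path!s}: {exc}") from exc
    elif fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.asarray(volume.data, np.float64).transpose(2, 1, 0))
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        try:
            sitk.WriteImage(img, str(path))
        except Exception as exc:
            raise FormatError(f"cannot write NRRD file {path!s}: {exc}") from exc
    else:
        raise FormatError(f"unsupported write format {fmt!r}")


def write_mask(
    mask: BinaryMask,
    path: str | os.PathLike,
    format: Literal["nifti", "nrrd"] | None = None,
) -> None:
    """Write a binary mask; reloading gives back the identical voxel set."""
    vol = ImageVolume(mask.data.astype(np.uint8), mask.spacing)
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0])
        try:
            nib.save(nib.Nifti1Image(vol.data.astype(np.uint8), affine), str(path))
        except Exception as exc:
            raise FormatError(f"cannot write NIfTI file {path!s}: {exc}") from exc
    elif fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(vol.data.astype(np.uint8).transpose(2, 1, 0))
        img.SetSpacing(vol.spacing)
        try:
            sitk.WriteImage(img, str(path))
        except Exception as exc:
            raise FormatError(f"cannot write NRRD file {path!s}: {exc}") from exc
    else:
        raise FormatError(f"unsupported write format {fmt!r}")


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a binary mask previously written by :func:`write_mask`."""
    vol = read_volume(path)
    return BinaryMask((np.asarray(vol.data) > 0.5).astype(np.uint8), vol.spacing)


def mip(volume: ImageVolume, axis: int) -> np.ndarray:
    """Maximum intensity projection along one axis.

    The standard rendering for angiographic volumes: each output pixel is the
    maximum intensity along the projection ray.
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    return np.asarray(volume.data).max(axis=axis)


def save_mip(image2d: np.ndarray, path: str | os.PathLike) -> None:
    """Save a 2D projection as a grayscale PNG/TIFF."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(str(path), np.asarray(image2d).T, cmap="gray", origin="lower")
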