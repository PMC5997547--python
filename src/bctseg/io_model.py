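"""Volumes, slices and label maps: containers, conventions and file I/O.

Conventions shared by every module:

* Arrays are indexed ``(slice, row, col)``, 0-based.  The slice axis is
  the cranio-caudal direction of the coronal stack, i.e. the direction
  along which the classifier iterates slice by slice.
* All internal processing happens on normalized ``[0, 1]`` intensities;
  :func:`normalize` maps raw HU (or arbitrary scalar) volumes onto that
  range once, up front.
* Label codes are fixed so outputs are comparable across runs:
  0 background, 1 adipose, 2 fibroglandular, 3 skin, 4 vasculature.

Supported formats: DICOM series (read), NIfTI ``.nii``/``.nii.gz``
(read/write) and multi-page TIFF (read/write).  Label maps are written
as unsigned 8-bit.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError, FormatError

logger = logging.getLogger(__name__)

#: Default in-plane voxel pitch (mm) used when file metadata carries none;
#: matches the 273 um reconstructed voxel size typical of dedicated breast CT.
DEFAULT_SPACING_MM = 0.273

# Label codes -----------------------------------------------------------
BACKGROUND = 0
ADIPOSE = 1
FIBROGLANDULAR = 2
SKIN = 3
VASCULATURE = 4

LABELS = (BACKGROUND, ADIPOSE, FIBROGLANDULAR, SKIN, VASCULATURE)
LABEL_NAMES = {
    BACKGROUND: "background",
    ADIPOSE: "adipose",
    FIBROGLANDULAR: "fibroglandular",
    SKIN: "skin",
    VASCULATURE: "vasculature",
}
#: Tissue classes (background excluded), in code order.
TISSUE_LABELS = (ADIPOSE, FIBROGLANDULAR, SKIN, VASCULATURE)


@dataclass
class Volume:
    """A 3D scalar volume with voxel spacing.

    Parameters
    ----------
    data
        ``(slice, row, col)`` scalar array, HU or normalized ``[0, 1]``.
    spacing
        Voxel pitch in mm, one value per axis.
    normalized
        True once :func:`normalize` has mapped the data onto ``[0, 1]``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (
        DEFAULT_SPACING_MM,
        DEFAULT_SPACING_MM,
        DEFAULT_SPACING_MM,
    )
    normalized: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"Volume data must be 3D, got {self.data.ndim}D")
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")
        if self.normalized:
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise FormatError(
                    f"normalized volume outside [0,1]: [{lo}, {hi}]"
                )

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def get_slice(self, index: int) -> "ImageSlice":
        return ImageSlice(self.data[index], self.spacing[1:])


@dataclass
class ImageSlice:
    """A single 2D coronal slice, indexed ``(i, j) = (row, col)``."""

    data: np.ndarray
    spacing: tuple[float, float] = (DEFAULT_SPACING_MM, DEFAULT_SPACING_MM)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise FormatError(f"ImageSlice data must be 2D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("ImageSlice contains non-finite values")


@dataclass
class LabelMap:
    """Integer per-voxel class codes, same shape as the source image."""

    data: np.ndarray
    spacing: tuple = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise FormatError("LabelMap data must be an integer array")
        bad = np.setdiff1d(np.unique(self.data), np.asarray(LABELS))
        if bad.size:
            raise FormatError(f"LabelMap contains invalid codes: {bad.tolist()}")
        if self.spacing is None:
            ndim = self.data.ndim
            self.spacing = (DEFAULT_SPACING_MM,) * ndim

    def class_mask(self, code: int) -> np.ndarray:
        return self.data == code


# ----------------------------------------------------------------------
# Loading


def _load_dicom_dir(path: Path) -> Volume:
    import pydicom

    files = sorted(
        p for p in path.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", "")
    )
    if not files:
        raise FormatError(f"no DICOM files in {path}")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception as exc:  # pragma: no cover - passthrough detail
            raise FormatError(f"unreadable DICOM file {f}: {exc}") from exc

    def sort_key(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return int(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    arrays = [ds.pixel_array for ds in datasets]
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise FormatError(f"inconsistent slice shapes in DICOM series: {shapes}")
    data = np.stack(arrays).astype(np.float64)
    ds0 = datasets[0]
    slope = float(getattr(ds0, "RescaleSlope", 1.0))
    intercept = float(getattr(ds0, "RescaleIntercept", 0.0))
    data = data * slope + intercept
    if hasattr(ds0, "PixelSpacing"):
        ri, ci = (float(v) for v in ds0.PixelSpacing)
    else:
        ri = ci = DEFAULT_SPACING_MM
        logger.warning("DICOM series without PixelSpacing; assuming %.3f mm", ri)
    zi = float(getattr(ds0, "SliceThickness", 0) or 0) or ri
    return Volume(data, spacing=(zi, ri, ci))


def _load_nifti(path: Path) -> Volume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"unreadable NIfTI file {path}: {exc}") from exc
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 2:
        arr = arr[..., np.newaxis]
    if arr.ndim != 3:
        raise FormatError(f"NIfTI volume must be 2D/3D, got {arr.ndim}D")
    # NIfTI stores (col, row, slice); internal order is (slice, row, col).
    data = np.transpose(arr, (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    if any(s <= 0 for s in spacing):
        spacing = (DEFAULT_SPACING_MM,) * 3
        logger.warning("NIfTI with non-positive zooms; assuming %.3f mm", spacing[0])
    return Volume(data, spacing=spacing)


def _load_tiff_stack(path: Path) -> Volume:
    import tifffile

    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:
        raise FormatError(f"unreadable TIFF file {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise FormatError(f"TIFF stack must be 2D/3D, got {arr.ndim}D")
    logger.warning(
        "TIFF carries no voxel spacing; assuming %.3f mm isotropic",
        DEFAULT_SPACING_MM,
    )
    return Volume(arr.astype(np.float64), spacing=(DEFAULT_SPACING_MM,) * 3)


_LOADERS = {
    "dicom_dir": _load_dicom_dir,
    "nifti": _load_nifti,
    "tiff_stack": _load_tiff_stack,
}


def load_volume(path: str | os.PathLike, format: str | None = None) -> Volume:
    """Read a volume from disk.

    Parameters
    ----------
    path
        File (NIfTI, multi-page TIFF) or directory (DICOM series).
    format
        One of ``dicom_dir``, ``nifti``, ``tiff_stack``; guessed from the
        path when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"path does not exist: {path}")
    if format is None:
        if path.is_dir():
            format = "dicom_dir"
        elif path.name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif path.suffix.lower() in (".tif", ".tiff"):
            format = "tiff_stack"
        else:
            raise FormatError(f"cannot guess format of {path}")
    try:
        loader = _LOADERS[format]
    except KeyError:
        raise FormatError(f"unknown format {format!r}") from None
    return loader(path)


# ----------------------------------------------------------------------
# Normalization


def normalize(volume: Volume) -> Volume:
    """Linearly rescale a volume so min -> 0 and max -> 1.

    Idempotent: a volume already flagged as normalized is returned
    unchanged.  Raises :class:`DegenerateInputError` on constant input.
    """
    if volume.normalized:
        return volume
    data = np.asarray(volume.data, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    if not np.isfinite([lo, hi]).all():
        raise DegenerateInputError("volume has non-finite dynamic range")
    if hi == lo:
        raise DegenerateInputError("constant-valued volume cannot be normalized")
    out = (data - lo) / (hi - lo)
    return replace(volume, data=out, normalized=True)


# ----------------------------------------------------------------------
# Saving


def save_labelmap(labels: LabelMap, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a label map as unsigned 8-bit NIfTI or multi-page TIFF.

    ``load_labelmap(save_labelmap(x))`` is bit-identical.
    """
    path = Path(path)
    data = labels.data
    if data.ndim == 2:
        data = data[np.newaxis]
    data8 = data.astype(np.uint8)
    if format is None:
        if path.name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif path.suffix.lower() in (".tif", ".tiff"):
            format = "tiff_stack"
        else:
            raise FormatError(f"cannot guess format of {path}")
    spacing = labels.spacing
    if len(spacing) == 2:
        spacing = (DEFAULT_SPACING_MM,) + tuple(spacing)
    try:
        if format == "nifti":
            import nibabel as nib

            arr = np.transpose(data8, (2, 1, 0))
            affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
            img = nib.Nifti1Image(arr, affine)
            img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
            nib.save(img, str(path))
        elif format == "tiff_stack":
            import tifffile

            tifffile.imwrite(str(path), data8, photometric="minisblack")
        else:
            raise FormatError(f"unknown format {format!r}")
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc


def load_labelmap(path: str | os.PathLike, format: str | None = None) -> LabelMap:
    """Read a label map written by :func:`save_labelmap`."""
    vol = load_volume(path, format)
    return LabelMap(np.rint(vol.data).astype(np.uint8), spacing=vol.spacing)


def save_volume(volume: Volume, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a scalar volume (float32) as NIfTI or multi-page TIFF."""
    path = Path(path)
    if format is None:
        if path.name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif path.suffix.lower() in (".tif", ".tiff"):
            format = "tiff_stack"
        else:
            raise FormatError(f"cannot guess format of {path}")
    data = np.asarray(volume.data, dtype=np.float32)
    try:
        if format == "nifti":
            import nibabel as nib

            arr = np.transpose(data, (2, 1, 0))
            s = volume.spacing
            affine = np.diag([s[2], s[1], s[0], 1.0])
            img = nib.Nifti1Image(arr, affine)
            img.header.set_zooms((s[2], s[1], s[0]))
            nib.save(img, str(path))
        elif format == "tiff_stack":
            import tifffile

            tifffile.imwrite(str(path), data, photometric="minisblack")
        else:
            raise FormatError(f"unknown format {format!r}")
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc
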