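"""Reading and writing CT series and 2D radiographic images.

The internal conventions used throughout the package are fixed here:

* A :class:`CTVolume` stores Hounsfield units (HU) in a 3D array indexed
  ``(z, y, x)`` where ``z`` runs superior-to-inferior (slice 0 is the most
  superior slice), ``y`` is the in-plane row (anterior-to-posterior for a
  standard supine axial acquisition) and ``x`` the in-plane column.
* Physical spacing is ``(dz, dy, dx)`` in millimetres.  The inter-slice
  spacing ``dz`` is derived from consecutive slice *positions*, never from
  the slice-thickness tag, because thickness and reconstruction increment
  differ in overlapping reconstructions.
* All 2D images handed to the registration stage live in ``[0, 1]``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

log = logging.getLogger(__name__)

HU_MIN = -1100
HU_MAX = 32767

_CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"  # CT Image Storage


@dataclass
class CTVolume:
    """A 3D grid of Hounsfield-unit scalars with physical spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        HU scalars, slice 0 most superior.
    spacing : tuple of float
        ``(dz, dy, dx)`` in mm, all strictly positive.
    superior_first : bool
        Slice ordering flag; the loaders always normalise to ``True``.
    source_meta : dict
        Free-form provenance (series UID, file names, ...).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    superior_first: bool = True
    source_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("CTVolume requires a 3D array")
        if any(d < 2 for d in self.values.shape):
            raise ValueError(f"grid dimensions must be >= 2, got {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be three strictly positive numbers, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")
        vmin, vmax = float(self.values.min()), float(self.values.max())
        if vmin < HU_MIN or vmax > HU_MAX:
            raise ValueError(f"HU range [{vmin}, {vmax}] outside [{HU_MIN}, {HU_MAX}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class Image2D:
    """A 2D scalar image, indexed (row, column)."""

    values: np.ndarray
    pixel_spacing: tuple[float, float] | None = None  # (dr, dc) mm, or None if unknown
    intensity_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Image2D requires a 2D array")
        if any(d < 2 for d in self.values.shape):
            raise ValueError(f"image dimensions must be >= 2x2, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if self.intensity_range is None:
            self.intensity_range = (float(self.values.min()), float(self.values.max()))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def _read_slice(path: Path) -> Dataset:
    return pydicom.dcmread(str(path))


def load_ct_series(directory: str | os.PathLike) -> CTVolume:
    """Load a directory of single-frame axial DICOM slices into a :class:`CTVolume`.

    Slices are sorted by physical position along the patient z axis
    (superior first); the rescale slope/intercept is applied so stored
    values become true HU; ``dz`` is the median of consecutive position
    differences.

    Raises
    ------
    ValueError
        On mixed series, inconsistent slice dimensions, missing position
        tags (the message names the offending file) or non-uniform
        inter-slice gaps beyond 1%.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ".ima", ""})
    if not paths:
        paths = sorted(p for p in directory.iterdir() if p.is_file())
    slices: list[tuple[float, Dataset, Path]] = []
    for p in paths:
        try:
            ds = _read_slice(p)
        except Exception:
            continue  # non-DICOM clutter is ignored
        if "ImagePositionPatient" not in ds:
            raise ValueError(f"slice {p.name} lacks ImagePositionPatient; cannot sort by position")
        slices.append((float(ds.ImagePositionPatient[2]), ds, p))
    if len(slices) < 2:
        raise ValueError(f"need at least 2 DICOM slices in {directory}")

    uids = {s[1].get("SeriesInstanceUID", "") for s in slices}
    if len(uids) > 1:
        raise ValueError(f"directory mixes {len(uids)} series: {sorted(uids)}")
    shapes = {(int(s[1].Rows), int(s[1].Columns)) for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent slice dimensions: {sorted(shapes)}")

    # superior first: descending patient z
    slices.sort(key=lambda t: -t[0])
    zs = np.array([t[0] for t in slices])
    gaps = -np.diff(zs)
    if np.any(gaps <= 0):
        raise ValueError("duplicate or non-monotone slice positions")
    dz = float(np.median(gaps))
    if np.max(np.abs(gaps - dz)) > 0.01 * dz:
        raise ValueError(f"non-uniform inter-slice gaps (median {dz:.4f} mm, spread {gaps.min():.4f}-{gaps.max():.4f})")

    planes = []
    for _, ds, _p in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(slope * arr + intercept)
    vol = np.stack(planes, axis=0)

    ps = slices[0][1].PixelSpacing  # (row, col) per the standard
    dy, dx = float(ps[0]), float(ps[1])
    meta = {
        "series_uid": slices[0][1].get("SeriesInstanceUID", ""),
        "n_files": len(slices),
        "directory": str(directory),
    }
    return CTVolume(vol, (dz, dy, dx), superior_first=True, source_meta=meta)


def save_ct_series(vol: CTVolume, directory: str | os.PathLike) -> int:
    """Write one 16-bit DICOM CT file per slice; returns the slice count.

    Integer HU survive a save/load round trip exactly; spacing to 1e-6 mm.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    dz, dy, dx = vol.spacing
    nz = vol.shape[0]
    stored = np.round(vol.values).astype(np.int16)
    for i in range(nz):
        ds = Dataset()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = _CT_SOP_CLASS
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.SOPClassUID = _CT_SOP_CLASS
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = "synthetic^phantom"
        ds.PatientID = "SYN"
        ds.Rows, ds.Columns = int(vol.shape[1]), int(vol.shape[2])
        ds.PixelSpacing = [f"{dy:.6f}", f"{dx:.6f}"]
        ds.SliceThickness = f"{dz:.6f}"
        ds.InstanceNumber = i + 1
        # superior-first: slice i sits at patient z = -i*dz
        ds.ImagePositionPatient = ["0", "0", f"{-i * dz:.6f}"]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "0"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored[i].tobytes()
        ds.save_as(str(directory / f"slice_{i:04d}.dcm"), enforce_file_format=True)
    return nz


def _normalize_minmax(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        log.warning("constant image: degenerate intensity range maps to all zeros")
        return np.zeros_like(arr, dtype=float)
    return (arr - lo) / (hi - lo)


def load_reference_image(path: str | os.PathLike) -> Image2D:
    """Load a reference X-ray (single-frame DICOM CR/DX, or 8/16-bit grayscale raster).

    Output values are min-max scaled to ``[0, 1]``.  MONOCHROME1 DICOM data
    are inverted so that bone reads bright, matching the DRR convention.
    """
    path = Path(path)
    spacing: tuple[float, float] | None = None
    try:
        ds = pydicom.dcmread(str(path))
        is_dicom = True
    except Exception:
        is_dicom = False
    if is_dicom:
        nframes = int(getattr(ds, "NumberOfFrames", 1))
        if nframes > 1:
            raise ValueError(f"multi-frame DICOM not supported ({nframes} frames)")
        if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
            raise ValueError("color DICOM images are not supported")
        arr = ds.pixel_array.astype(np.float64)
        if str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2")) == "MONOCHROME1":
            arr = arr.max() - arr
        if "PixelSpacing" in ds:
            spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        elif "ImagerPixelSpacing" in ds:
            spacing = (float(ds.ImagerPixelSpacing[0]), float(ds.ImagerPixelSpacing[1]))
    else:
        import imageio.v2 as iio

        arr = np.asarray(iio.imread(str(path)))
        if arr.ndim == 3:
            raise ValueError("color raster images are not supported; provide grayscale")
        arr = arr.astype(np.float64)
    return Image2D(_normalize_minmax(arr), pixel_spacing=spacing)


def save_image(img: Image2D, path: str | os.PathLike) -> None:
    """Write a 16-bit grayscale PNG/TIFF.

    Values are clipped to ``[0, 1]`` and quantized uniformly onto
    ``0..65535``, so relative intensities are preserved up to a single
    affine map and the quantization error is bounded by ``1/65535``.
    """
    import imageio.v2 as iio

    arr = np.clip(img.values, 0.0, 1.0)
    q = np.round(arr * 65535.0).astype(np.uint16)
    iio.imwrite(str(path), q)
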