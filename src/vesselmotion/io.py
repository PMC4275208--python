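"""Reading and writing dynamic CT series and ROI masks.

A monitor-phase acquisition is a time-ordered stack of 2-D axial frames at a
fixed slice position.  Intensities are Hounsfield units (HU) throughout; DICOM
rescale slope/intercept is applied at read time.  The in-plane coordinate
convention is 0-based ``(row, col)`` with the row axis mapped to the
anterior-posterior (AP) direction and the column axis to the lateral (LAT)
direction of an axial frame; displacement sign is positive toward increasing
index.

Supported on-disk dialects:

* DICOM series directory (one single-frame instance per time point),
* NIfTI with time as the last axis,
* 16-bit grayscale TIFF/PNG stacks with a JSON sidecar.  Unsigned 16-bit
  storage cannot hold negative HU, so stacks store ``HU + 1024``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

#: Offset added to HU before writing unsigned 16-bit image stacks.
STACK_HU_OFFSET = 1024

__all__ = [
    "ImageSeries",
    "RoiMask",
    "WindowSettings",
    "FormatError",
    "ConfigurationError",
    "read_series",
    "write_series",
    "apply_window",
    "read_mask",
    "write_mask",
]


class FormatError(ValueError):
    """Input data violates the expected file-format contract."""


class ConfigurationError(ValueError):
    """Required acquisition metadata is missing and no override was given."""


@dataclass(frozen=True)
class WindowSettings:
    """CT display window: ``level`` is the centre, ``width`` the full range (HU).

    The standard abdominal soft-tissue window is level 40 HU, width 350 HU.
    """

    level: float = 40.0
    width: float = 350.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"window width must be > 0, got {self.width}")


@dataclass(frozen=True)
class ImageSeries:
    """Time-ordered 2-D frames with physical spacing and timing metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``, intensities in HU.
    pixel_spacing
        Isotropic in-plane spacing, mm/pixel.
    interscan_time
        Seconds between consecutive frames.
    slice_thickness
        Slice thickness in mm (metadata only; no through-plane computation).
    acquisition_times
        Optional per-frame seconds-from-start; defaults to
        ``interscan_time * arange(n_frames)``.
    """

    frames: np.ndarray
    pixel_spacing: float
    interscan_time: float
    slice_thickness: float = 5.0
    acquisition_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise FormatError(
                f"frames must be a (n_frames, rows, cols) array, got shape {frames.shape}"
            )
        if self.pixel_spacing <= 0:
            raise ValueError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        if self.interscan_time <= 0:
            raise ValueError(f"interscan_time must be > 0, got {self.interscan_time}")
        object.__setattr__(self, "frames", frames)
        if self.acquisition_times is not None:
            times = np.asarray(self.acquisition_times, dtype=float)
            if times.shape != (frames.shape[0],):
                raise ValueError("acquisition_times must have one entry per frame")
            object.__setattr__(self, "acquisition_times", times)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def times(self) -> np.ndarray:
        """Seconds from the first frame, per frame."""
        if self.acquisition_times is not None:
            return self.acquisition_times - self.acquisition_times[0]
        return self.interscan_time * np.arange(self.n_frames, dtype=float)

    def frame(self, index: int) -> np.ndarray:
        return self.frames[index]


@dataclass(frozen=True)
class RoiMask:
    """Binary artery delineation on one frame, as a set of pixel coordinates.

    ``pixels`` is an ``(n, 2)`` integer array of ``(row, col)`` coordinates.
    """

    pixels: np.ndarray
    frame_index: int = 0
    frame_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        pixels = np.atleast_2d(np.asarray(self.pixels, dtype=np.int64))
        if pixels.size == 0:
            pixels = pixels.reshape(0, 2)
        if pixels.shape[1] != 2:
            raise ValueError("pixels must be an (n, 2) array of (row, col)")
        # canonical order so set semantics survive round trips
        if pixels.shape[0]:
            order = np.lexsort((pixels[:, 1], pixels[:, 0]))
            pixels = np.unique(pixels[order], axis=0)
        object.__setattr__(self, "pixels", pixels)
        if self.frame_shape is not None:
            r, c = self.frame_shape
            if pixels.shape[0] and (
                pixels[:, 0].min() < 0
                or pixels[:, 1].min() < 0
                or pixels[:, 0].max() >= r
                or pixels[:, 1].max() >= c
            ):
                raise FormatError("mask contains pixels outside the frame bounds")

    def __len__(self) -> int:
        return self.pixels.shape[0]

    @property
    def is_empty(self) -> bool:
        return len(self) == 0

    def area_mm2(self, pixel_spacing: float) -> float:
        """ROI area: pixel count times the squared in-plane spacing."""
        return len(self) * pixel_spacing**2

    def to_array(self, frame_shape: tuple[int, int] | None = None) -> np.ndarray:
        shape = frame_shape or self.frame_shape
        if shape is None:
            raise ValueError("frame_shape required to rasterize a mask")
        arr = np.zeros(shape, dtype=bool)
        if len(self):
            arr[self.pixels[:, 0], self.pixels[:, 1]] = True
        return arr

    @classmethod
    def from_array(cls, mask: np.ndarray, frame_index: int = 0) -> "RoiMask":
        mask = np.asarray(mask)
        rows, cols = np.nonzero(mask)
        return cls(
            pixels=np.column_stack([rows, cols]),
            frame_index=frame_index,
            frame_shape=mask.shape,  # type: ignore[arg-type]
        )

    def translate(self, offset: tuple[int, int], frame_shape: tuple[int, int] | None = None) -> "RoiMask":
        """Shift the mask by an integer ``(drow, dcol)``, clipping at bounds."""
        shape = frame_shape or self.frame_shape
        moved = self.pixels + np.asarray(offset, dtype=np.int64)
        if shape is not None:
            keep = (
                (moved[:, 0] >= 0)
                & (moved[:, 1] >= 0)
                & (moved[:, 0] < shape[0])
                & (moved[:, 1] < shape[1])
            )
            moved = moved[keep]
        return RoiMask(pixels=moved, frame_index=self.frame_index, frame_shape=shape)


# ---------------------------------------------------------------------------
# windowing


def apply_window(series: ImageSeries, w: WindowSettings) -> ImageSeries:
    """Map HU linearly from ``[level - width/2, level + width/2]`` to [0, 1].

    Values outside the window are clamped.  The mapping is monotone
    non-decreasing in the input HU.
    """
    lo = w.level - w.width / 2.0
    mapped = np.clip((series.frames - lo) / w.width, 0.0, 1.0)
    return replace(series, frames=mapped)


# ---------------------------------------------------------------------------
# series I/O


def read_series(
    path: str | Path,
    format: str | None = None,
    *,
    pixel_spacing: float | None = None,
    interscan_time: float | None = None,
    slice_thickness: float | None = None,
) -> ImageSeries:
    """Read a dynamic series from disk.

    ``format`` is one of ``{"dicom-dir", "nifti", "image-stack"}``; when
    omitted it is inferred from the path.  Keyword overrides supply metadata
    missing from the files (mandatory for bare image stacks without a
    sidecar).
    """
    path = Path(path)
    if format is None:
        format = _infer_format(path)
    if format == "dicom-dir":
        series = _read_dicom_dir(path)
    elif format == "nifti":
        series = _read_nifti(path, pixel_spacing, interscan_time)
    elif format == "image-stack":
        series = _read_stack(path, pixel_spacing, interscan_time, slice_thickness)
    else:
        raise ValueError(f"unknown series format {format!r}")
    overrides = {}
    if pixel_spacing is not None:
        overrides["pixel_spacing"] = pixel_spacing
    if interscan_time is not None:
        overrides["interscan_time"] = interscan_time
    if slice_thickness is not None:
        overrides["slice_thickness"] = slice_thickness
    return replace(series, **overrides) if overrides else series


def write_series(series: ImageSeries, path: str | Path, format: str = "image-stack") -> None:
    """Write a series to disk (``image-stack`` or ``nifti``)."""
    path = Path(path)
    if format == "image-stack":
        _write_stack(series, path)
    elif format == "nifti":
        _write_nifti(series, path)
    else:
        raise ValueError(f"cannot write series format {format!r}")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if path.is_dir():
        if any(path.glob("*.dcm")):
            return "dicom-dir"
        return "image-stack"
    raise ValueError(f"cannot infer series format from {path}")


def _read_dicom_dir(path: Path) -> ImageSeries:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FormatError(f"no DICOM instances in {path}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    def sort_key(ds):
        t = getattr(ds, "AcquisitionTime", None)
        if t not in (None, ""):
            return (0, float(t))
        return (1, int(getattr(ds, "InstanceNumber", 0)))

    datasets.sort(key=sort_key)
    frames, times = [], []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        frames.append(arr * slope + intercept)
        t = getattr(ds, "AcquisitionTime", None)
        times.append(float(t) if t not in (None, "") else None)
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"heterogeneous frame dimensions: {sorted(shapes)}")
    ds0 = datasets[0]
    spacing = getattr(ds0, "PixelSpacing", None)
    if spacing is None:
        raise ConfigurationError("DICOM series lacks PixelSpacing")
    sr, sc = float(spacing[0]), float(spacing[1])
    if abs(sr - sc) > 1e-9:
        raise FormatError(f"anisotropic in-plane spacing ({sr}, {sc}) not supported")
    acq = None
    interscan = None
    if all(t is not None for t in times) and len(times) > 1:
        acq = np.asarray(times, dtype=float)
        steps = np.diff(acq)
        if np.any(steps > 0):
            interscan = float(np.mean(steps[steps > 0]))
    if interscan is None:
        interscan = 3.0
    return ImageSeries(
        frames=np.stack(frames),
        pixel_spacing=sr,
        interscan_time=interscan,
        slice_thickness=float(getattr(ds0, "SliceThickness", 5.0)),
        acquisition_times=acq,
    )


def _read_nifti(path: Path, pixel_spacing, interscan_time) -> ImageSeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise FormatError(f"expected 3-D NIfTI (rows, cols, time), got shape {data.shape}")
    zooms = img.header.get_zooms()
    sr, sc = float(zooms[0]), float(zooms[1])
    if abs(sr - sc) > 1e-9:
        raise FormatError(f"anisotropic in-plane spacing ({sr}, {sc}) not supported")
    spacing = pixel_spacing if pixel_spacing is not None else sr
    dt = interscan_time if interscan_time is not None else float(zooms[2])
    if dt <= 0:
        raise ConfigurationError("interscan time missing from NIfTI header; pass it explicitly")
    frames = np.moveaxis(data, -1, 0)
    return ImageSeries(frames=frames, pixel_spacing=spacing, interscan_time=dt)


def _write_nifti(series: ImageSeries, path: Path) -> None:
    import nibabel as nib

    data = np.moveaxis(series.frames, 0, -1)
    affine = np.diag([series.pixel_spacing, series.pixel_spacing, 1.0, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms((series.pixel_spacing, series.pixel_spacing, series.interscan_time))
    nib.save(img, str(path))


_SIDECAR = "series.json"


def _write_stack(series: ImageSeries, path: Path) -> None:
    import tifffile

    path.mkdir(parents=True, exist_ok=True)
    stored = np.round(series.frames + STACK_HU_OFFSET)
    if stored.min() < 0 or stored.max() > np.iinfo(np.uint16).max:
        raise FormatError("HU values out of range for 16-bit offset storage")
    for i, frame in enumerate(stored.astype(np.uint16)):
        tifffile.imwrite(str(path / f"frame_{i:04d}.tif"), frame)
    meta = {
        "pixel_spacing_mm": series.pixel_spacing,
        "interscan_time_s": series.interscan_time,
        "slice_thickness_mm": series.slice_thickness,
        "hu_offset": STACK_HU_OFFSET,
        "n_frames": series.n_frames,
    }
    if series.acquisition_times is not None:
        meta["acquisition_times_s"] = list(map(float, series.acquisition_times))
    (path / _SIDECAR).write_text(json.dumps(meta, indent=2))


def _read_stack(path: Path, pixel_spacing, interscan_time, slice_thickness) -> ImageSeries:
    import tifffile
    from PIL import Image

    meta = {}
    sidecar = path / _SIDECAR
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    spacing = pixel_spacing if pixel_spacing is not None else meta.get("pixel_spacing_mm")
    dt = interscan_time if interscan_time is not None else meta.get("interscan_time_s")
    if spacing is None:
        raise ConfigurationError("pixel spacing missing: no sidecar and no override")
    if dt is None:
        raise ConfigurationError("interscan time missing: no sidecar and no override")
    thickness = (
        slice_thickness if slice_thickness is not None else meta.get("slice_thickness_mm", 5.0)
    )
    offset = meta.get("hu_offset", STACK_HU_OFFSET)
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")
    )
    if not files:
        raise FormatError(f"no image frames in {path}")
    frames = []
    for f in files:
        if f.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(str(f))
        else:
            arr = np.asarray(Image.open(f))
        frames.append(arr.astype(float) - offset)
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"heterogeneous frame dimensions: {sorted(shapes)}")
    acq = meta.get("acquisition_times_s")
    return ImageSeries(
        frames=np.stack(frames),
        pixel_spacing=float(spacing),
        interscan_time=float(dt),
        slice_thickness=float(thickness),
        acquisition_times=np.asarray(acq, dtype=float) if acq is not None else None,
    )


# ---------------------------------------------------------------------------
# mask I/O


def write_mask(mask: RoiMask, path: str | Path, frame_shape: tuple[int, int] | None = None) -> None:
    """Write a mask as 8-bit PNG (0/255) or NIfTI labels, by extension."""
    from PIL import Image

    path = Path(path)
    arr = mask.to_array(frame_shape)
    if path.name.lower().endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(arr.astype(np.uint8), np.eye(4)), str(path))
    else:
        Image.fromarray(np.where(arr, 255, 0).astype(np.uint8)).save(path)


def read_mask(
    path: str | Path,
    frame_index: int = 0,
    frame_shape: tuple[int, int] | None = None,
) -> RoiMask:
    """Read a binary mask; nonzero pixels are inside the ROI."""
    path = Path(path)
    if path.name.lower().endswith((".nii", ".nii.gz")):
        import nibabel as nib

        arr = np.asanyarray(nib.load(str(path)).dataobj)
        if arr.ndim == 3 and arr.shape[-1] == 1:
            arr = arr[..., 0]
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    if frame_shape is not None and arr.shape != tuple(frame_shape):
        raise FormatError(
            f"mask shape {arr.shape} does not match frame shape {tuple(frame_shape)}"
        )
    mask = RoiMask.from_array(arr != 0, frame_index=frame_index)
    if mask.is_empty:
        warnings.warn(f"mask read from {path} is empty", stacklevel=2)
    return mask
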