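"""Barycenter-based vessel tracking, bolus-trigger monitoring, dose arithmetic.

The vessel section's barycenter is the arithmetic mean of the ROI pixel
coordinates,

.. math:: C(a, b) = \\left(\\frac{1}{n}\\sum_i x_i, \\frac{1}{n}\\sum_i y_i\\right),

and the frame-to-frame displacement is the difference of successive
barycenters, :math:`\\Delta v = C_2 - C_1 = (a_2 - a_1,\\; b_2 - b_1)`.
Positions are kept at sub-pixel precision; rounding happens only when an
integer mask must be translated during motion-corrected tracking.

Bolus tracking mimics the Smart Prep monitor phase: the mean HU inside the
ROI is measured each frame and the diagnostic scan is triggered on the first
frame whose mean reaches the enhancement threshold (130 HU in the emulated
protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .flow import FlowParams, horn_schunck, roi_displacement
from .io import ImageSeries, RoiMask

__all__ = [
    "Trajectory",
    "EnhancementCurve",
    "barycenter",
    "displacement",
    "track_manual",
    "roi_mean_hu",
    "bolus_trigger",
    "track_corrected",
    "dose_arithmetic",
]

#: Smart Prep enhancement threshold (HU) that starts the diagnostic scan phase.
DEFAULT_TRIGGER_HU = 130.0


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed barycenter positions and frame-to-frame displacements.

    ``barycenters`` has shape ``(n_frames, 2)`` as sub-pixel ``(row, col)``
    positions; ``displacements`` has shape ``(n_frames - 1, 2)`` and each row
    equals the difference of its flanking barycenters exactly.
    """

    barycenters: np.ndarray
    units_state: str = "pixels"

    def __post_init__(self) -> None:
        b = np.asarray(self.barycenters, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2:
            raise ValueError("barycenters must be an (n, 2) array")
        if self.units_state not in ("pixels", "mm"):
            raise ValueError(f"unknown units_state {self.units_state!r}")
        object.__setattr__(self, "barycenters", b)

    @property
    def displacements(self) -> np.ndarray:
        return np.diff(self.barycenters, axis=0)

    @property
    def step_magnitudes(self) -> np.ndarray:
        """Per-step Euclidean displacement magnitudes (the reported movement)."""
        d = self.displacements
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def path_length(self) -> float:
        """Cumulative path length (sum of per-step magnitudes)."""
        return float(self.step_magnitudes.sum())

    def to_mm(self, pixel_spacing: float) -> "Trajectory":
        if self.units_state != "pixels":
            raise ValueError(f"expected pixel units, got {self.units_state!r}")
        return Trajectory(self.barycenters * pixel_spacing, units_state="mm")

    def __len__(self) -> int:
        return self.barycenters.shape[0]


@dataclass(frozen=True)
class EnhancementCurve:
    """Per-frame ROI mean enhancement with the bolus-trigger decision.

    ``trigger_index`` is the first (0-based) frame whose ROI mean reaches the
    threshold, or ``None`` if the threshold is never reached.
    """

    times: np.ndarray
    roi_mean_hu: np.ndarray
    threshold: float = DEFAULT_TRIGGER_HU

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.roi_mean_hu, dtype=float)
        if t.shape != h.shape or t.ndim != 1:
            raise ValueError("times and roi_mean_hu must be 1-D of equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "roi_mean_hu", h)

    @property
    def trigger_index(self) -> int | None:
        return bolus_trigger(self.roi_mean_hu, self.threshold)

    @property
    def trigger_time(self) -> float | None:
        idx = self.trigger_index
        return None if idx is None else float(self.times[idx])


def barycenter(roi: RoiMask) -> tuple[float, float]:
    """Arithmetic mean of the ROI pixel coordinates, sub-pixel ``(row, col)``."""
    if roi.is_empty:
        raise ValueError("cannot compute the barycenter of an empty ROI")
    centre = roi.pixels.mean(axis=0)
    return float(centre[0]), float(centre[1])


def displacement(
    c1: Sequence[float], c2: Sequence[float]
) -> tuple[tuple[float, float], float]:
    """Componentwise difference ``c2 - c1`` and its Euclidean magnitude."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if not (np.all(np.isfinite(c1)) and np.all(np.isfinite(c2))):
        raise ValueError("positions must be finite")
    delta = c2 - c1
    return (float(delta[0]), float(delta[1])), float(np.hypot(delta[0], delta[1]))


def track_manual(series: ImageSeries, masks: Sequence[RoiMask]) -> Trajectory:
    """Barycenter trajectory from one manual delineation per frame."""
    if len(masks) != series.n_frames:
        raise ValueError(
            f"need one mask per frame: {series.n_frames} frames, {len(masks)} masks"
        )
    centres = []
    for i, mask in enumerate(masks):
        if mask is None or mask.is_empty:
            raise ValueError(f"missing or empty mask for frame {i}")
        centres.append(barycenter(mask))
    return Trajectory(np.asarray(centres), units_state="pixels")


def roi_mean_hu(frame: np.ndarray, roi: RoiMask) -> float:
    """Arithmetic mean HU over the ROI pixels of one frame."""
    if roi.is_empty:
        raise ValueError("cannot average over an empty ROI")
    frame = np.asarray(frame, dtype=float)
    rows, cols = roi.pixels[:, 0], roi.pixels[:, 1]
    if rows.max() >= frame.shape[0] or cols.max() >= frame.shape[1]:
        raise ValueError("ROI extends beyond the frame bounds")
    return float(frame[rows, cols].mean())


def bolus_trigger(
    roi_means: Sequence[float], threshold: float = DEFAULT_TRIGGER_HU
) -> int | None:
    """First 0-based index whose ROI mean reaches the threshold, else ``None``.

    The comparison is ``>=``: reaching the threshold triggers.
    """
    means = np.asarray(roi_means, dtype=float)
    if means.size == 0:
        raise ValueError("empty enhancement sequence")
    hits = np.nonzero(means >= threshold)[0]
    return int(hits[0]) if hits.size else None


def _round_toward_zero(x: float) -> int:
    """Nearest integer, ties toward zero (so +0.5 -> 0, -0.5 -> 0)."""
    return int(np.sign(x) * np.ceil(abs(x) - 0.5))


def track_corrected(
    series: ImageSeries,
    initial_roi: RoiMask,
    flow_params: FlowParams | None = None,
    reduction: str = "norm-of-mean",
) -> tuple[list[RoiMask], Trajectory]:
    """Propagate an initial ROI through the series using optical flow.

    For each consecutive frame pair the dense motion field is estimated, its
    mean displacement over the current ROI is rounded to the nearest integer
    offset (ties toward zero), and the ROI is translated by that offset
    (clipped at the frame bounds).  Returns the per-frame masks and the
    barycenter trajectory they induce.  Hard integer shifting keeps the ROI
    pixel count — and hence its area — invariant while it stays in bounds.
    """
    if series.n_frames < 2:
        raise ValueError("motion-corrected tracking needs at least 2 frames")
    if initial_roi.is_empty:
        raise ValueError("initial ROI is empty")
    flow_params = flow_params or FlowParams()
    shape = series.frame_shape
    masks = [RoiMask(initial_roi.pixels, frame_index=0, frame_shape=shape)]
    for t in range(series.n_frames - 1):
        mvf = horn_schunck(
            series.frame(t), series.frame(t + 1), flow_params, source_pair=(t, t + 1)
        )
        ap, lat, _ = roi_displacement(mvf, masks[-1], reduction=reduction)
        offset = (_round_toward_zero(ap), _round_toward_zero(lat))
        moved = masks[-1].translate(offset, frame_shape=shape)
        if moved.is_empty:
            raise ValueError(f"ROI fully pushed out of bounds at frame {t + 1}")
        masks.append(RoiMask(moved.pixels, frame_index=t + 1, frame_shape=shape))
    centres = np.asarray([barycenter(m) for m in masks])
    return masks, Trajectory(centres, units_state="pixels")


def dose_arithmetic(
    tube_current_ma: float,
    rotation_time_s: float,
    ctdi_per_scan_mgy: float,
    n_scans: int,
) -> tuple[float, float]:
    """Per-scan tube current-time product (mAs) and cumulative CTDIvol (mGy).

    The emulated monitor-phase protocol runs 40 mA at 0.6 s rotation
    (24 mAs, 2.81 mGy CTDIvol per scan); the cumulative dose is the per-scan
    CTDIvol times the number of scans.
    """
    if min(tube_current_ma, rotation_time_s, ctdi_per_scan_mgy, n_scans) <= 0:
        raise ValueError("all dose inputs must be > 0")
    return tube_current_ma * rotation_time_s, ctdi_per_scan_mgy * n_scans


def enhancement_curve(
    series: ImageSeries,
    masks: Sequence[RoiMask] | RoiMask,
    threshold: float = DEFAULT_TRIGGER_HU,
) -> EnhancementCurve:
    """ROI mean enhancement per frame, for a fixed ROI or per-frame masks."""
    if isinstance(masks, RoiMask):
        masks = [masks] * series.n_frames
    if len(masks) != series.n_frames:
        raise ValueError("need one mask per frame")
    means = [roi_mean_hu(series.frame(i), m) for i, m in enumerate(masks)]
    return EnhancementCurve(times=series.times, roi_mean_hu=np.asarray(means), threshold=threshold)
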