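"""Synthetic monitor-phase CT phantoms with known ground-truth motion.

Each phantom is a time series of 2-D frames containing a bright
quasi-circular vessel section on a uniform soft-tissue background.  The
vessel follows a configured trajectory (static, linear drift, sinusoidal
respiration, or a single-step jump emulating gross patient movement), its
intensity follows a logistic contrast-enhancement ramp emulating an
intravenous injection at 3-3.5 ml/s, and additive Gaussian noise emulates
quantum noise.  Defaults mirror the emulated monitor-phase protocol:
0.82 mm/pixel in-plane spacing, 3 s interscan time, a vessel area near
600 mm^2, and an enhancement curve crossing the 130 HU trigger threshold
mid-series.

The disc is rendered with 4x4 supersampled coverage anti-aliasing so
sub-pixel motion is expressible; the ground-truth mask per frame is the
half-coverage support (pixels at least half inside the disc).  The ground
truth (exact trajectory, per-frame masks, noise-free enhancement) is what a
radiologist's ideal manual delineation would produce, and is returned
alongside the frames so every pipeline stage can be validated without
patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .io import ImageSeries, RoiMask

__all__ = [
    "StaticTrajectory",
    "LinearDrift",
    "SinusoidalTrajectory",
    "StepJump",
    "EnhancementModel",
    "PhantomConfig",
    "PhantomTruth",
    "generate",
    "default_suite",
]

_SUPERSAMPLE = 4  # sub-pixel samples per axis for coverage anti-aliasing


@dataclass(frozen=True)
class StaticTrajectory:
    """Vessel fixed at the initial position."""

    def offset_px(self, frame: int, time_s: float, spacing: float) -> tuple[float, float]:
        return (0.0, 0.0)


@dataclass(frozen=True)
class LinearDrift:
    """Constant drift of ``(drow, dcol)`` pixels per frame."""

    drow_px: float
    dcol_px: float = 0.0

    def offset_px(self, frame: int, time_s: float, spacing: float) -> tuple[float, float]:
        return (self.drow_px * frame, self.dcol_px * frame)


@dataclass(frozen=True)
class SinusoidalTrajectory:
    """Respiratory oscillation dominated by one axis.

    Amplitudes are in mm (AP along rows, LAT along columns), the period in
    seconds; the offset at time t is ``amp * sin(2 pi t / period + phase)``.
    """

    amplitude_ap_mm: float
    amplitude_lat_mm: float = 0.0
    period_s: float = 4.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_ap_mm < 0 or self.amplitude_lat_mm < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.period_s <= 0:
            raise ValueError("period must be > 0")

    def offset_px(self, frame: int, time_s: float, spacing: float) -> tuple[float, float]:
        s = np.sin(2 * np.pi * time_s / self.period_s + self.phase)
        return (self.amplitude_ap_mm * s / spacing, self.amplitude_lat_mm * s / spacing)


@dataclass(frozen=True)
class StepJump:
    """Static until ``jump_frame``, then offset by a fixed mm displacement.

    Emulates a single gross patient movement during the monitor phase.
    """

    jump_frame: int
    jump_ap_mm: float
    jump_lat_mm: float = 0.0

    def offset_px(self, frame: int, time_s: float, spacing: float) -> tuple[float, float]:
        if frame < self.jump_frame:
            return (0.0, 0.0)
        return (self.jump_ap_mm / spacing, self.jump_lat_mm / spacing)


Trajectory = Union[StaticTrajectory, LinearDrift, SinusoidalTrajectory, StepJump]


@dataclass(frozen=True)
class EnhancementModel:
    """Logistic contrast-enhancement ramp in HU.

    ``hu(t) = baseline + (plateau - baseline) / (1 + exp(-rate (t - onset)))``.
    A flat curve is expressed with ``plateau == baseline``.
    """

    baseline_hu: float = 45.0
    plateau_hu: float = 250.0
    onset_s: float = 10.0
    rate_per_s: float = 0.5

    def hu(self, time_s) -> np.ndarray:
        t = np.asarray(time_s, dtype=float)
        rise = 1.0 / (1.0 + np.exp(-self.rate_per_s * (t - self.onset_s)))
        return self.baseline_hu + (self.plateau_hu - self.baseline_hu) * rise


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of one synthetic monitor-phase acquisition."""

    frame_shape: tuple[int, int] = (96, 96)
    n_frames: int = 8
    pixel_spacing: float = 0.82
    interscan_time: float = 3.0
    vessel_radius_mm: float = 13.8
    vessel_center0: tuple[float, float] = (48.0, 48.0)
    trajectory: Trajectory = field(default_factory=StaticTrajectory)
    enhancement: EnhancementModel = field(default_factory=EnhancementModel)
    background_hu: float = -50.0
    psf_fwhm_mm: float = 1.6
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vessel_radius_mm <= 0:
            raise ValueError("vessel_radius_mm must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")

    @property
    def vessel_radius_px(self) -> float:
        return self.vessel_radius_mm / self.pixel_spacing

    def centers_px(self) -> np.ndarray:
        """Exact sub-pixel vessel centre per frame, shape (n_frames, 2)."""
        out = np.empty((self.n_frames, 2))
        for k in range(self.n_frames):
            t = k * self.interscan_time
            dr, dc = self.trajectory.offset_px(k, t, self.pixel_spacing)
            out[k] = (self.vessel_center0[0] + dr, self.vessel_center0[1] + dc)
        return out


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth paired with a generated phantom series."""

    trajectory_px: np.ndarray
    pixel_spacing: float
    masks: list[RoiMask]
    enhancement_true: np.ndarray

    @property
    def trajectory_mm(self) -> np.ndarray:
        return self.trajectory_px * self.pixel_spacing

    @property
    def displacement_px(self) -> np.ndarray:
        return np.diff(self.trajectory_px, axis=0)

    @property
    def displacement_mm(self) -> np.ndarray:
        return self.displacement_px * self.pixel_spacing

    @property
    def step_magnitudes_mm(self) -> np.ndarray:
        d = self.displacement_mm
        return np.hypot(d[:, 0], d[:, 1])


def _disc_coverage(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Fraction of each pixel covered by the disc, by 4x4 supersampling."""
    rows, cols = shape
    r0 = max(int(np.floor(center[0] - radius)) - 1, 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 2, rows)
    c0 = max(int(np.floor(center[1] - radius)) - 1, 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 2, cols)
    coverage = np.zeros(shape, dtype=float)
    if r0 >= r1 or c0 >= c1:
        return coverage
    sub = (np.arange(_SUPERSAMPLE) + 0.5) / _SUPERSAMPLE - 0.5
    rr = np.arange(r0, r1)[:, None] + sub[None, :]  # (nr, s)
    cc = np.arange(c0, c1)[:, None] + sub[None, :]
    dr2 = (rr - center[0]) ** 2  # (nr, s)
    dc2 = (cc - center[1]) ** 2
    inside = (dr2[:, None, :, None] + dc2[None, :, None, :]) <= radius**2
    coverage[r0:r1, c0:c1] = inside.mean(axis=(2, 3))
    return coverage


def generate(config: PhantomConfig) -> tuple[ImageSeries, PhantomTruth]:
    """Render the phantom and its ground truth.

    Each frame is background + anti-aliased disc at the current enhancement
    HU + Gaussian noise; identical seeds give bit-identical output.  The
    noise layer is the only seed-dependent part, so noise-free renders are
    identical across seeds.
    """
    centers = config.centers_px()
    radius = config.vessel_radius_px
    rows, cols = config.frame_shape
    for k, (r, c) in enumerate(centers):
        if r - radius < 0 or c - radius < 0 or r + radius > rows - 1 or c + radius > cols - 1:
            raise ValueError(f"vessel leaves the frame bounds at frame {k}")

    times = config.interscan_time * np.arange(config.n_frames)
    enh = config.enhancement.hu(times)
    clean = np.empty((config.n_frames,) + tuple(config.frame_shape))
    masks: list[RoiMask] = []
    enh_true = np.empty(config.n_frames)
    psf_sigma_px = config.psf_fwhm_mm / (2.354820045 * config.pixel_spacing)
    for k in range(config.n_frames):
        cov = _disc_coverage(config.frame_shape, tuple(centers[k]), radius)
        clean[k] = config.background_hu + cov * (enh[k] - config.background_hu)
        if psf_sigma_px > 0:
            # in-plane reconstruction point-spread of the scanner kernel
            from scipy.ndimage import gaussian_filter

            clean[k] = gaussian_filter(clean[k], psf_sigma_px, mode="nearest")
        mask = RoiMask.from_array(cov >= 0.5, frame_index=k)
        masks.append(mask)
        px = mask.pixels
        enh_true[k] = float(clean[k][px[:, 0], px[:, 1]].mean())

    frames = clean
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        frames = clean + rng.normal(0.0, config.noise_sd, size=clean.shape)

    series = ImageSeries(
        frames=frames,
        pixel_spacing=config.pixel_spacing,
        interscan_time=config.interscan_time,
    )
    truth = PhantomTruth(
        trajectory_px=centers,
        pixel_spacing=config.pixel_spacing,
        masks=masks,
        enhancement_true=enh_true,
    )
    return series, truth


def _suite_configs(base_seed: int = 0) -> dict[str, PhantomConfig]:
    """The fixed phantom suite: the study conditions for desk-scale runs.

    Covers static, sub-pixel drift, slow drift, mild and moderate
    respiration, a single-step extreme excursion, and a noisy variant.  Seeds
    are derived deterministically from ``base_seed``.
    """

    def seed(k: int) -> int:
        return (base_seed * 10007 + k) % 2**31

    mild = SinusoidalTrajectory(amplitude_ap_mm=1.5, amplitude_lat_mm=0.5, period_s=5.0)
    return {
        "static": PhantomConfig(trajectory=StaticTrajectory(), seed=seed(1)),
        "subpixel_drift": PhantomConfig(
            trajectory=LinearDrift(drow_px=0.3), seed=seed(2)
        ),
        "slow_drift": PhantomConfig(trajectory=LinearDrift(drow_px=1.0), seed=seed(3)),
        "mild_respiration": PhantomConfig(trajectory=mild, seed=seed(4)),
        "moderate_respiration": PhantomConfig(
            trajectory=SinusoidalTrajectory(
                amplitude_ap_mm=4.0, amplitude_lat_mm=1.5, period_s=4.0
            ),
            seed=seed(5),
        ),
        "extreme_excursion": PhantomConfig(
            trajectory=StepJump(jump_frame=4, jump_ap_mm=10.0),
            frame_shape=(112, 96),
            vessel_center0=(48.0, 48.0),
            seed=seed(6),
        ),
        "noisy": PhantomConfig(trajectory=mild, noise_sd=20.0, seed=seed(7)),
    }


def default_suite(base_seed: int = 0) -> dict[str, tuple[ImageSeries, PhantomTruth]]:
    """Generate the named fixture collection used throughout validation."""
    return {name: generate(cfg) for name, cfg in _suite_configs(base_seed).items()}


def bolus_demo_config(seed: int = 0) -> PhantomConfig:
    """Drift phantom demonstrating the bolus-tracking failure mode.

    A small vessel (radius 5 mm) drifts 1 px/frame, leaving the static
    frame-0 ROI long before the contrast bolus arrives (late logistic onset),
    so the fixed ROI never reaches the trigger threshold while a
    motion-corrected ROI keeps measuring the true enhancement.
    """
    return PhantomConfig(
        frame_shape=(96, 96),
        n_frames=28,
        vessel_radius_mm=5.0,
        vessel_center0=(20.0, 48.0),
        trajectory=LinearDrift(drow_px=1.0),
        enhancement=EnhancementModel(
            baseline_hu=45.0, plateau_hu=250.0, onset_s=45.0, rate_per_s=0.35
        ),
        noise_sd=0.0,
        seed=seed % 2**31,
    )
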