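"""Dense 2-D Horn–Schunck optical flow between consecutive CT frames.

The motion vector field (MVF) between frames :math:`f(t)` and :math:`f(t+1)`
is estimated by the classic variational method of Horn & Schunck (1981): the
brightness-constancy gradient constraint

.. math:: f_x u + f_y v + f_t = 0

is combined with a global smoothness penalty weighted by :math:`\\alpha`, and
solved with the Jacobi-style iteration

.. math::

    u^{(n+1)} = \\bar u^{(n)}
        - f_x \\frac{f_x \\bar u^{(n)} + f_y \\bar v^{(n)} + f_t}
                     {\\alpha^2 + f_x^2 + f_y^2}

(and symmetrically for :math:`v`), starting from the zero field.  Here
:math:`u` is the column (lateral, LAT) component and :math:`v` the row
(anterior-posterior, AP) component; the published workflow this implements
uses :math:`\\alpha = 5` on HU-scale intensities and 100 iterations.

The solver is single-resolution by construction: displacements well beyond
the linearisation range of the gradient constraint (more than a few pixels
for sharp structures) are systematically underestimated, a known limitation
of plain Horn–Schunck.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import convolve

__all__ = [
    "FlowParams",
    "MotionVectorField",
    "UnitsError",
    "horn_schunck",
    "total_movement",
    "to_physical",
    "to_velocity",
    "roi_displacement",
]


class UnitsError(ValueError):
    """A unit conversion was applied to a field in the wrong units state."""


# Horn & Schunck's weighted 8-neighbour local average: 4-neighbours 1/6,
# diagonals 1/12, centre excluded.
_HS_KERNEL = np.array(
    [
        [1 / 12, 1 / 6, 1 / 12],
        [1 / 6, 0.0, 1 / 6],
        [1 / 12, 1 / 6, 1 / 12],
    ]
)
_MEAN4_KERNEL = np.array(
    [
        [0.0, 0.25, 0.0],
        [0.25, 0.0, 0.25],
        [0.0, 0.25, 0.0],
    ]
)


@dataclass(frozen=True)
class FlowParams:
    """Horn–Schunck solver parameters.

    alpha
        Smoothness weight (dimensionless, balances against HU-scale
        gradients).  Default 5.
    n_iterations
        Fixed iteration count.  Default 100.
    averaging_kernel
        ``"horn-schunck"`` (4-neighbours 1/6, diagonals 1/12) or
        ``"mean4"`` (plain 4-neighbour mean).
    gradient_scheme
        ``"horn-schunck"`` (averaged forward differences over the 2x2x2
        space-time cube) or ``"central"`` (central spatial differences on the
        frame average, plain temporal difference).
    stop_tolerance
        Optional mean-absolute-update early-stop threshold in pixels; ``None``
        (default) always runs the full ``n_iterations``.
    """

    alpha: float = 5.0
    n_iterations: int = 100
    averaging_kernel: str = "horn-schunck"
    gradient_scheme: str = "horn-schunck"
    stop_tolerance: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if self.averaging_kernel not in ("horn-schunck", "mean4"):
            raise ValueError(f"unknown averaging_kernel {self.averaging_kernel!r}")
        if self.gradient_scheme not in ("horn-schunck", "central"):
            raise ValueError(f"unknown gradient_scheme {self.gradient_scheme!r}")


@dataclass(frozen=True)
class MotionVectorField:
    """Per-pixel AP/LAT displacement between two frames.

    ``ap`` is the row-direction component, ``lat`` the column-direction
    component.  ``units_state`` walks ``pixels -> mm -> mm_per_s`` through the
    declared conversions only.
    """

    ap: np.ndarray
    lat: np.ndarray
    units_state: str = "pixels"
    source_pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        ap = np.asarray(self.ap, dtype=float)
        lat = np.asarray(self.lat, dtype=float)
        if ap.shape != lat.shape or ap.ndim != 2:
            raise ValueError("ap and lat must be 2-D arrays of identical shape")
        if self.units_state not in ("pixels", "mm", "mm_per_s"):
            raise ValueError(f"unknown units_state {self.units_state!r}")
        object.__setattr__(self, "ap", ap)
        object.__setattr__(self, "lat", lat)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ap.shape  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        return total_movement(self)


def _gradients(f0: np.ndarray, f1: np.ndarray, scheme: str):
    """Spatial/temporal derivatives with edge replication.

    ``fy`` is the row derivative (AP axis), ``fx`` the column derivative
    (LAT axis), ``ft`` the temporal forward difference.
    """
    if scheme == "horn-schunck":
        # forward differences averaged over the 2x2x2 space-time cube,
        # edge-replicated so the output keeps the frame shape
        p0 = np.pad(f0, ((0, 1), (0, 1)), mode="edge")
        p1 = np.pad(f1, ((0, 1), (0, 1)), mode="edge")
        fx = 0.25 * (
            (p0[:-1, 1:] - p0[:-1, :-1])
            + (p0[1:, 1:] - p0[1:, :-1])
            + (p1[:-1, 1:] - p1[:-1, :-1])
            + (p1[1:, 1:] - p1[1:, :-1])
        )
        fy = 0.25 * (
            (p0[1:, :-1] - p0[:-1, :-1])
            + (p0[1:, 1:] - p0[:-1, 1:])
            + (p1[1:, :-1] - p1[:-1, :-1])
            + (p1[1:, 1:] - p1[:-1, 1:])
        )
        ft = 0.25 * (
            (p1[:-1, :-1] - p0[:-1, :-1])
            + (p1[1:, :-1] - p0[1:, :-1])
            + (p1[:-1, 1:] - p0[:-1, 1:])
            + (p1[1:, 1:] - p0[1:, 1:])
        )
    else:  # central
        mean = 0.5 * (f0 + f1)
        padded = np.pad(mean, 1, mode="edge")
        fx = 0.5 * (padded[1:-1, 2:] - padded[1:-1, :-2])
        fy = 0.5 * (padded[2:, 1:-1] - padded[:-2, 1:-1])
        ft = f1 - f0
    return fx, fy, ft


def horn_schunck(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    params: FlowParams | None = None,
    source_pair: tuple[int, int] | None = None,
) -> MotionVectorField:
    """Estimate the dense motion vector field from ``frame_t`` to ``frame_t1``.

    Returns displacements in pixels per frame interval.  Deterministic: the
    field is initialised to zero and updated exactly ``n_iterations`` times
    (unless an explicit ``stop_tolerance`` halts it earlier).
    """
    params = params or FlowParams()
    f0 = np.asarray(frame_t, dtype=float)
    f1 = np.asarray(frame_t1, dtype=float)
    if f0.shape != f1.shape:
        raise ValueError(f"frame shapes differ: {f0.shape} vs {f1.shape}")
    if f0.ndim != 2 or min(f0.shape) < 3:
        raise ValueError(f"frames must be 2-D and at least 3x3, got {f0.shape}")
    if not (np.all(np.isfinite(f0)) and np.all(np.isfinite(f1))):
        raise ValueError("frames contain non-finite pixels")

    fx, fy, ft = _gradients(f0, f1, params.gradient_scheme)
    denom = params.alpha**2 + fx**2 + fy**2
    kernel = _HS_KERNEL if params.averaging_kernel == "horn-schunck" else _MEAN4_KERNEL

    u = np.zeros_like(f0)  # LAT (column) component
    v = np.zeros_like(f0)  # AP (row) component
    for _ in range(params.n_iterations):
        ub = convolve(u, kernel, mode="nearest")
        vb = convolve(v, kernel, mode="nearest")
        constraint = (fx * ub + fy * vb + ft) / denom
        u_new = ub - fx * constraint
        v_new = vb - fy * constraint
        if params.stop_tolerance is not None:
            delta = 0.5 * (np.mean(np.abs(u_new - u)) + np.mean(np.abs(v_new - v)))
            u, v = u_new, v_new
            if delta < params.stop_tolerance:
                break
        else:
            u, v = u_new, v_new

    return MotionVectorField(ap=v, lat=u, units_state="pixels", source_pair=source_pair)


def total_movement(mvf: MotionVectorField) -> np.ndarray:
    """Per-pixel Euclidean displacement magnitude, sqrt(AP^2 + LAT^2)."""
    return np.hypot(mvf.ap, mvf.lat)


def to_physical(mvf: MotionVectorField, pixel_spacing: float) -> MotionVectorField:
    """Convert a pixel-unit field to mm using the in-plane spacing."""
    if mvf.units_state != "pixels":
        raise UnitsError(f"to_physical expects pixel units, got {mvf.units_state!r}")
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be > 0")
    return replace(
        mvf, ap=mvf.ap * pixel_spacing, lat=mvf.lat * pixel_spacing, units_state="mm"
    )


def to_velocity(mvf: MotionVectorField, interscan_time: float) -> MotionVectorField:
    """Convert an mm displacement field to mm/s using the interscan time."""
    if mvf.units_state != "mm":
        raise UnitsError(f"to_velocity expects mm units, got {mvf.units_state!r}")
    if interscan_time <= 0:
        raise ValueError("interscan_time must be > 0")
    return replace(
        mvf,
        ap=mvf.ap / interscan_time,
        lat=mvf.lat / interscan_time,
        units_state="mm_per_s",
    )


def roi_displacement(
    mvf: MotionVectorField, roi, reduction: str = "norm-of-mean"
) -> tuple[float, float, float]:
    """Reduce the per-pixel field to one ``(ap, lat, movement)`` triple.

    ``ap`` and ``lat`` are the means of the components over the ROI pixels.
    With the default ``"norm-of-mean"`` reduction the movement is the
    Euclidean norm of that mean vector; ``"mean-of-norms"`` instead averages
    the per-pixel magnitudes over the ROI.
    """
    if roi.is_empty:
        raise ValueError("cannot reduce flow over an empty ROI")
    rows, cols = roi.pixels[:, 0], roi.pixels[:, 1]
    if rows.max() >= mvf.shape[0] or cols.max() >= mvf.shape[1]:
        raise ValueError("ROI extends beyond the flow-field bounds")
    ap_mean = float(np.mean(mvf.ap[rows, cols]))
    lat_mean = float(np.mean(mvf.lat[rows, cols]))
    if reduction == "norm-of-mean":
        movement = float(np.hypot(ap_mean, lat_mean))
    elif reduction == "mean-of-norms":
        movement = float(np.mean(np.hypot(mvf.ap[rows, cols], mvf.lat[rows, cols])))
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    return ap_mean, lat_mean, movement


def flow_to_table(mvf: MotionVectorField):
    """Export the field as a tidy (row, col, ap, lat, magnitude, units) table."""
    import pandas as pd

    rows, cols = np.indices(mvf.shape)
    mag = total_movement(mvf)
    return pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "ap": mvf.ap.ravel(),
            "lat": mvf.lat.ravel(),
            "magnitude": mag.ravel(),
            "units": mvf.units_state,
        }
    )
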