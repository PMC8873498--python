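"""Joint angles, locally weighted smoothing, angular velocities, descriptives.

Each of the eight angle-bearing joints (bilateral shoulders, elbows, hips,
knees) carries an interior angle defined by the joint and two adjacent
joints: the shoulder angle is spanned by the contralateral shoulder and the
ipsilateral elbow; the elbow by the ipsilateral shoulder and wrist; the hip
by the contralateral hip and the ipsilateral knee; the knee by the
ipsilateral hip and ankle.  Angles are interior (in [0, 180] degrees) and
therefore invariant to translation, rotation, uniform scaling and mirror
reflection of the image — camera distance and framing do not affect them.

The raw angle series (missing wherever any of its three keypoints was
filtered out) is repaired and denoised in one step with locally weighted
linear regression (tricube weights, single pass) over frame time, evaluated
at every frame.  Angular velocity is the symmetric difference quotient of the
smoothed angle, in degrees per second, undefined at the two endpoint frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    SmoothingError,
    ValidationError,
)
from .joints import ANGLE_TRIPLES, Joint
from .keypoint_io import KeypointSeries

__all__ = [
    "AngleSeries",
    "VelocitySeries",
    "DescriptiveStats",
    "joint_angle",
    "angle_series",
    "smooth_interpolate",
    "angular_velocity",
    "descriptive_stats",
    "write_kinematics",
]


@dataclass
class AngleSeries:
    """Raw and smoothed interior-angle series for one angle-bearing joint.

    ``theta`` is the per-frame raw angle in degrees (NaN where undefined);
    ``smoothed`` is the same-length repaired series (None until
    :func:`smooth_interpolate` has run).
    """

    joint: Joint
    frame_rate: float
    theta: np.ndarray
    smoothed: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.theta)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class VelocitySeries:
    """Angular velocity in degrees/second; endpoints are NaN by construction."""

    joint: Joint
    frame_rate: float
    omega: np.ndarray


@dataclass
class DescriptiveStats:
    """Max, min, mean and sample standard deviation of one signal."""

    maximum: float
    minimum: float
    mean: float
    sd: float


def joint_angle(center, a, b) -> float:
    """Interior angle at ``center`` between rays to ``a`` and ``b``, degrees.

    Accepts 2-vectors or arrays of shape (..., 2); computed as
    atan2(|cross|, dot), which is numerically stable near 0 and 180 degrees.
    Coincident points give NaN for array input and raise for scalars.
    """
    center = np.asarray(center, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u = a - center
    v = b - center
    dot = u[..., 0] * v[..., 0] + u[..., 1] * v[..., 1]
    cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    degenerate = (np.hypot(u[..., 0], u[..., 1]) == 0) | (np.hypot(v[..., 0], v[..., 1]) == 0)
    if center.ndim == 1:
        if degenerate:
            raise DegenerateGeometryError("coincident keypoints: angle undefined")
        return float(np.degrees(np.arctan2(abs(cross), dot)))
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(np.abs(cross), dot))
    return np.where(degenerate, np.nan, ang)


def angle_series(series: KeypointSeries, joint: Joint) -> AngleSeries:
    """Raw interior-angle series for one angle-bearing joint.

    The angle at a frame is defined iff the joint and both adjacent joints
    are observed (post-filtering) at that frame; otherwise it is NaN.
    """
    if joint not in ANGLE_TRIPLES:
        raise ValidationError(f"{joint.value} does not carry an angle (distal joint)")
    adj_a, adj_b = ANGLE_TRIPLES[joint]
    cx, cy = series.joint_xy(joint)
    ax, ay = series.joint_xy(adj_a)
    bx, by = series.joint_xy(adj_b)
    center = np.stack([cx, cy], axis=-1)
    a = np.stack([ax, ay], axis=-1)
    b = np.stack([bx, by], axis=-1)
    theta = joint_angle(center, a, b)
    return AngleSeries(joint=joint, frame_rate=series.frame_rate, theta=theta)


def smooth_interpolate(
    angles: AngleSeries,
    span: float = 0.05,
    overshoot_warn_deg: float = 0.5,
    delta_frac: float = 0.01,
) -> AngleSeries:
    """Repair and denoise an angle series by locally weighted regression.

    Fits a single-pass local linear regression with tricube weights over
    frame time to the defined angles, evaluated at every frame (including
    missing ones, so smoothing doubles as interpolation).  ``span`` is the
    window width as a fraction of total frames (default 0.05); the output is
    clipped to [0, 180] and a warning is emitted if the fit overshot that
    range by more than ``overshoot_warn_deg``.  Deterministic given input
    and parameters.

    ``delta_frac`` is the standard lowess shortcut: within a time interval
    of ``delta_frac`` x duration the fit is linearly interpolated between
    anchor fits instead of being recomputed (exact on locally linear data;
    set 0 to refit at every observed frame).  Missing frames are always
    evaluated with the full local regression.
    """
    if not 0.0 < span <= 1.0:
        raise ValidationError(f"span must be in (0, 1], got {span}")
    theta = np.asarray(angles.theta, dtype=float)
    n = len(theta)
    defined = np.isfinite(theta)
    n_def = int(defined.sum())
    window = span * n
    # the local fit uses int(frac * n_def) = int(min(window, n_def)) points
    if n_def < 4 or min(window, n_def) < 4:
        raise SmoothingError(
            f"{angles.joint.value}: {n_def} defined points with window "
            f"{window:.1f} frames — too few to fit locally"
        )
    t = angles.times
    frac = min(1.0, window / n_def)
    delta = delta_frac * (t[-1] - t[0]) if n > 1 else 0.0
    smoothed = np.empty(n)
    smoothed[defined] = lowess(
        theta[defined], t[defined], frac=frac, it=0, delta=delta, return_sorted=False
    )
    if n_def < n:
        smoothed[~defined] = lowess(
            theta[defined], t[defined], frac=frac, it=0, xvals=t[~defined]
        )
    over = np.nanmax(np.concatenate([[0.0], smoothed - 180.0, -smoothed]))
    if over > overshoot_warn_deg:
        warnings.warn(
            f"{angles.joint.value}: smoothed angle overshot [0, 180] by {over:.2f} deg",
            stacklevel=2,
        )
    smoothed = np.clip(smoothed, 0.0, 180.0)
    if not np.all(np.isfinite(smoothed)):
        raise SmoothingError(f"{angles.joint.value}: smoothing produced non-finite values")
    return replace(angles, smoothed=smoothed)


def angular_velocity(angles: AngleSeries) -> VelocitySeries:
    """Symmetric-difference-quotient angular velocity of the smoothed series.

    omega[t] = (theta[t+1] - theta[t-1]) / (2 dt) in degrees/second; the first
    and last frames are NaN.  Second-order accurate for smooth signals.
    """
    if angles.smoothed is None:
        raise ValidationError("smooth_interpolate must run before angular_velocity")
    theta = angles.smoothed
    if len(theta) < 3:
        raise InsufficientDataError("need at least 3 frames for a central difference")
    dt = 1.0 / angles.frame_rate
    omega = np.full(len(theta), np.nan)
    omega[1:-1] = (theta[2:] - theta[:-2]) / (2.0 * dt)
    return VelocitySeries(joint=angles.joint, frame_rate=angles.frame_rate, omega=omega)


def write_kinematics(
    infant_id: str,
    angles: dict[Joint, AngleSeries],
    velocities: dict[Joint, "VelocitySeries"],
    path,
) -> None:
    """Tidy per-infant kinematics CSV: infant_id, joint, frame, theta_raw,
    theta_smooth, omega (blank fields where undefined)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["infant_id", "joint", "frame", "theta_raw", "theta_smooth", "omega"])

        def fmt(v):
            return f"{v:.6g}" if np.isfinite(v) else ""

        for joint, ang in angles.items():
            om = velocities[joint].omega if joint in velocities else np.full(ang.n_frames, np.nan)
            sm = ang.smoothed if ang.smoothed is not None else np.full(ang.n_frames, np.nan)
            for f in range(ang.n_frames):
                writer.writerow(
                    [infant_id, joint.value, f, fmt(ang.theta[f]), fmt(sm[f]), fmt(om[f])]
                )


def descriptive_stats(values: np.ndarray) -> DescriptiveStats:
    """Max, min, mean, sample sd (n-1 denominator) over defined values."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise InsufficientDataError("no defined values")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return DescriptiveStats(
        maximum=float(values.max()),
        minimum=float(values.min()),
        mean=float(values.mean()),
        sd=sd,
    )
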