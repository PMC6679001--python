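"""Curvature-angle kinematics on a fixed arc-length grid.

The central kinematic variable is the signed *curvature angle*
theta(s, t): the planar angle between the chord from ``s`` to
``s + d_ref`` and the chord from ``s - d_ref`` to ``s`` along the traced
midline, with ``d_ref`` = 10 µm by default.  On a circular arc of radius R
this equals ``d_ref / R`` (the chords are tangent directions at points
``d_ref`` apart, so their angle is arc/radius); on a straight flagellum it
is zero.  The sign follows the z-component of the cross product of the two
chords, so mirroring the trace flips it.

Near the ends the chords are truncated to the available arc (one-sided);
positions where either chord would be empty are masked.  A strict variant
that masks everything within ``d_ref`` of either end is available via
``KinematicsConfig.mask_ends``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d

from .trace import FlagellarTrace

__all__ = [
    "KinematicsConfig",
    "CurvatureField",
    "resample_arclength",
    "curvature_angle",
    "build_field",
    "write_field_csv",
    "read_field_csv",
]


@dataclass(frozen=True)
class KinematicsConfig:
    """Parameters of the curvature-angle computation.

    curvature_ref_distance_um: chord separation d_ref (µm).
    head_ref_distance_um: arc distance defining the head reference vector.
    arclen_step_um: resampling step of the fixed arc-length grid; must be
        fine relative to d_ref (<= d_ref / 5) so the chord end points lie on
        the grid.
    angle_unit: unit for exported angles ("degrees" or "radians"); all
        internal computation is in radians.
    mask_ends: if True, positions within d_ref of either end are masked
        instead of using one-sided truncated chords.
    """

    curvature_ref_distance_um: float = 10.0
    head_ref_distance_um: float = 10.0
    arclen_step_um: float = 1.0
    angle_unit: str = "degrees"
    mask_ends: bool = False

    def validate(self) -> None:
        if not self.curvature_ref_distance_um > 0:
            raise ValueError("curvature_ref_distance_um must be positive")
        if not 0 < self.arclen_step_um <= self.curvature_ref_distance_um / 5:
            raise ValueError("arclen_step_um must be in (0, curvature_ref_distance_um / 5]")
        if self.angle_unit not in ("degrees", "radians"):
            raise ValueError("angle_unit must be 'degrees' or 'radians'")


@dataclass
class CurvatureField:
    """Curvature angles on a (position x time) grid.

    theta_rad has shape (n_s, n_t) and is in radians; ``valid`` masks cells
    where no trace or no chord was available.  ``theta(unit)`` converts.
    """

    s_um: np.ndarray
    t_s: np.ndarray
    theta_rad: np.ndarray
    valid: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        if self.theta_rad.shape != (len(self.s_um), len(self.t_s)):
            raise ValueError("theta matrix shape must be (n_positions, n_times)")
        if self.valid.shape != self.theta_rad.shape:
            raise ValueError("valid mask shape must match theta")
        if not np.isfinite(self.theta_rad[self.valid]).all():
            raise ValueError("theta must be finite on valid cells")

    def theta(self, unit: str = "degrees") -> np.ndarray:
        if unit == "degrees":
            return np.degrees(self.theta_rad)
        if unit == "radians":
            return self.theta_rad
        raise ValueError(f"unknown angle unit {unit!r}")


@dataclass
class ResampledFrames:
    """Traces resampled onto a common arc-length grid."""

    s_um: np.ndarray
    xy_um: np.ndarray  # (n_frames, n_s, 2)
    valid: np.ndarray  # (n_frames, n_s)
    t_s: np.ndarray
    frame_rate_hz: float


def resample_arclength(trace: FlagellarTrace, config: KinematicsConfig = KinematicsConfig()) -> ResampledFrames:
    """Resample each frame's midline onto the fixed grid s = 0, h, 2h, ...

    x(s) and y(s) are interpolated with cubic splines; the grid spans the
    longest frame, and positions beyond a given frame's own length are
    masked.  Frames with fewer than 2 points (failed traces) yield fully
    masked rows.
    """
    config.validate()
    step = config.arclen_step_um
    max_len = max((f.length_um for f in trace.frames if f.ok and f.n_points >= 2), default=0.0)
    if max_len <= 0:
        raise ValueError("no traceable frames to resample")
    s = np.arange(0.0, max_len + 1e-9, step)
    n_frames = len(trace.frames)
    xy = np.zeros((n_frames, len(s), 2))
    valid = np.zeros((n_frames, len(s)), dtype=bool)
    for i, f in enumerate(trace.frames):
        if not f.ok or f.n_points < 2:
            continue
        arclen = f.arclen_um
        if not np.all(np.diff(arclen) > 0):
            keep = np.concatenate([[True], np.diff(arclen) > 0])
            arclen = arclen[keep]
            pts = f.xy_um[keep]
        else:
            pts = f.xy_um
        kind = "cubic" if len(arclen) >= 4 else "linear"
        fx = interp1d(arclen, pts[:, 0], kind=kind, bounds_error=False)
        fy = interp1d(arclen, pts[:, 1], kind=kind, bounds_error=False)
        ok = s <= arclen[-1] + 1e-9
        xy[i, ok, 0] = fx(np.minimum(s[ok], arclen[-1]))
        xy[i, ok, 1] = fy(np.minimum(s[ok], arclen[-1]))
        valid[i] = ok
    t = np.array([f.frame_index for f in trace.frames], dtype=float) / trace.frame_rate_hz
    return ResampledFrames(s_um=s, xy_um=xy, valid=valid, t_s=t, frame_rate_hz=trace.frame_rate_hz)


def curvature_angle(
    xy: np.ndarray,
    s: np.ndarray,
    valid: np.ndarray | None = None,
    config: KinematicsConfig = KinematicsConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Signed curvature angle theta(s) of one resampled frame (radians).

    Returns ``(theta, ok)`` on the input grid.  The forward chord runs from
    s to min(s + d_ref, L), the backward chord from max(s - d_ref, 0) to s
    (one-sided truncation at the ends unless ``config.mask_ends``); the
    angle is measured from the backward to the forward chord, positive
    counter-clockwise in the (x right, y down) image frame.
    """
    config.validate()
    n = len(s)
    theta = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    vi = np.flatnonzero(valid)
    if len(vi) < 2:
        warnings.warn("frame shorter than two valid points; curvature masked")
        return theta, ok
    lo, hi = vi[0], vi[-1]
    if s[hi] - s[lo] < config.curvature_ref_distance_um:
        warnings.warn("frame shorter than the curvature reference distance; all masked")
        return theta, ok
    step = s[1] - s[0] if n > 1 else config.arclen_step_um
    k = int(round(config.curvature_ref_distance_um / step))
    i = np.arange(lo, hi + 1)
    fwd_i = np.minimum(i + k, hi)
    bwd_i = np.maximum(i - k, lo)
    good = (fwd_i > i) & (bwd_i < i)
    if config.mask_ends:
        good &= (i + k <= hi) & (i - k >= lo)
    f = xy[fwd_i] - xy[i]
    b = xy[i] - xy[bwd_i]
    cross = b[:, 0] * f[:, 1] - b[:, 1] * f[:, 0]
    dot = np.einsum("ij,ij->i", b, f)
    th = np.arctan2(cross, dot)
    theta[i[good]] = th[good]
    ok[i[good]] = True
    if not ok.any():
        warnings.warn("frame shorter than the curvature reference distance; all masked")
    return theta, ok


def build_field(
    trace: FlagellarTrace, config: KinematicsConfig = KinematicsConfig()
) -> CurvatureField:
    """Stack per-frame curvature angles into the (position x time) field."""
    if trace.n_frames < 2:
        raise ValueError("need at least 2 frames to build a curvature field")
    rs = resample_arclength(trace, config)
    n_s, n_t = len(rs.s_um), len(rs.t_s)
    theta = np.full((n_s, n_t), np.nan)
    valid = np.zeros((n_s, n_t), dtype=bool)
    for j in range(n_t):
        th, ok = curvature_angle(rs.xy_um[j], rs.s_um, rs.valid[j], config)
        theta[:, j] = th
        valid[:, j] = ok
    theta[~valid] = 0.0
    return CurvatureField(s_um=rs.s_um, t_s=rs.t_s, theta_rad=theta, valid=valid,
                          frame_rate_hz=rs.frame_rate_hz)


def write_field_csv(field: CurvatureField, path, config: KinematicsConfig = KinematicsConfig()) -> None:
    """Long-format CSV: frame, time_s, s_um, theta, valid."""
    n_s, n_t = field.theta_rad.shape
    theta = field.theta(config.angle_unit)
    col = "theta_deg" if config.angle_unit == "degrees" else "theta_rad"
    df = pd.DataFrame({
        "frame": np.repeat(np.arange(n_t), n_s),
        "time_s": np.repeat(field.t_s, n_s),
        "s_um": np.tile(field.s_um, n_t),
        col: theta.T.ravel(),
        "valid": field.valid.T.ravel(),
    })
    df.to_csv(path, index=False)


def read_field_csv(path, frame_rate_hz: float | None = None) -> CurvatureField:
    df = pd.read_csv(path, float_precision="round_trip")
    s = np.unique(df["s_um"].to_numpy())
    t = np.unique(df["time_s"].to_numpy())
    col = "theta_deg" if "theta_deg" in df.columns else "theta_rad"
    piv = df.pivot_table(index="s_um", columns="time_s", values=col, sort=True)
    vpiv = df.pivot_table(index="s_um", columns="time_s", values="valid", sort=True)
    theta = piv.to_numpy()
    if col == "theta_deg":
        theta = np.radians(theta)
    valid = vpiv.to_numpy() > 0.5
    theta[~valid] = 0.0
    if frame_rate_hz is None:
        dt = np.diff(t)
        frame_rate_hz = 1.0 / dt.min() if len(dt) else 1.0
    return CurvatureField(s_um=s, t_s=t, theta_rad=theta, valid=valid, frame_rate_hz=frame_rate_hz)
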