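"""Synthetic flagellar waveforms and dark-field-like movie rendering.

The generator produces a planar beating flagellum with known kinematics so
that every downstream stage (tracing, curvature, spectral, asymmetry) can be
validated by parameter recovery.  The waveform is parameterized in the
tangent angle

    psi(s, t) = asym_offset(s) + amp_envelope(s) * sin(2*pi*f*t - 2*pi*s/lambda)

with arc length ``s`` (µm), time ``t`` (s), beat frequency ``f`` (Hz) and
spatial wavelength ``lambda`` (µm).  The midline is obtained by integrating
the unit tangent from a fixed (tethered) head point, mirroring a tethered
sperm whose head sticks to the chamber surface.

``asym_offset`` is the *static* tangent-angle profile.  Note that a constant
offset is merely a rigid rotation of the whole cell and therefore produces no
beat asymmetry in any rotation-invariant bending measure; to inject a static
*curvature-angle* offset theta0 (the quantity the asymmetry statistic
recovers) use :func:`arc_offset`, which returns the tangent ramp
``theta0 * s / d_ref`` — a circular arc whose chord-to-chord curvature angle
over the reference distance ``d_ref`` equals theta0 at every interior
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .io import Movie

__all__ = [
    "WaveformParams",
    "GroundTruth",
    "RenderError",
    "arc_offset",
    "constant",
    "generate_waveform",
    "render_movie",
    "ground_truth_table",
    "simulate_asymmetry_profiles",
]

#: arc-length discretization of the ground-truth midline (µm)
GT_STEP_UM = 0.25


def constant(value: float) -> Callable[[np.ndarray], np.ndarray]:
    """Return a vectorized arc-length function that is identically ``value``."""

    def f(s: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(s, dtype=float), float(value))

    return f


def arc_offset(theta0_rad: float, d_ref_um: float = 10.0) -> Callable[[np.ndarray], np.ndarray]:
    """Static tangent-angle ramp whose curvature angle equals ``theta0_rad``.

    A circular arc of radius ``R = d_ref_um / theta0_rad`` has tangent angle
    ``theta0 * s / d_ref`` and a chord-to-chord curvature angle (reference
    distance ``d_ref_um``) of exactly ``theta0_rad`` at interior positions,
    which is what the local beat-asymmetry statistic recovers.
    """

    def f(s: np.ndarray) -> np.ndarray:
        return float(theta0_rad) * np.asarray(s, dtype=float) / float(d_ref_um)

    return f


@dataclass(frozen=True)
class WaveformParams:
    """Ground-truth parameters of the synthetic beating flagellum.

    Defaults are plausible mouse-sperm scales at the recording conditions of
    the analysis (200 fps, 0.65 µm/px): an 80 µm flagellum carrying a 20 Hz
    traveling bending wave of 60 µm wavelength with a 0.5 rad tangent-angle
    amplitude, rendered at a peak ridge intensity of 10000 counts with
    additive Gaussian noise of 10 % of the ridge peak.
    """

    length_um: float = 80.0
    beat_freq_hz: float = 20.0
    amp_envelope: Callable[[np.ndarray], np.ndarray] = field(default_factory=lambda: constant(0.5))
    asym_offset: Callable[[np.ndarray], np.ndarray] = field(default_factory=lambda: constant(0.0))
    wavelength_um: float = 60.0
    frame_rate_hz: float = 200.0
    n_frames: int = 400
    pixel_size_um: float = 0.65
    noise_sd: float = 1000.0
    seed: int = 0
    #: peak intensity of the rendered ridge (counts, 16-bit range)
    peak_intensity: float = 10000.0
    #: flat camera offset (counts) so additive noise is not clipped at zero
    baseline_intensity: float = 3000.0
    #: Gaussian cross-section SD of the rendered ridge (px)
    ridge_sigma_px: float = 1.5
    #: relative amplitude of the bright head blob (0 disables it)
    head_amp: float = 2.0
    #: Gaussian SD of the head blob (px)
    head_sigma_px: float = 2.0

    def validate(self) -> None:
        if not self.length_um > 0:
            raise ValueError("length_um must be positive")
        if not 0 < self.beat_freq_hz < self.frame_rate_hz / 2:
            raise ValueError(
                f"beat_freq_hz={self.beat_freq_hz} violates the Nyquist bound "
                f"(0, {self.frame_rate_hz / 2})"
            )
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.wavelength_um > 0:
            raise ValueError("wavelength_um must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Exact kinematics of a generated waveform.

    Attributes
    ----------
    s_um : (n_s,) arc-length grid from 0 (head) to the flagellar length.
    t_s : (n_t,) frame times in seconds.
    psi : (n_s, n_t) tangent-angle field (rad).
    xy_um : (n_t, n_s, 2) midline coordinates per frame, head first (µm).
    curvature_angle : (n_s, n_t) nominal chord-to-chord curvature angle at
        the configured reference distance (rad); NaN where a chord does not
        fit.
    curvature_ref_um : reference distance used for ``curvature_angle``.
    asymmetry_rad : (n_s,) nominal asymmetry profile — the absolute static
        curvature angle of the time-averaged shape (rad); NaN at the ends.
    beat_freq_hz : nominal beat frequency.
    params : the generating parameters.
    """

    s_um: np.ndarray
    t_s: np.ndarray
    psi: np.ndarray
    xy_um: np.ndarray
    curvature_angle: np.ndarray
    curvature_ref_um: float
    asymmetry_rad: np.ndarray
    beat_freq_hz: float
    params: WaveformParams


def _chord_angles(xy: np.ndarray, s: np.ndarray, d_ref: float) -> np.ndarray:
    """Chord-to-chord curvature angle along one curve (NaN where no chord fits).

    ``xy``: (n, 2) points on a fixed arc-length grid ``s``.
    """
    ds = s[1] - s[0]
    k = int(round(d_ref / ds))
    n = len(s)
    theta = np.full(n, np.nan)
    if k < 1 or 2 * k >= n:
        return theta
    fwd = xy[2 * k :] - xy[k:-k]  # chord s -> s+d
    bwd = xy[k:-k] - xy[: -2 * k]  # chord s-d -> s
    cross = bwd[:, 0] * fwd[:, 1] - bwd[:, 1] * fwd[:, 0]
    dot = np.einsum("ij,ij->i", bwd, fwd)
    theta[k:-k] = np.arctan2(cross, dot)
    return theta


def generate_waveform(params: WaveformParams) -> GroundTruth:
    """Evaluate the traveling-wave model and integrate the midline.

    The head is tethered at the origin with initial tangent along +x; the
    midline of frame ``t`` is ``(x, y)(s) = integral_0^s (cos psi, sin psi) du``
    evaluated on a 0.25 µm arc-length grid (midpoint rule), so consecutive
    points are well under 1.5 µm apart and arc length is exactly the grid.
    """
    params.validate()
    n_s = int(round(params.length_um / GT_STEP_UM)) + 1
    s = np.linspace(0.0, params.length_um, n_s)
    t = np.arange(params.n_frames) / params.frame_rate_hz
    amp = np.asarray(params.amp_envelope(s), dtype=float)
    off = np.asarray(params.asym_offset(s), dtype=float)
    phase = 2 * np.pi * params.beat_freq_hz * t[None, :] - 2 * np.pi * s[:, None] / params.wavelength_um
    psi = off[:, None] + amp[:, None] * np.sin(phase)

    # midpoint-rule integration of the unit tangent: O(ds^2) accurate
    psi_mid = 0.5 * (psi[:-1] + psi[1:])
    dx = GT_STEP_UM * np.cos(psi_mid)
    dy = GT_STEP_UM * np.sin(psi_mid)
    x = np.concatenate([np.zeros((1, params.n_frames)), np.cumsum(dx, axis=0)])
    y = np.concatenate([np.zeros((1, params.n_frames)), np.cumsum(dy, axis=0)])
    xy = np.stack([x.T, y.T], axis=-1)  # (n_t, n_s, 2)

    d_ref = 10.0
    curv = np.stack([_chord_angles(xy[i], s, d_ref) for i in range(params.n_frames)], axis=-1)

    # static shape = midline of the time-averaged tangent field
    psi0 = psi.mean(axis=1)
    psi0_mid = 0.5 * (psi0[:-1] + psi0[1:])
    x0 = np.concatenate([[0.0], np.cumsum(GT_STEP_UM * np.cos(psi0_mid))])
    y0 = np.concatenate([[0.0], np.cumsum(GT_STEP_UM * np.sin(psi0_mid))])
    asym = np.abs(_chord_angles(np.stack([x0, y0], axis=-1), s, d_ref))

    return GroundTruth(
        s_um=s,
        t_s=t,
        psi=psi,
        xy_um=xy,
        curvature_angle=curv,
        curvature_ref_um=d_ref,
        asymmetry_rad=asym,
        beat_freq_hz=params.beat_freq_hz,
        params=params,
    )


class RenderError(RuntimeError):
    """Raised when ground-truth coordinates do not fit the target frame."""


def render_movie(
    truth: GroundTruth,
    params: Optional[WaveformParams] = None,
    shape: Optional[tuple[int, int]] = None,
    margin_px: int = 10,
) -> Movie:
    """Render ground-truth midlines as a dark-field-like 16-bit movie.

    Each midline is drawn as a bright ridge with a Gaussian cross-section
    (intensity = peak * exp(-d^2 / 2 sigma^2) with d the distance to the
    midline), an optional brighter Gaussian blob marks the tethered head, and
    seeded additive Gaussian noise emulates camera noise.  If ``shape`` is
    omitted the frame is sized to the midline bounding box plus
    ``margin_px``; an explicit ``shape`` that clips any midline raises
    :class:`RenderError` naming the offending frame.
    """
    params = params or truth.params
    px = params.pixel_size_um
    xy_px = truth.xy_um / px
    lo = xy_px.reshape(-1, 2).min(axis=0)
    hi = xy_px.reshape(-1, 2).max(axis=0)

    if shape is None:
        origin = lo - margin_px
        shape = (
            int(np.ceil(hi[1] - lo[1])) + 2 * margin_px + 1,
            int(np.ceil(hi[0] - lo[0])) + 2 * margin_px + 1,
        )
    else:
        origin = lo - margin_px

    h, w = shape
    sigma = params.ridge_sigma_px
    reach = int(np.ceil(4 * sigma)) + 1
    rng = np.random.default_rng(params.seed)
    stack = np.empty((params.n_frames, h, w), dtype=np.uint16)
    yy, xx = np.mgrid[0:h, 0:w]

    for i in range(params.n_frames):
        pts = xy_px[i] - origin
        if (pts < -0.5).any() or (pts[:, 0] > w - 0.5).any() or (pts[:, 1] > h - 0.5).any():
            raise RenderError(f"frame {i}: midline coordinates outside the {h}x{w} frame")
        # candidate pixels: dilated bounding strip around the midline
        mask = np.zeros((h, w), dtype=bool)
        ix = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
        iy = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
        mask[iy, ix] = True
        from scipy.ndimage import binary_dilation

        mask = binary_dilation(mask, iterations=reach)
        cand = np.column_stack([xx[mask], yy[mask]])
        d, _ = cKDTree(pts).query(cand, k=1)
        frame = np.zeros((h, w), dtype=float)
        frame[mask] = params.peak_intensity * np.exp(-(d**2) / (2 * sigma**2))
        if params.head_amp > 0:
            hx, hy = pts[0]
            r2 = (xx - hx) ** 2 + (yy - hy) ** 2
            head = params.head_amp * params.peak_intensity * np.exp(-r2 / (2 * params.head_sigma_px**2))
            np.maximum(frame, head, out=frame)
        frame += params.baseline_intensity
        if params.noise_sd > 0:
            frame = frame + rng.normal(0.0, params.noise_sd, size=frame.shape)
        stack[i] = np.clip(frame, 0, 65535).astype(np.uint16)

    meta = {
        "seed": params.seed,
        "beat_freq_hz": params.beat_freq_hz,
        "length_um": params.length_um,
        "origin_px": [float(origin[0]), float(origin[1])],
        "head_xy_px": [float(xy_px[0, 0, 0] - origin[0]), float(xy_px[0, 0, 1] - origin[1])],
        "noise_sd": params.noise_sd,
        "baseline_intensity": params.baseline_intensity,
    }
    return Movie(stack=stack, frame_rate_hz=params.frame_rate_hz, pixel_size_um=px, meta=meta)


def simulate_asymmetry_profiles(
    n_sperm: int,
    s_um: Optional[np.ndarray] = None,
    base_deg: float = 5.0,
    effect_deg: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    smooth_sd_deg: float = 1.0,
    smooth_corr_um: float = 15.0,
    iid_sd_deg: float = 0.5,
    condition: str = "",
    rng: Optional[np.random.Generator] = None,
):
    """Draw synthetic per-sperm asymmetry profiles for statistics calibration.

    Each sperm's profile is ``base + effect(s) + smooth(s) + iid(s)`` where
    ``smooth`` is a Gaussian process with RBF correlation length
    ``smooth_corr_um`` — between-sperm differences in real recordings are
    smooth shape differences along the flagellum — plus a small iid
    per-position component.  Defaults give a realistic ~1.1 deg total
    between-sperm SD on a ~5 deg baseline.
    """
    from .asymmetry import AsymmetryProfile

    rng = rng or np.random.default_rng()
    if s_um is None:
        s_um = np.arange(0.0, 80.0, 1.0)
    s = np.asarray(s_um, dtype=float)
    n = len(s)
    cov = np.exp(-((s[:, None] - s[None, :]) ** 2) / (2 * smooth_corr_um**2))
    cov += 1e-10 * np.eye(n)
    chol = np.linalg.cholesky(cov)
    eff = np.zeros(n) if effect_deg is None else np.asarray(effect_deg(s), dtype=float)
    profiles = []
    for i in range(n_sperm):
        smooth = smooth_sd_deg * (chol @ rng.standard_normal(n))
        noise = iid_sd_deg * rng.standard_normal(n)
        a = base_deg + eff + smooth + noise
        profiles.append(AsymmetryProfile(
            s_um=s.copy(), a_deg=a, valid=np.ones(n, dtype=bool),
            n_frames=400, sperm_id=f"{condition}_{i}", condition=condition,
        ))
    return profiles


def ground_truth_table(truth: GroundTruth):
    """Ground truth as a long-format DataFrame.

    Columns: frame, point_index, x_um, y_um, arclen_um, tangent_angle_rad.
    """
    import pandas as pd

    n_t, n_s, _ = truth.xy_um.shape
    frame = np.repeat(np.arange(n_t), n_s)
    idx = np.tile(np.arange(n_s), n_t)
    return pd.DataFrame(
        {
            "frame": frame,
            "point_index": idx,
            "x_um": truth.xy_um[:, :, 0].ravel(),
            "y_um": truth.xy_um[:, :, 1].ravel(),
            "arclen_um": np.tile(truth.s_um, n_t),
            "tangent_angle_rad": truth.psi.T.ravel(),
        }
    )
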