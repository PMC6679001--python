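"""Frame preprocessing and flagellar midline tracing.

The tracer reconstructs the sperm flagellum midline from a single-sperm
dark-field frame in five stages:

1. preprocess: Gaussian blur (sigma 0.5 px) + rolling-ball background
   subtraction (radius 5 px);
2. binarize at a triangle threshold of the intensity histogram;
3. skeletonize the largest connected component and order the skeleton
   pixels along the longest geodesic path, head end first;
4. upscale the ordered point list 3-fold by spline interpolation;
5. refine each point to sub-pixel accuracy by fitting a 1-D Gaussian to the
   intensity profile along the local normal, then smooth positions and fit
   widths along the flagellum.

All tunable parameters live in :class:`TraceSettings`; the defaults are the
standard tracing settings for 200 fps / 0.65 µm-per-pixel mouse-sperm
recordings.  Coordinates use the image convention: origin at the top-left
pixel center, x rightward, y downward; arc length starts at 0 at the
head-side first point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.interpolate import splev, splprep
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize
from skimage.restoration import rolling_ball

from .io import Movie

__all__ = [
    "TraceSettings",
    "TracedFrame",
    "FlagellarTrace",
    "TraceFailure",
    "preprocess_frame",
    "triangle_threshold",
    "trace_midline",
    "refine_normals",
    "trace_frame",
    "trace_movie",
    "write_trace_csv",
    "read_trace_csv",
]

# quality flags
QUALITY_OK = 0
QUALITY_FIT_FAILED = 1
QUALITY_HEAD_EXCLUDED = 2


@dataclass(frozen=True)
class TraceSettings:
    """Tracing parameters (defaults = the standard settings set).

    gauss_sigma_px: pre-blur applied to the raw frame before background
        subtraction.  ``gauss_sigma_internal_px`` is the tracer's own blur
        applied before thresholding; the two are sequential.
    bg_radius_px: rolling-ball radius (5 px = 3.25 µm at 0.65 µm/px).
    normal_radius_um: half-length of the normal profile used for the
        Gaussian center fit.
    max_vector_len_points: maximum chord span (in points) for local tangent
        estimation; shrunk near the ends.
    smoothing_window_points: +/- neighbors for xy and fit-width smoothing.
    smoothing_distance_um: neighbors farther than this (euclidean) are
        excluded from the smoothing window.
    head_ref_distance_um: arc distance to the point forming the head
        reference vector.
    head_exclude_points: head points excluded from sub-pixel correction.
    """

    gauss_sigma_px: float = 0.5
    bg_radius_px: float = 5.0
    threshold_method: str = "triangle"
    gauss_sigma_internal_px: float = 1.0
    upscale_fold: int = 3
    normal_radius_um: float = 5.0
    max_vector_len_points: int = 14
    smoothing_window_points: int = 15
    smoothing_distance_um: float = 9.6
    head_ref_distance_um: float = 10.0
    head_exclude_points: int = 10
    min_branch_px: float = 5.0
    add_head_com_first_point: bool = False
    unify_start_points: bool = False
    filter_points_by_gauss_fits: bool = False
    repeat_gauss_fit_after_binarization: bool = False
    exclude_head_from_correction: bool = True
    smooth_normal_for_fit: bool = True

    def validate(self) -> None:
        for name in (
            "gauss_sigma_px",
            "bg_radius_px",
            "upscale_fold",
            "normal_radius_um",
            "max_vector_len_points",
            "smoothing_window_points",
            "smoothing_distance_um",
            "head_ref_distance_um",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"TraceSettings.{name} must be positive")


@dataclass
class TracedFrame:
    """Ordered midline of one frame, head to tip."""

    frame_index: int
    x_um: np.ndarray
    y_um: np.ndarray
    arclen_um: np.ndarray
    fit_width_um: np.ndarray
    quality: np.ndarray
    ok: bool = True
    message: str = ""

    @property
    def n_points(self) -> int:
        return len(self.x_um)

    @property
    def length_um(self) -> float:
        return float(self.arclen_um[-1]) if self.n_points else 0.0

    @property
    def xy_um(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])


@dataclass
class FlagellarTrace:
    """Per-frame traces of one movie."""

    frames: list[TracedFrame]
    pixel_size_um: float
    frame_rate_hz: float
    settings: TraceSettings = field(default_factory=TraceSettings)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_ok(self) -> int:
        return sum(f.ok for f in self.frames)


class TraceFailure(RuntimeError):
    """Raised when a frame contains no traceable flagellum."""


def preprocess_frame(frame: np.ndarray, settings: TraceSettings = TraceSettings()) -> np.ndarray:
    """Gaussian pre-blur + rolling-ball background subtraction.

    Returns a non-negative float image.  A constant image maps to all zeros
    (the rolling-ball background of a flat image is the image itself).
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale frame, got shape {frame.shape}")
    img = ndimage.gaussian_filter(frame.astype(float), sigma=settings.gauss_sigma_px)
    background = rolling_ball(img, radius=settings.bg_radius_px)
    out = img - background
    np.clip(out, 0, None, out=out)
    return out


class TriangleResult(NamedTuple):
    threshold: int
    degenerate: bool


def triangle_threshold(histogram: Sequence[float]) -> TriangleResult:
    """Triangle threshold on an intensity histogram.

    Draws the straight line from the histogram peak to the farthest
    non-empty bin and returns the bin index maximizing the perpendicular
    distance between histogram and line (both axes normalized to [0, 1] over
    the peak-to-far span, so the result is invariant to count and bin
    scaling).  Degenerate histograms (fewer than three distinct non-empty
    bins, or a flat span) return the peak bin with ``degenerate=True``.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1 or hist.size == 0:
        raise ValueError("histogram must be a non-empty 1-D array of counts")
    if not (hist > 0).any():
        raise ValueError("histogram has no counts")
    nonempty = np.flatnonzero(hist > 0)
    peak = int(np.argmax(hist))
    first, last = int(nonempty[0]), int(nonempty[-1])
    far = last if (last - peak) >= (peak - first) else first
    span = abs(far - peak)
    if span < 2 or hist[peak] == hist[far]:
        return TriangleResult(threshold=peak, degenerate=True)
    idx = np.arange(min(peak, far), max(peak, far) + 1)
    x = (idx - peak) / (far - peak)  # 0 at peak, 1 at far bin
    y = (hist[idx] - hist[far]) / (hist[peak] - hist[far])  # 1 at peak, 0 at far
    # line from (0, 1) to (1, 0): x + y - 1 = 0; distance = |x + y - 1| / sqrt(2)
    dist = (1.0 - x - y) / np.sqrt(2.0)
    return TriangleResult(threshold=int(idx[np.argmax(dist)]), degenerate=False)


def _threshold_value(img: np.ndarray, n_bins: int = 256) -> float:
    """Map the histogram-bin triangle threshold to an intensity value."""
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise TraceFailure("flat image: nothing to threshold")
    counts, edges = np.histogram(img, bins=n_bins, range=(lo, hi))
    res = triangle_threshold(counts)
    return float(edges[res.threshold + 1])


def _skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Ordered (x, y) pixel coordinates along the skeleton's longest geodesic.

    Builds the 8-connected pixel graph with euclidean edge weights and
    extracts the diameter path by a double Dijkstra sweep (exact on trees,
    which pruned skeletons are).
    """
    ys, xs = np.nonzero(skel)
    n = len(ys)
    if n < 2:
        raise TraceFailure("skeleton too short to trace")
    index = -np.ones(skel.shape, dtype=int)
    index[ys, xs] = np.arange(n)
    rows, cols, wts = [], [], []
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        y2, x2 = ys + dy, xs + dx
        ok = (y2 >= 0) & (y2 < skel.shape[0]) & (x2 >= 0) & (x2 < skel.shape[1])
        ok[ok] &= skel[y2[ok], x2[ok]]
        rows.append(np.arange(n)[ok])
        cols.append(index[y2[ok], x2[ok]])
        wts.append(np.full(ok.sum(), np.hypot(dy, dx)))
    g = sparse.coo_matrix(
        (np.concatenate(wts), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    g = g + g.T

    d0 = dijkstra(g, indices=0)
    d0[np.isinf(d0)] = -1
    a = int(np.argmax(d0))
    da, pred = dijkstra(g, indices=a, return_predecessors=True)
    da[np.isinf(da)] = -1
    b = int(np.argmax(da))
    path = [b]
    while path[-1] != a:
        p = pred[path[-1]]
        if p < 0:
            raise TraceFailure("disconnected skeleton")
        path.append(int(p))
    path = np.asarray(path)
    return np.column_stack([xs[path], ys[path]]).astype(float)


def trace_midline(
    preprocessed: np.ndarray,
    settings: TraceSettings = TraceSettings(),
    head_xy_px: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Trace the flagellar midline of a preprocessed frame.

    Binarizes at the triangle threshold, skeletonizes the largest connected
    component, orders the skeleton along its longest path starting at the
    head end, and upscales the point list ``upscale_fold``-fold by cubic
    spline interpolation.  Returns ordered (n, 2) pixel coordinates (x, y).

    The head end is the endpoint nearest ``head_xy_px`` when given (e.g. the
    tether point of the synthetic generator), otherwise the endpoint with the
    brighter local neighborhood — in dark-field recordings the sperm head
    scatters far more light than the flagellar tip.
    """
    settings.validate()
    img = ndimage.gaussian_filter(np.asarray(preprocessed, dtype=float),
                                  sigma=settings.gauss_sigma_internal_px)
    thr = _threshold_value(img)
    binary = img > thr
    labels, n_lab = ndimage.label(binary)
    if n_lab == 0:
        raise TraceFailure("no component above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
    big = np.flatnonzero(sizes >= 0.25 * sizes.max()) + 1
    if len(big) > 1:
        raise TraceFailure(f"{len(big)} comparably sized components above threshold")
    comp = labels == (int(np.argmax(sizes)) + 1)
    skel = skeletonize(comp)
    # ordering along the longest geodesic path drops every side branch; any
    # leftover branch longer than min_branch_px is worth a warning
    path = _skeleton_path(skel)
    n_off_path = int(skel.sum()) - len(path)
    if n_off_path > settings.min_branch_px:
        # message kept constant so repeated per-frame warnings deduplicate
        warnings.warn("skeleton has more than two endpoints; longest path taken")

    # head-end ordering
    if head_xy_px is not None:
        h = np.asarray(head_xy_px, dtype=float)
        if np.linalg.norm(path[-1] - h) < np.linalg.norm(path[0] - h):
            path = path[::-1]
    else:
        if _end_brightness(img, path[-1]) > _end_brightness(img, path[0]):
            path = path[::-1]

    if settings.add_head_com_first_point:
        com = _component_com(img, comp)
        path = np.vstack([com, path])

    # mild smoothing removes pixel jaggies before spline upscaling
    if len(path) >= 7:
        sm = np.column_stack([
            np.convolve(path[:, 0], np.ones(5) / 5, mode="valid"),
            np.convolve(path[:, 1], np.ones(5) / 5, mode="valid"),
        ])
        path = np.vstack([path[:1], sm, path[-1:]])
    n_out = settings.upscale_fold * len(path)
    if len(path) >= 4:
        tck, _ = splprep([path[:, 0], path[:, 1]], s=len(path) * 0.05, k=3)
        u = np.linspace(0, 1, n_out)
        path = np.column_stack(splev(u, tck))
    else:
        u0 = np.linspace(0, 1, len(path))
        u = np.linspace(0, 1, n_out)
        path = np.column_stack([np.interp(u, u0, path[:, 0]), np.interp(u, u0, path[:, 1])])
    path = _extend_end(path[::-1], img)[::-1]  # head end
    path = _extend_end(path, img)  # tip end
    return path


def _sample_line(img: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [pts[:, 1], pts[:, 0]], order=1, mode="nearest")


def _extend_end(path: np.ndarray, img: np.ndarray, step_px: float = 0.25, max_px: float = 12.0) -> np.ndarray:
    """Extend the last point of ``path`` to the true ridge end.

    Skeletonization retracts the end of a thresholded ribbon by roughly half
    its width, while blurring makes the ridge appear to continue beyond its
    end: the along-ridge intensity crosses half its interior level about
    ``w_half`` (the ridge half-width at half-maximum, i.e. the apparent tip
    extension of the point-spread) beyond the true end.  The end point is
    therefore placed at the outward half-maximum crossing minus the local
    cross-section half-width at half-maximum.
    """
    if len(path) < 12:
        return path
    ref = float(np.median(_sample_line(img, path[-10:])))
    if ref <= 0:
        return path
    tang = path[-1] - path[-8]
    nrm = np.linalg.norm(tang)
    if nrm == 0:
        return path
    tang /= nrm

    u = np.arange(step_px, max_px, step_px)
    ray = path[-1][None, :] + u[:, None] * tang[None, :]
    inb = (ray[:, 0] >= 0) & (ray[:, 0] <= img.shape[1] - 1) & \
          (ray[:, 1] >= 0) & (ray[:, 1] <= img.shape[0] - 1)
    if not inb.all():
        ray, u = ray[inb], u[inb]
    if len(u) == 0:
        return path
    prof = _sample_line(img, ray)
    below = np.flatnonzero(prof < 0.5 * ref)
    if len(below) == 0:
        return path  # never drops: nothing reliable to extend to
    j = below[0]
    if j == 0:
        crossing = 0.0
    else:
        v0, v1 = prof[j - 1], prof[j]
        frac = (0.5 * ref - v0) / (v1 - v0) if v1 != v0 else 0.0
        crossing = u[j - 1] + frac * step_px

    # local cross-section half-width at half max = apparent tip extension
    normal = np.array([-tang[1], tang[0]])
    un = np.arange(0.0, 8.0, step_px)
    w_sides = []
    for sgn in (1.0, -1.0):
        cs = path[-1][None, :] + (sgn * un)[:, None] * normal[None, :]
        np.clip(cs[:, 0], 0, img.shape[1] - 1, out=cs[:, 0])
        np.clip(cs[:, 1], 0, img.shape[0] - 1, out=cs[:, 1])
        p = _sample_line(img, cs)
        b = np.flatnonzero(p < 0.5 * p[0])
        if len(b):
            w_sides.append(un[b[0]])
    if not w_sides:
        return path
    w_half = float(np.mean(w_sides))

    ext = crossing - w_half
    if ext <= step_px:
        return path
    n_new = int(ext / step_px)
    extra = path[-1][None, :] + (step_px * np.arange(1, n_new + 1))[:, None] * tang[None, :]
    return np.vstack([path, extra])


def _end_brightness(img: np.ndarray, pt: np.ndarray, radius: int = 4) -> float:
    y, x = int(round(pt[1])), int(round(pt[0]))
    sl = img[max(0, y - radius) : y + radius + 1, max(0, x - radius) : x + radius + 1]
    return float(sl.mean()) if sl.size else 0.0


def _component_com(img: np.ndarray, comp: np.ndarray) -> np.ndarray:
    cy, cx = ndimage.center_of_mass(img * comp)
    return np.array([cx, cy])


def _tangents(points: np.ndarray, max_vec: int, smooth: bool, window: int) -> np.ndarray:
    """Unit tangents from symmetric chords of up to ``max_vec`` points."""
    n = len(points)
    k = np.minimum(max_vec // 2, np.minimum(np.arange(n), n - 1 - np.arange(n)))
    k = np.maximum(k, 1)
    i = np.arange(n)
    lo = np.clip(i - k, 0, n - 1)
    hi = np.clip(i + k, 0, n - 1)
    t = points[hi] - points[lo]
    if smooth and n >= 3:
        w = min(window, (n - 1) // 2)
        kern = np.ones(2 * w + 1)
        norm = np.convolve(np.ones(n), kern, mode="same")
        t = np.column_stack([
            np.convolve(t[:, 0], kern, mode="same") / norm,
            np.convolve(t[:, 1], kern, mode="same") / norm,
        ])
    nrm = np.linalg.norm(t, axis=1)
    nrm[nrm == 0] = 1.0
    return t / nrm[:, None]


def _gaussian_center_fit(
    profiles: np.ndarray, u: np.ndarray, min_rel: float = 0.3, min_samples: int = 5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row Gaussian center/width by weighted log-quadratic least squares.

    For samples I(u) of a Gaussian ridge, ln I is an exact quadratic in u;
    fitting it with weights I^2 (the standard variance weighting for
    log-transformed data) recovers center and SD in closed form, row-wise
    vectorized.  Returns (center, sigma, valid).
    """
    p = np.asarray(profiles, dtype=float)
    rowmax = p.max(axis=1, keepdims=True)
    use = (p > np.maximum(min_rel * rowmax, 1e-12)) & (rowmax > 0)
    w = np.where(use, p**2, 0.0)
    logp = np.where(use, np.log(np.where(use, p, 1.0)), 0.0)
    basis = np.column_stack([np.ones_like(u), u, u**2])  # (m, 3)
    # normal equations per row: (B^T W B) c = B^T W y
    bw = w[:, :, None] * basis[None, :, :]  # (n, m, 3)
    ata = np.einsum("nmi,mj->nij", bw, basis)
    atb = np.einsum("nmi,nm->ni", bw, logp)
    ok = use.sum(axis=1) >= min_samples
    center = np.zeros(len(p))
    sigma = np.full(len(p), np.nan)
    dets = np.abs(np.linalg.det(ata)) > 1e-12
    ok &= dets
    if ok.any():
        coef = np.linalg.solve(ata[ok], atb[ok][:, :, None])[:, :, 0]  # (k, 3): c0 + c1 u + c2 u^2
        c1, c2 = coef[:, 1], coef[:, 2]
        safe_c2 = np.where(c2 < 0, c2, -1.0)
        ctr = -c1 / (2 * safe_c2)
        sig = np.sqrt(-1.0 / (2 * safe_c2))
        inside = (c2 < 0) & (np.abs(ctr) <= u.max())
        okidx = np.flatnonzero(ok)
        center[okidx[inside]] = ctr[inside]
        sigma[okidx[inside]] = sig[inside]
        ok[okidx[~inside]] = False
    return center, sigma, ok


def refine_normals(
    points: np.ndarray,
    preprocessed: np.ndarray,
    settings: TraceSettings = TraceSettings(),
    pixel_size_um: float = 0.65,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sub-pixel refinement of an ordered point list on its image.

    Samples the intensity along the local normal within
    +/- ``normal_radius_um`` of each point, fits a 1-D Gaussian and moves the
    point to the fitted center; positions and fit widths are then smoothed
    over +/- ``smoothing_window_points`` neighbors lying within
    ``smoothing_distance_um``.  Points whose fit fails keep their input
    position and are flagged; the first ``head_exclude_points`` points are
    never relocated (the bright head saturates the normal profile).

    Returns ``(points, width_um, quality)``.
    """
    settings.validate()
    pts = np.asarray(points, dtype=float).copy()
    n = len(pts)
    img = np.asarray(preprocessed, dtype=float)
    quality = np.zeros(n, dtype=int)

    tang = _tangents(pts, settings.max_vector_len_points, settings.smooth_normal_for_fit,
                     settings.smoothing_window_points)
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])

    r_px = settings.normal_radius_um / pixel_size_um
    u = np.arange(-r_px, r_px + 1e-9, 0.25)
    sample_xy = pts[:, None, :] + u[None, :, None] * normals[:, None, :]
    prof = ndimage.map_coordinates(
        img, [sample_xy[:, :, 1].ravel(), sample_xy[:, :, 0].ravel()], order=1, mode="nearest"
    ).reshape(n, len(u))
    center, sigma, ok = _gaussian_center_fit(prof, u)

    quality[~ok] = QUALITY_FIT_FAILED
    move = ok.copy()
    if settings.exclude_head_from_correction and settings.head_exclude_points > 0:
        head = min(settings.head_exclude_points, n)
        move[:head] = False
        quality[:head] = QUALITY_HEAD_EXCLUDED
    pts[move] += center[move, None] * normals[move]
    width_px = np.where(ok, sigma, np.nan)

    if settings.repeat_gauss_fit_after_binarization:
        prof2 = ndimage.map_coordinates(
            img,
            [(pts[:, None, :] + u[None, :, None] * normals[:, None, :])[:, :, 1].ravel(),
             (pts[:, None, :] + u[None, :, None] * normals[:, None, :])[:, :, 0].ravel()],
            order=1, mode="nearest",
        ).reshape(n, len(u))
        c2, s2, ok2 = _gaussian_center_fit(prof2, u)
        redo = ok2 & move
        pts[redo] += c2[redo, None] * normals[redo]
        width_px = np.where(ok2, s2, width_px)

    pts = _window_smooth(pts, pts, settings, pixel_size_um)
    wcol = width_px[:, None]
    width_px = _window_smooth(wcol, pts, settings, pixel_size_um)[:, 0]
    return pts, width_px * pixel_size_um, quality


def _window_smooth(
    values: np.ndarray, pts: np.ndarray, settings: TraceSettings, pixel_size_um: float
) -> np.ndarray:
    """Moving average over +/- window neighbors within the accepted xy distance."""
    n = len(values)
    w = settings.smoothing_window_points
    off = np.arange(-w, w + 1)
    raw = np.arange(n)[:, None] + off[None, :]
    idx = np.clip(raw, 0, n - 1)
    # symmetric window, shrunk near the ends: a one-sided window would drag
    # the end points inward along the arc
    half = np.minimum(w, np.minimum(np.arange(n), n - 1 - np.arange(n)))
    inwin = (raw == idx) & (np.abs(off)[None, :] <= half[:, None])
    d = np.linalg.norm(pts[idx] - pts[:, None, :], axis=2) * pixel_size_um
    ok = inwin & (d <= settings.smoothing_distance_um)
    vals = values[idx]  # (n, 2w+1, k)
    finite = np.isfinite(vals).all(axis=2)
    ok &= finite
    wts = ok.astype(float)
    denom = wts.sum(axis=1)
    denom[denom == 0] = 1.0
    out = np.einsum("nw,nwk->nk", wts, np.nan_to_num(vals)) / denom[:, None]
    allnan = ~finite.any(axis=1)
    out[allnan] = values[allnan]
    return out


def trace_frame(
    frame: np.ndarray,
    settings: TraceSettings = TraceSettings(),
    pixel_size_um: float = 0.65,
    frame_index: int = 0,
    head_xy_px: Optional[tuple[float, float]] = None,
) -> TracedFrame:
    """Full single-frame pipeline: preprocess, trace, refine, to µm."""
    pre = preprocess_frame(frame, settings)
    pts = trace_midline(pre, settings, head_xy_px=head_xy_px)
    pts, width_um, quality = refine_normals(pts, pre, settings, pixel_size_um)
    if settings.filter_points_by_gauss_fits:
        keep = quality != QUALITY_FIT_FAILED
        pts, width_um, quality = pts[keep], width_um[keep], quality[keep]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1) * pixel_size_um
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    return TracedFrame(
        frame_index=frame_index,
        x_um=pts[:, 0] * pixel_size_um,
        y_um=pts[:, 1] * pixel_size_um,
        arclen_um=arclen,
        fit_width_um=width_um,
        quality=quality,
    )


def trace_movie(
    movie: Movie,
    settings: TraceSettings = TraceSettings(),
    head_xy_px: Optional[tuple[float, float]] = None,
) -> FlagellarTrace:
    """Trace every frame of a movie; failed frames are kept as placeholders.

    The head hint defaults to ``movie.meta['head_xy_px']`` when present
    (synthetic movies record their tether point there).
    """
    if head_xy_px is None and "head_xy_px" in movie.meta:
        head_xy_px = tuple(movie.meta["head_xy_px"])
    frames: list[TracedFrame] = []
    empty = np.empty(0)
    for i in range(movie.n_frames):
        try:
            frames.append(
                trace_frame(movie.stack[i], settings, movie.pixel_size_um, i, head_xy_px)
            )
        except (TraceFailure, ValueError) as exc:
            frames.append(
                TracedFrame(i, empty, empty, empty, empty, np.empty(0, dtype=int),
                            ok=False, message=str(exc))
            )
    if settings.unify_start_points:
        _unify_start_points(frames, movie.pixel_size_um)
    return FlagellarTrace(frames=frames, pixel_size_um=movie.pixel_size_um,
                          frame_rate_hz=movie.frame_rate_hz, settings=settings)


def _unify_start_points(frames: list[TracedFrame], pixel_size_um: float) -> None:
    """Snap every frame's first point to the across-frame median head position.

    The tethered head does not move between frames; pinning the traced start
    point to its median location removes residual head jitter so arc length 0
    refers to the same material point in every frame.
    """
    heads = np.array([[f.x_um[0], f.y_um[0]] for f in frames if f.ok and f.n_points])
    if len(heads) == 0:
        return
    med = np.median(heads, axis=0)
    for f in frames:
        if not f.ok or f.n_points == 0:
            continue
        f.x_um[0], f.y_um[0] = med
        seg = np.linalg.norm(np.diff(f.xy_um, axis=0), axis=1)
        f.arclen_um = np.concatenate([[0.0], np.cumsum(seg)])


def write_trace_csv(trace: FlagellarTrace, path) -> None:
    rows = []
    for f in trace.frames:
        if not f.ok:
            continue
        rows.append(pd.DataFrame({
            "frame": f.frame_index,
            "point_index": np.arange(f.n_points),
            "x_um": f.x_um,
            "y_um": f.y_um,
            "arclen_um": f.arclen_um,
            "fit_width_um": f.fit_width_um,
            "quality_flag": f.quality,
        }))
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["frame", "point_index", "x_um", "y_um", "arclen_um", "fit_width_um", "quality_flag"]
    )
    df.to_csv(path, index=False)


def read_trace_csv(path, pixel_size_um: float, frame_rate_hz: float,
                   settings: TraceSettings = TraceSettings()) -> FlagellarTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    frames = []
    for fi, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("point_index")
        frames.append(TracedFrame(
            frame_index=int(fi),
            x_um=grp["x_um"].to_numpy(),
            y_um=grp["y_um"].to_numpy(),
            arclen_um=grp["arclen_um"].to_numpy(),
            fit_width_um=grp["fit_width_um"].to_numpy(),
            quality=grp["quality_flag"].to_numpy(dtype=int),
        ))
    return FlagellarTrace(frames=frames, pixel_size_um=pixel_size_um,
                          frame_rate_hz=frame_rate_hz, settings=settings)
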