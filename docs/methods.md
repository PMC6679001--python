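# Methods

This note documents the models, algorithms and numerical choices behind
`flagbeat`, in the order the pipeline runs them.

## Synthetic waveform model

The generator produces a planar flagellum parameterized in the tangent
angle,

    psi(s, t) = psi0(s) + A(s) * sin(2*pi*f*t - 2*pi*s/lambda),

with arc length `s` (µm), beat frequency `f` (Hz), spatial wavelength
`lambda` (µm), amplitude envelope `A(s)` (rad) and a static tangent-angle
profile `psi0(s)`. The midline is the integral of the unit tangent from a
fixed head point (midpoint rule on a 0.25 µm grid), emulating a tethered
sperm whose head sticks to the chamber surface; head yaw is not simulated.
Parameterizing in tangent angle (rather than transverse displacement) makes
the curvature-angle ground truth exact, because the pipeline's kinematic
variable is itself an angle.

Defaults describe a realistic mouse-sperm recording: length 80 µm,
wavelength 60 µm, amplitude 0.5 rad, 20 Hz beat sampled at 200 fps for
400 frames at 0.65 µm/px. These scales are modelling choices, not
measurements.

**Static asymmetry.** A *constant* psi0 is a rigid rotation of the whole
cell and therefore carries no beat asymmetry — every rotation-invariant
bending measure is blind to it. To inject a static *curvature-angle*
offset theta0 (the quantity the asymmetry statistic estimates), use
`arc_offset(theta0)`, the tangent ramp `theta0 * s / d_ref`: a circular arc
of radius `d_ref/theta0` whose chord-to-chord curvature angle is exactly
theta0 at every interior position. The ground-truth asymmetry profile is
accordingly computed as the |static curvature angle| of the time-averaged
shape, which also makes the symmetric-beat case exactly zero over integer
beat cycles.

**Rendering.** Each midline is drawn as a ridge with Gaussian cross-section
(SD 1.5 px) by evaluating `peak * exp(-d^2/2 sigma^2)` on the exact
distance `d` to the densely sampled midline (KD-tree query restricted to a
dilated band around the curve). A brighter Gaussian blob (2× peak, SD 2 px)
marks the tethered head — in dark-field the head scatters far more light
than the flagellum — and anchors head-side ordering when no tether hint is
given. A flat camera baseline (3000 counts) plus seeded additive Gaussian
noise completes the model; movies are 16-bit TIFF. Deliberately *not*
modelled: Poisson shot noise (dark-field SNR is high), out-of-focus blur,
3-D motion, hydrodynamics, intensity falloff toward the thin endpiece.
Passing recovery tests on these movies therefore demonstrates correctness
of the algorithms, not robustness to every real-world artifact; the main
omissions that could matter on real data are the endpiece fading into the
noise floor and debris touching the flagellum.

## Tracing

Per frame: Gaussian pre-blur (sigma 0.5 px) → rolling-ball background
subtraction (radius 5 px, scikit-image) → tracer-internal blur
(sigma 1.0 px; the two blurs are applied sequentially) → triangle threshold
→ largest connected component → skeletonization → longest geodesic path
(8-connected pixel graph, euclidean edge weights, double Dijkstra sweep;
side branches are dropped by construction and warned about above 5 px) →
3-fold spline upscaling → sub-pixel Gaussian refinement → windowed
smoothing.

The triangle threshold maximizes the perpendicular distance between the
histogram and the straight line from its peak to the farthest non-empty
bin, with both axes normalized to the peak-to-far span so the answer is
invariant to count scaling and trailing empty bins; degenerate histograms
(span < 2 bins or a flat span) return the peak bin with a flag.

**End correction.** Two opposing biases meet at the flagellar ends:
skeletonization retracts the end of a thresholded ribbon by about half its
width, while blurring makes the ridge appear to continue ~1 half-width
*beyond* its true end (the point-spread's apparent tip extension). Each end
point is therefore placed at the outward half-maximum crossing of the
along-ridge intensity minus the local cross-section half-width at half
maximum. Likewise, the position/width smoothing windows are forced to be
symmetric (shrinking near the ends): a one-sided moving average would drag
the end points inward along the arc. Together these keep the recovered arc
length of a rendered quarter circle within ~1 % of truth.

**Sub-pixel refinement.** The intensity along each point's local normal
(±5 µm, 0.25 px sampling, bilinear interpolation) is fitted with a 1-D
Gaussian via weighted log-quadratic least squares (weights I², samples
above 30 % of the row maximum). For a Gaussian profile the log is exactly
quadratic, so the fit is closed-form and exact in the noise-free case, and
it vectorizes across all points of a frame — an iterative optimizer would
be orders of magnitude slower for no accuracy gain. Fits that fail
(non-concave, off-range center, too few samples) leave the point in place
with a quality flag. The first 10 points are never relocated (the bright
head saturates the normal profile); tangents are smoothed before normals
are formed; positions and fit widths are then averaged over ±15 neighbors
within 9.6 µm. Optional stages — prepending the head center of mass,
dropping failed-fit points, repeating the fit, unifying start points across
frames (median head position) — are implemented but off by default. The
semantics of a "head rotation matrix radius" in the historical settings
vocabulary are not fully documented anywhere we know of; it is interpreted
here as the number of head points excluded from correction.

Measured on the synthetic movies at 10 % ridge-peak noise: midline RMS
error ≈ 0.2 px over 5–90 % of the arc length, arc-length SD across a beat
≈ 1 % of the mean.

## Curvature angle

Traces are resampled onto the fixed grid s = 0, 1, 2, … µm (cubic
interpolation of x(s), y(s); the grid spans the longest frame and positions
beyond a frame's own length are masked). The curvature angle is

    theta(s) = signed angle from chord [s - d, s] to chord [s, s + d],

d = 10 µm, sign from the z-component of the chord cross product (so
mirroring flips it; rigid motions leave it unchanged). On a circle the two
chords are tangent directions d apart, giving exactly theta = d/R — the
oracle used in the tests. Whether the historical definition used
chord-to-chord or tangent-to-tangent angles is not documented; the two
converge for smooth curves and the arc identity pins this implementation's
convention. At the ends the chords are truncated to the available arc
(one-sided); frames shorter than d are fully masked, and a strict
`mask_ends` variant masks everything within d of either end. The 1 µm grid
step puts 46 grid points into the 15–60 µm frequency-averaging band.

## Spectral analysis

Per position, 400-frame windows (non-overlapping, starting at frame 0,
spectra averaged if the movie is longer), mean-subtracted, rectangular
window, no zero padding: the bin width is frame_rate/400 = 0.5 Hz at
200 fps and bin-centered test tones stay exact, which keeps the test
oracles closed-form. Masked samples are mean-imputed up to 5 % per window;
positions with more masking are skipped. f₁ is the highest-power bin above
DC. f₂ is the second-highest *local maximum* — not the second-largest bin,
which would usually be a leakage shoulder of f₁ — and must carry at least
`min_rel_power` = 5 % of the f₁ peak power. Without that floor, f₂ on a
clean recording falls on the small geometric harmonic at 2f (the chord
angle is a mildly nonlinear functional of the tangent wave, so a pure
tangent-angle oscillation at f leaks a few percent of power to 2f) or on a
noise bin, and the merge (f₁+f₂)/2 would be biased away from f by
construction. With the floor, a genuine second peak (e.g. a two-tone beat
at amplitude ratio 0.5, power ratio 0.25) is kept, while harmonic and noise
peaks fall back to f₂ = f₁ and the merge is a no-op. An
`exclude_harmonics` option additionally rejects (half-)integer multiples of
f₁. The sperm-level frequency is the plain mean of (f₁+f₂)/2 over
15 µm ≤ s ≤ 60 µm.

## Asymmetry and statistics

a(s) = |time average of valid theta(s, ·)| in degrees; positions with under
50 % valid frames are masked. The average should span integer beat cycles —
with 400 frames at 200 fps every frequency on the 0.5 Hz grid does.

Difference curves: paired by sperm id when both groups match (the default —
the same tethered cell is typically measured before and after stimulation),
reporting mean ± SD across sperm of the within-sperm change; otherwise the
difference of group means with pooled SD.

Significance: the factors of the two-way ANOVA are condition × flagellar
position with sperm as replicates (the design is a reconstruction; the
position factor is what yields per-position p-values). The pooled
within-cell mean square supplies the error term, and conditions are
compared within each position by Tukey's honestly significant difference
(studentized range, k = number of conditions; for k = 2 this reduces
exactly to a two-sided t-test and is computed via the t distribution for
speed). p(s) < 0.05 positions are reported as maximal contiguous regions
with each region's minimum p. Zero residual variance and cells with fewer
than two sperm raise informative errors instead of returning NaN.

This is a pointwise level-α analysis along a correlated profile: isolated
false-positive positions appear at the chance rate and neighboring
positions are not independent. A repeated-measures or mixed-effects model
(sperm as random effect), or cluster-based permutation inference, would be
the more principled alternative and is deliberately out of scope; the
omnibus ANOVA table is attached to the comparison for reference.

**Calibration simulations** run on synthetic asymmetry *profiles* rather
than full movies: each sperm's profile is a 5° baseline plus a smooth
Gaussian-process deviation (SD 1°, correlation length 15 µm — between-sperm
differences in real data are smooth shape differences) plus 0.5° of iid
per-position noise, 80 positions at 1 µm. Null simulations (10 vs 10
sperm, 20 replicates) give a pointwise false-positive rate of ~4–5 %; a 3°
effect confined to s < 30 µm is detected as a significant region
overlapping [0, 30] µm in every replicate while positions beyond 45 µm
stay at the chance rate.

## One-beat-cycle projection

n = round(frame rate / beat frequency) consecutive traces (nearest-integer
rounding; the ratio is rarely integer) are overlaid in colormap order with
a 50 µm scale bar. The overlay is built from the vector traces; each source
frame is used exactly once.

## Problem sizes and determinism

The validation suite uses movies of 400 frames (frequency and asymmetry
recovery; 20 replicates spanning 10/15/20/27 Hz) and 20–40 frames
(tracing accuracy over 1–4 beat cycles), all at 10 % ridge-peak noise, and
20-replicate profile simulations for the statistics. All randomness flows
through explicit seeds: identical seeds give bit-identical movies and
byte-identical pipeline CSVs.

## Known limitations

- The tracer assumes exactly one flagellum-like component per frame;
  multi-sperm scenes must be cropped first. Self-crossing waveforms (deep
  3-D rolls projected to 2-D) would break the longest-path ordering.
- Sub-bin frequency resolution is not attempted: a beat at 20.25 Hz reads
  as 20 or 20.5 Hz. Window length trades resolution against stationarity.
- The asymmetry statistic conflates any static bend with beat asymmetry;
  it cannot distinguish a curved resting shape from an asymmetric dynamic
  envelope.
- End regions (within ~10 µm of head and tip) use one-sided chords and are
  the least reliable part of every profile; the 15–60 µm band used for
  sperm-level summaries avoids them.
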