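# Methods

`wormlf` reconstructs the 3D posture and locomotion of *C. elegans* from raw
light field micrographs and quantifies behaviour from the resulting skeleton
time series. This note records the models, the numerical choices, and what
the synthetic validation does and does not establish.

## Light field model

A microlens array at the native image plane turns one camera exposure into a
tiled mosaic of circular subimages. Rectification resamples the mosaic onto
an axis-aligned lattice, producing a 4D radiance array `L(x, y, u, v)`:
`(x, y)` index microlenses (spatial samples), `(u, v)` index pixels within a
subimage (angular samples, centred on the chief ray). Samples outside an
inscribed circular aperture (default 0.95 of the subimage half-pitch) are
invalid — the corners of a square tile receive no light in the instrument —
and every operation carries per-sample validity weights so that integration
renormalizes automatically at field edges.

Computational refocusing shears the array parallel to the spatial plane,

    L_alpha(x, y, u, v) = L(u(1 − 1/alpha) + x/alpha,
                            v(1 − 1/alpha) + y/alpha, u, v),

and the shear maps to axial position through

    dz = P (1 − 1/alpha) F / M²,

with `P` the subimage pitch in camera pixels, `F` the microlens focal length
(µm) and `M` the transverse magnification. Reachable depths are bounded by
`P·F/M²`. With the nominal synthetic optics (P = 19 px, F = 10 mm, M = 10,
6.5 µm camera pixels) the bound is 1.9 mm and the spatial sample spacing in
object space is 12.35 µm.

Two refocus operators are provided. `refocus` implements the equation above
(a group action: composing shears multiplies the alphas) and is the
persisted, user-facing operator. `shift_refocus` translates each pinhole
view by `(1 − 1/alpha)(u, v)` — the same focusing operation without the
1/alpha output magnification. Depth-cue sweeps use the shift form so that a
given spatial pixel interrogates the same scene point at every shear value;
with the magnified form, a pixel drifts across the scene as alpha varies and
a degenerate photo-consistency minimum appears wherever the drifted pixel
lands on featureless background.

Both operators interpolate bilinearly, which keeps them linear in the
radiance. The response sweep applies a constant half-pixel sampling dither to
every slice: without it, alpha = 1 is the only shear needing no
interpolation, making the native-focus slice artificially the sharpest and
biasing the defocus cue toward zero depth.

## Lattice rectification

The subimage pitch and orientation are initialized from the dominant peak of
the windowed 2D Fourier spectrum (a genuine lattice peak is a sharp isolated
maximum on its frequency ring; smooth content yields ring-prominence ratios
of only a few, and the detector rejects images below a prominence of 30).
The peak angle is sign-ambiguous under the square-lattice fold, so both
candidates enter a coarse offset scan, followed by Nelder–Mead refinement of
(pitch, orientation, offset) that maximizes a disc-tile contrast: mean
intensity sampled at subimage centres minus mean intensity at tile corners,
which vignetting darkens regardless of scene content. On clean mosaics this
recovers the pitch to well under 0.01 px. When a flat-field background
exposure is available, the lattice should be estimated from it rather than
from a scene frame: scene content and sensor noise can bias the fit by
~0.1 px in offset, which we measured to inflate the noisy calibration RMSE
roughly eightfold.

## Depth estimation

For each shear in a sweep (default: 256 values spaced uniformly in depth
over a configured range), the refocused, view-integrated image yields two
per-pixel responses:

* **defocus** `D_alpha`: box-mean (window 5 px) of the absolute 5-point
  Laplacian — sharpness, maximal in focus;
* **correspondence** `C_alpha`: box-mean (window 5 px) of the angular
  standard deviation across valid views (population 1/N normalization) —
  photo-consistency, minimal in focus.

Per pixel, the cue optima are the argmax/argmin over the sweep, with a
confidence defined as the ratio of the response at the optimum to the
next-best strict local extremum (epsilon-flattened at 1e-12), clipped to
[1, cap] with cap 10; a flat response gives confidence 1 and an
"unreliable" flag.

The cues are fused by minimizing, over the sweep's discrete labels,

    E(z) = Σ_p [ w_d(p)·|z_p − z_d(p)| + w_c(p)·|z_p − z_c(p)| ]
         + λ Σ_{p~q} min(|z_p − z_q|, τ),

with weights `w = confidence / cap` (zero for unreliable pixels), λ = 0.5
and τ = 10 labels by default. The "dp" solver is exact Viterbi over whole
scanlines; on narrow problems (when `K^min(H, W)` is small) it switches to
an exact dynamic program over column super-labels, so small instances are
solved globally — the test suite verifies agreement with exhaustive
enumeration on all random instances up to 6 pixels and 4 labels. On full
frames, scanline sweeps alternate over rows and columns from multiple
initializations (confidence-weighted mean and each cue's own labelling),
keeping the lowest energy. ICM is available as a configurable alternative.

Calibration fits an ordinary least-squares line of estimated on known depth
and reports gradient, intercept, R² and residual RMSE. Downstream correction
divides estimates by the gradient, so corrected estimates regress on known
depth with unit slope (multiplying by a sub-unity gradient would shrink
rather than correct them). Per-frame summaries over the phantom footprint
use the median, which is insensitive to edge pixels whose response windows
mix in background.

**Precision budget.** Across the full 1.9 mm reachable band the total
disparity at the aperture edge is only P/2 ≈ 9.5 px, so sub-pixel matching
at ~0.1 px limits single-pixel depth precision to roughly 20–25 µm at these
optics. Frame-level summaries average hundreds of pixels and reach a few µm,
which is why the calibration benchmarks (R² ≥ 0.9989 and RMSE within the
11.1 µm instrument bound) hold with margin while per-pixel error bounds are
set in sweep-step units at a ~20 µm step.

## Worm reconstruction

Segmentation of the on-axis pinhole view: adaptive local-mean threshold
(window 51 px, offset 0.02 of the normalized range, worm darker than
background), largest connected component, hole filling, morphological
closing (disc radius 3), then a region-based (Chan–Vese-type) morphological
active contour with a fixed iteration budget (30), keeping the darker phase
and re-enforcing single-component/hole-free topology. Masks with less than
`min_area` (200 px by default; scale to the image) raise "no worm found".

Depth maps are filtered with a two-frame temporal Kalman step: the previous
measurement (variance r) propagated through process noise q is fused with
the current measurement (variance r), giving
`x_t = z_{t−1} + K(z_t − z_{t−1})`, `K = (r + q)/(2r + q)`; q → ∞ recovers
the raw measurements and a constant pixel is never altered.

The midline is the longest geodesic path through the thinned mask
(8-connected pixel graph, Dijkstra twice; side branches shorter than
`prune_len` = 8 px are pruned first; more than two surviving endpoints is an
error). Depth along the midline is the median over the local cross-section
(a disc of the local half-width from the distance transform) — a robust
stand-in for the contrast-weighted average over the worm thickness that the
instrument reports. A cubic smoothing spline (fixed penalty, chosen for
frame-to-frame stability over GCV) through the (x, y, z) samples is
resampled at 26 equally spaced arc-length positions → 25 segments.

Head/tail identity is not observable in a single frame without texture
cues; endpoint order is chosen to maximize continuity with the previous
frame, with a `--flip-head` override in the CLI. Frames whose thinned
skeleton contains a cycle, keeps more than two endpoints, or whose area
exceeds 1.6 × (midline length × modal width) are flagged self-occluded and
dropped from skeleton output (an automated version of excluding coiled
postures, which this representation cannot reconstruct).

Each segment's orientation is described by the azimuth theta in the xy
plane (unwrapped along the body) and the elevation phi out of the xy plane
(zero for planar postures; an inclination-from-z convention would differ by
a constant that mean-zeroing removes). Both 25-vectors are mean-zeroed; the
removed means, segment lengths and origin are retained, so
`angles_to_skeleton` reintegrates the exact coordinates.

## Behaviour metrics

Centroid speed is the forward difference of the skeleton centroid.
Non-planar deviation is R₃/R₁, the ratio of the shortest to longest
principal axes of the 26-point cloud (PCA of the 3×3 covariance; 0 for
planar or collinear postures). Curving rate is the angle between successive
centroid *displacement* vectors per unit time — the literal per-frame
position-vector formula is origin-dependent and cannot mean "curving"; the
angle is folded to [0, π/2] through an absolute value by default, with a
signed-angle option. Directional autocorrelation is
`D(n) = (1/(N−n)) Σ v_i·v_{i+n}` over unit displacement directions
(displacement, not body-axis, directions), and its decay is fit by
`A·exp(−b t)` with b ≥ 0.

Forward runs are maximal intervals with centroid speed ≥ 10 µm/s, a
positive component of motion along the tail-to-nose axis, sustained
≥ 0.5 s; the thresholds are package choices. Explored volumes are
axis-aligned bounding boxes (body: all points; nose: first point), in mm³;
a convex-hull variant would be stricter but the box matches how such volumes
are normally reported. Strain comparisons first average every metric per
worm, report group mean ± SEM over worms, and test differences with Welch's
unequal-variance t-test (decay constants compared on per-worm exponential
fits).

## Postural modes and the rhodonea model

Eigenworms are the principal components of the concatenated mean-zeroed
angle-vector ensemble (column-centred SVD); each mode's sign is fixed so its
largest-magnitude element is positive. Azimuthal and polar modes of rolling
locomotion are closely similar, so a single shared basis — the azimuthal
set — projects both channels; the ensemble column mean is subtracted only
from the channel that built the basis (the other channel's ensemble mean is
zero to numerical precision). A flag allows separate bases for comparison.

For a swimming worm the paired first-mode amplitudes follow

    a^theta(t) = A cos[k(at + c)] cos(at + c),
    a^phi(t)   = A cos[k(at + c)] sin(at + c),

a rose curve whose parameter k is the ratio of undulation frequency to the
slow rotation of the oscillation plane (body roll). The fit initializes
k·a from the dominant spectral peak of `a_theta² + a_phi²` (the squared
envelope oscillates at 2ka), scans k on a coarse grid (0.5–20, step 0.25)
with a phase scan dense enough to resolve the fast phase k·c, refines
(A, k, a, c) jointly by bounded least squares from each initialization, and
polishes the best candidate to tight tolerances. k is fitted independently
for modes 1 and 2 and summarized as mean ± SD.

## Synthetic phantoms

The generator produces ground truth at three levels, all reproducible from a
seed (identical parameters and seed give bit-identical output).

*Locomotion*: a traveling bending wave
`beta(s, t) = A sin(2πs/λ − 2πft)` (defaults: amplitude 0.6 rad, wavelength
1.5 body lengths, 0.5 Hz, 25 segments of a 1 mm body, 20 frames/s, angular
noise 0.05 rad) whose oscillation plane rolls about the body axis once per
`roll_ratio` undulation cycles, phase-locked so the eigenmode amplitudes
follow the rose curve with k = roll_ratio (default 8.5). Tangent angles are
integrated with fixed segment lengths, so body length is conserved exactly;
the centroid translates at 50 µm/s.

*Scene*: a tube swept along the midline. The footprint is the lateral
projection (exact point-to-segment distances, so the boundary is not eroded
by discrete midline sampling); the per-pixel depth is the z of the nearest
midline point — the centreline dominates a contrast-weighted average over
the body thickness; intensity darkens with the square root of the
normalized chord (DIC-like sharp edges) modulated by a smooth seeded
texture so the depth cues are informative across the body.

*Light field*: each valid view is the scene shifted laterally by
`(1 − 1/alpha(dz))(u, v)` samples — exactly the disparity model the
reconstruction inverts, so pipeline validation is exact rather than
approximate. Depth is quantized into layers (1 µm or 128 layers, whichever
is coarser) and each layer is shifted with cubic-spline interpolation
(linear renderer shifts on top of the bilinear refocus produced measurable
pixel-locking bias in the correspondence cue). Per-subimage cos⁴-type
vignetting, a matching flat-field background mosaic, and seeded Gaussian
read noise are separate, optional degradations.

What passing synthetic tests shows: the reconstruction inverts its own
forward model to the stated accuracy, the statistics and fits are correct,
and the pipeline is stable under sensor noise and vignetting. What it does
not show: robustness to optical effects the renderer omits — depth-dependent
blur beyond the shear model, DIC shadowing, refraction inside the gel,
occlusion between overlapping body parts — or to head/tail texture cues it
does not emulate.

## Problem sizes used in validation

Calibration benchmarks run a 26×26-microlens rod phantom (494² px mosaic,
≤ 512²) at 21 depths over ±1 mm with a 256-step sweep; the worm depth
benchmark a 40×40 scene with an 81-step sweep over ±400 µm; eigenworm
compactness 2000 frames; rhodonea recovery 20 seeded noisy replicates.
These sizes keep each suite in the minutes range on one CPU while leaving
the measured margins (e.g. calibration RMSE ≈ 2.5 µm vs the 11.1 µm bound)
wide.

## Known limitations

* Self-occluded (coiled) postures are detected and excluded, not
  reconstructed.
* Per-pixel depth precision is bounded by the angular baseline
  (~20–25 µm at the nominal optics); thin-structure depth relies on the
  correspondence cue, as the defocus cue is flat at sub-pixel blur scales.
* Head/tail assignment is purely temporal; a sequence that starts flipped
  stays flipped unless overridden.
* The rectifier assumes a square lattice with |rotation| < 5° and
  near-integer pixels per subimage.
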