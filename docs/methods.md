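# Methods

This note documents the measurement models implemented in woundlab, the
conventions and numerical choices behind them, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Conventions

Image coordinates are 0-based `(row, col)`.  Track and point coordinates are
continuous `(x, y)` in μm with x rightward and y **downward** — the native
image convention, so tracks overlay their source movies without flipping.
All angles cross the I/O boundary in degrees and are measured in image
space; `woundlab.io.angle_image_to_math` is the single documented conversion
to the y-up mathematical convention (a sign flip).  Because every angular
quantity in the package is a *difference* of two angles measured in the same
space (displacement vs wound direction, nucleus→MTOC vs wound direction),
results are identical in either convention; rotation-equivariance tests
enforce this.

Default acquisition intervals follow the experiments being emulated:
15 min/frame for phase-contrast tracking movies, 3.7 s/frame for confocal
leading-edge movies, 0.4 s/frame for 30 s in FRAP.

## Track polarity metrics

For a nucleus track with points (tᵢ, xᵢ, yᵢ), trajectory length T is the
summed Euclidean step length and displacement D the start→end vector.
Straightness S = D/T, orientation O = cos(θ_D − θ_w), polarity index
P = S·O, speed T = T/Δt, speed D = D/Δt, polarized speed = speed D · P.
Whole-course speeds use each track's own elapsed time; per-interval
instantaneous speeds are deliberately not computed.

A cell with zero net displacement has no defined displacement angle, so O
and P are reported as missing (NaN), not zero — scoring them 0 would bias
group means toward "unpolarized".  Group summaries report the exclusion
count alongside n.  An exactly stationary cell reports all speeds as 0.
Front-line selection (which cells to track) is the caller's responsibility;
the module scores whatever tracks it is given.

Caveat: the group summary averages `displacement_angle_deg` arithmetically;
for angles clustered around 0°/360° this column is not meaningful (use the
orientation cosine instead, which is wrap-free).

## Wound coverage

`segment_wound` passes binary masks through, or segments phase-contrast
frames by local texture: cells are strongly textured and the cell-free
scratch smooth, so the local standard deviation (7 px uniform-filter
moments), Otsu-thresholded, separates them; the wound is the largest smooth
component.  The variance window erodes the smooth region by about half the
window radius, so a compensating 2 px dilation restores the boundary
(validated at Jaccard ≥ 0.99 on synthetic scenes).  This segmentation is a
stand-in validated only on synthetic data; real phase images may need
different texture scales.

Mean initial width = wound area / extent along the scratch axis, the
principal axis (SVD) of the wound pixels — scratches are assumed straight.
The 90 ± 5 μm gate is boundary-inclusive.  Coverage is
100·(area_Ti − area(Tf ∩ Ti))/area_Ti, clipped to [0, 100]: restricting Tf
to the initial footprint prevents cell loss elsewhere in the field from
producing >100% closure.

## Leading-edge superposition and filopodia

`superpose` compares the first and last mask of a time window: advance =
final∧¬initial, retraction = initial∧¬final, still = initial∧final; the
summary metric is advance area divided by the leading-edge perimeter, i.e.
the mean advance depth in μm (5 min windows are the conventional choice).

Filopodia are detected per frame as connected components of the residue of
the cell mask over its morphological opening ("envelope").  The opening
radius is 1.5 μm — large enough that 0.2–0.8 μm-wide filopodia are removed,
small enough that the lamellipodium contour survives.  It is computed with
two Euclidean distance transforms (erosion = interior distance > r,
dilation = distance from the eroded set ≤ r), equivalent to a disk opening
but much faster at these radii; envelopes are cached per frame.  Residue
components must touch the envelope (floating debris is discarded), reach a
length ≥ 1.0 μm and have mean width ≤ 0.8 μm.  Length is the Euclidean
extent from the attachment point to the farthest pixel plus one pixel —
for a thin unbranched protrusion this equals its geodesic skeleton length
while being immune to skeleton-tip erosion.  The 1.0/0.8/1.5 μm thresholds
were chosen so protrusions in the observed 1.5–7 μm length range are
detected; none of them is sharp in real data.

Detections are linked across consecutive frames to the nearest base within
1 μm, ties broken by smallest length change.  Only complete cycles are
kept: the maximum must fall strictly inside the observed lifetime and the
event must vanish before the movie ends (events still present at the last
frame, or never seen to grow/retract, are discarded).

Speeds follow the two-denominator definition: protrusion speed =
max\_length/(t\_max − birth), overall speed = max\_length/(death − birth),
where overall includes the dwell time at maximum length.  Because lengths
below the 1 μm detection floor are invisible, birth and death are
extrapolated to zero length from straight-line fits of the observed growth
and retraction segments (the dwell plateau is excluded from both fits);
the extrapolation is clamped to a physically plausible window and falls
back to ±1 frame when the segment is too short to fit.  On scripted scenes
this recovers both speeds within a few percent.

Classification: an event is *lamellipodic* if the envelope edge under its
base (±2.5 μm window) advances by more than 0.2 μm between the event's
first and last observed frame, else *exploratory*.  The threshold separates
an advancing lamellipodium from edge jitter in the synthetic scenes; on
real data it should be checked against the mask noise level.

Shape descriptors: circularity 4πA/P² and roundness 4A/(π·major\_axis²).
The perimeter is the length of the Gaussian-smoothed (σ = 2 px)
marching-squares boundary contour; pixel-step and Crofton estimators both
carry shape-dependent biases of ~5–10% (staircase on disks, axis alignment
on squares) that the smoothed contour avoids.

## Kymographs and actin waves

A kymograph samples each frame along a line ROI at 1 px spacing with
bilinear interpolation, averaging `width_px` parallel offsets.  The line is
drawn from the edge inward along the local normal; row 0 is the edge end,
which defines retrograde polarity (movement toward larger rows = away from
the edge = retrograde).

Ridge detection per column takes local maxima above `median + 3σ̂` with
prominence ≥ 3σ̂, where σ̂ is the 1.4826-normalised MAD of frame-to-frame
intensity differences.  This noise estimator is the load-bearing choice: a
global intensity MAD measures the wave modulation itself once wave trains
cover the field (wave spacing ≈ 1 μm at slow speed/low frequency) and then
no ridge clears the threshold, while temporal differences stay essentially
pure pixel noise because ridges move ≪ 1 px/frame.  Peaks are refined to
subpixel by a 3-point parabola — necessary because the slowest waves move
only ~0.03 px/frame.  Peaks are linked greedily across adjacent columns
within 2 rows; traces shorter than 5 columns are dropped; the speed is the
|Theil–Sen slope| (robust to outlier ridge points) times
pixel\_size/frame\_interval.  At these settings the measured false-positive
rate on pure-noise kymographs is 0.00 traces per kymograph, and scripted
speeds across 0.005–0.04 μm/s are recovered within 1%.

Frequency is the number of retrograde traces whose row span crosses a fixed
reference row, divided by the acquisition duration.  A per-unit-edge-length
frequency would be an alternative reading; the fixed reference row is the
implemented one.  The speed–frequency association across cells uses
Spearman rank correlation.

## FRAP

Normalisation:
F\_norm(t) = [(F\_raw − F\_bg)/(F\_pre − F\_bg)] ÷ [(F\_ref − F\_bg)/(F\_ref,pre − F\_bg)],
so the pre-bleach level maps to 1 and any mono-exponential acquisition
bleaching shared with the unbleached reference ROI cancels exactly.  The
reference is assumed to be a same-cell unbleached ROI.

The recovery model is the exponential approach to plateau
F(t) = F₀ + (plateau − F₀)(1 − e^(−kt)) — the standard single-exponential
FRAP reading — fitted by `scipy.optimize.curve_fit` with initial guesses
F₀ = first post-bleach point, plateau = mean of the last five points, k
from the time to half recovery, and bounds −0.2 ≤ F₀ ≤ plateau-feasible
≤ 1.2, k > 0.  These guesses converge reliably on 75-point traces at the
noise levels tested (σ up to 3% of pre-bleach).  Mobile fraction =
(plateau − F₀)/(1 − F₀); half-time = ln2/k.  The fit is scale-invariant by
construction.  Non-converged fits are flagged and excluded from (but
counted in) the mobile-fraction summary.

Not modelled: diffusion-reaction kinetics, two-component recoveries, bleach
spot geometry, or diffusion too fast for the 0.4 s sampling — the
single-exponential mobile fraction is a phenomenological summary, not a
diffusion coefficient.

## Ratiometric FRET

Both ratio channels are background-subtracted (median of a user-supplied
background ROI) and Gaussian-smoothed (σ = 1 px; the smoothing scale is a
convention, not derived from data).  The cell footprint comes from Otsu
thresholding of the dedicated YFP channel with holes filled.  The activity
map is FRET/CFP inside the footprint, excluding pixels whose smoothed CFP
signal is below background + 3·MAD of the background ROI (dim-pixel ratio
blow-up guard).  The map is invariant to common multiplicative gain and,
after correct subtraction, to uniform additive background; any display LUT
is presentation-only.

Front/rear ratio: cell pixels are projected onto the wound direction; the
front band is the wound-side 25% of the projected extent and the rear band
the opposite 25% (`front_depth_fraction`; the exact ROI geometry is a
declared convention — the band construction makes it reproducible).
F/R = mean front activity / mean rear activity.

QC implements the machine-checkable exclusions — background median above
50% of the cell median, detector saturation — and passes through manual
flags (out of focus, overlapping cell, isolated from the monolayer) that
cannot be decided from the images alone.  Spectral bleed-through correction
is **not** applied; absolute ratios are therefore probe- and
instrument-specific, which is exactly why the front/rear ratio (a
within-cell contrast) is the reported statistic.

## MTOC polarization

Deviation is the unsigned angle in [0°, 180°] between the nucleus→MTOC
vector and the wound-closure direction; a cell is polarized iff deviation
≤ 60°, boundary inclusive.  The 60° is read as a half-angle from the ideal
line (deviation up to 60° either side).  The nucleus centroid is the anchor
of the reference vector.  Coincident nucleus/MTOC annotations are flagged
invalid rather than silently classified.  Under uniformly random MTOC
placement the expected polarized fraction is 60/180 ≈ 33.3%, the chance
baseline.  Whole-MT-array polarization can be scored with the same cone
rule on a caller-supplied array-orientation vector; the package does not
estimate array direction from images.  Group fractions carry Wilson 95%
binomial CIs.

## Statistics

Each group is tested for normality with the D'Agostino–Pearson omnibus test
(needs n ≥ 8; smaller groups force the non-parametric branch with a
warning).  All groups must pass for a parametric comparison — the
conservative choice when groups disagree.  Two groups: Student's t-test if
normal, Mann–Whitney otherwise.  Three or more groups go to Kruskal–Wallis
with Dunn's post-hoc (rank-sum z statistics with tie correction,
Bonferroni-adjusted over all pairs; no further correction is layered on) —
the multi-group branch is non-parametric regardless of normality, matching
how multi-group figures are conventionally treated in this assay
literature.  All tests are two-sided.  Stars: \*p<0.05, \*\*p<0.01,
\*\*\*p<0.001, \*\*\*\*p<0.0001.  The type-I error of the whole decision
tree is verified to stay within [0.02, 0.08] at α = 0.05 on Gaussian nulls.

## Synthetic data: what it does and does not emulate

All generators are seeded (`numpy.random.default_rng`) and bit-reproducible,
and every one emits machine-readable ground truth.

* **Tracks**: biased persistent random walk; heading = wrap-safe convex
  combination b·bias + (1−b)·(previous + wrapped-Gaussian noise), constant
  step length.  The convex combination gives a monotone map from bias
  strength to expected orientation.  Not modelled: speed fluctuations,
  cell–cell collisions, contact inhibition.
* **Wound masks**: a vertical cell-free band narrowing symmetrically;
  closure\_fraction maps exactly to removed area.  Phase-like images add
  Gaussian texture over cells only.
* **Leading-edge movies**: straight edge with optional advancing cosine
  lamellipodium bumps; planar Gaussian-profile ridges (~3 px wide) born at
  the edge at the scripted frequency — including waves born before frame 0
  so the field is populated from the start — travelling rearward at the
  scripted speed; filopodia as 3 px-wide bars growing/dwelling/retracting
  linearly above the local edge.  Acceptance-scale scenes are rendered at
  0.1 μm/px so that mask quantization (±1 px) stays well below the 10%
  speed tolerance for the shortest 2 μm filopodia.  Not modelled: curved
  edges, branching filopodia, fluorophore photobleaching, wave dispersion.
* **FRAP**: exact single-exponential recovery times a shared
  acquisition-bleaching exponential, plus Gaussian noise; the reference ROI
  carries the same bleaching.  Pre-bleach F = 1000, post-bleach floor 200
  by default.
* **FRET**: polygonal cell with scripted front/rear ratio split at a
  quantile of the footprint along the wound direction; YFP footprint
  rendered bright for segmentation; additive Gaussian noise only (no photon
  shot noise, no bleed-through).
* **MTOC**: polarized cells draw deviations uniformly inside the cone,
  unpolarized ones uniformly outside; nucleus positions uniform in the
  field.

Passing the recovery tests therefore shows the *estimators* are correct and
unbiased at realistic noise, not that segmentation of real microscopy is
solved — mask quality, uneven illumination, focus drift and biological
heterogeneity are out of scope of the synthetic scenes.

## Problem sizes used in the test suite

Recovery tests run at desk scale chosen to keep Monte-Carlo error
comfortably inside the asserted tolerances: 1000 tracks for the identity
checks, 81-frame (300 s) kymographs at 0.2 μm/px, 100 noise kymographs for
the false-positive rate, 8 FRAP replicates per mobile fraction (plus a
100-trace bias check), 200×260 px FRET scenes, 400–600 cells per MTOC
condition, a 45-frame 300×1600 px ten-filopodium scene, and 500 null
simulations for the decision-tree error rate.
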