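# Methods

This note records the models, conventions and numerical choices behind
`mangograde`, and what the synthetic validation does and does not show.

## Imaging model and calibration

The package assumes the two-view capture geometry of an in-line grading
platform: a downward-looking camera (default 8 mm lens, 4.5 µm pixel pitch)
450 mm above the tray, with a plane mirror providing the side view at a
total optical path h₃ + h₄ = 500 mm. All conversions use the thin-lens scale
model

    object size [mm] = image size [px] × pixel pitch [mm/px] × distance [mm] / focal length [mm]

The side view's distance is fixed, so fruit height is measured first, from
the side silhouette's vertical bounding-box extent. Height then sets the
top view's object distance h₁ = h₂ − f·height with `plane_fraction`
f = 0.5 by default: the widest horizontal section of an ovoid fruit lies
near mid-height, so that is where the top-view silhouette's rim sits. The
fraction is exposed in `CameraGeometry` because the "object plane" of a
rounded solid is genuinely ambiguous; with the synthetic generator the
choice cancels exactly, and on real fruit it changes scale by well under 1%
for plausible fractions. Mirror foreshortening (the 65° mirror tilt) is not
modelled; the plane-mirror equal-path assumption is used as-is. Lens
distortion is out of scope.

Pixel conventions: 0-based indices, x right, y down, pixel centres at
integer coordinates. A span of d pixels is measured as
(max index − min index + 1): with centres on the integer grid this count is
an unbiased estimate of the underlying physical extent, which matters
because any constant half-pixel bias would propagate cubically into volume.

## Segmentation

Top view: fruit = blue band in the open interval (20, 90). The upper
threshold separates fruit from the bright tray, the lower one removes the
near-black stem so the stalk does not distort the boundary harmonics.
Side view: three repeated channel thresholds, B < 120, G < 110, B < 100,
each restricted to the region surviving the previous pass, with a 7×7
median filter between passes. The pass values are configuration, tuned on
the synthetic shadow model (shadow darker than tray in all bands but
lighter than fruit in B); they are not claimed to be optimal for any real
camera. Cleanup: connected components smaller than `min_area` (500 px at
1600×850, scaled with frame area) are dropped, but the largest component is
always kept so a small fruit is never deleted; interior holes left by dark
spots are filled.

The boundary is the outer border of the single remaining component, traced
with Moore-neighbour tracing: clockwise in image coordinates, starting at
the topmost-then-leftmost boundary pixel, terminated by state-cycle
detection (the walk is a deterministic map on (pixel, previous-background)
states, so the traced cycle is exact). Rasterising the trace and filling
reproduces the mask exactly; this round trip is tested.

## Shape features

The centroid uses the Green's-theorem polygon formula on the closed
contour. The distance signature R(k) is resampled to 512 points by periodic
linear interpolation on the boundary index and rescaled so max R = 100,
making the Fourier features scale-invariant. Magnitudes use the DFT with
1/N outside the square root, so a constant signature c gives |F(0)| = c and
a unit cosine gives |F(1)| = ½. The harmonic sums S_p = Σ_{m=0}^{10}
|F(m)|·mᵖ weight high frequencies progressively; the m = 0 size term drops
out.

Roundness is 4·area/(π·max-diameter²), which scores a circle at 1. Max
diameter is the maximum Feret diameter of the convex hull (plus one pixel
for the half-pixel rim at each end) and min diameter the extent
perpendicular to it; aspect = max/min, area ratio = area/aspect.

Two numerical facts worth knowing. First, the digitised boundary of an
ideal circle is not featureless: the square grid leaves a small residual
concentrated at harmonics 4, 8, 12 (S3 ≈ 20 for a radius-100 disc, against
≈ 300–900 for fruit-shaped masks). This floor is shared by all masks at a
given resolution and does not affect discrimination; a test pins it down.
Second, S1–S3 are exactly translation invariant and move by ≲ 0.2% under
90°/180° rotations (start-point and resampling effects only).

Area ratio's absolute scale depends on whether areas are in pixels or mm²
and on image resolution; features computed by this package are consistent
with models trained by this package, but coefficients imported from
elsewhere presume the acquisition scale they were fitted at. The shipped
default model is therefore useful for its published arithmetic and for
classifying features on its native scale, while pipeline runs on synthetic
scenes should use a model trained on the same feature scale (`train`).

## Shape classification

Fisher classification functions: coefficients W⁻¹μ_c and constants
−½μ_cᵀW⁻¹μ_c + log π_c, with W the pooled within-class covariance
(scatter/(n−g)) and equal priors by default. Ties break deterministically
to the first listed class (regular). Because the pooled covariance uses the
n−g denominator, duplicating every training row perturbs coefficients at
O(1/n); decisions are unchanged, and that decision-level invariance is what
the tests assert.

Stepwise selection minimises Wilks' Λ = det(W_scatter)/det(T_scatter): at
each step the candidate with the largest partial
F = (Λ_p/Λ_{p+1} − 1)·(n − g − p)/(g − 1) enters if F ≥ F-to-enter, then
any retained feature whose partial F has dropped below F-to-remove leaves.
Defaults are the conventional per-test thresholds 3.84/2.71. Note that
these control the error rate of one test, not of a whole selection run:
with three pure-noise candidates the chance that at least one enters is
≈ 1 − 0.95³ ≈ 14%, so exact-support recovery at 95% reliability needs
family-calibrated thresholds (6.63/5.0 for three noise features), which is
what the selection-power test uses.

## Volume, mass and grading

Disk method: both masks are rotated major-axis horizontal (no-op for
axis-aligned fruit; nearest-neighbour rotation otherwise), per-column
extents are read off, the side profile is linearly resampled to the top
profile's slice count, and V = Σ π(Δy/2)(Δz/2)Δx with Δx = one top-view
pixel in mm. Accuracy on digital ellipsoids is ≤ 1% at ≥ 200 slices and
≤ 0.2% at ≥ 1000; end-to-end through segmentation and calibration the
error stays ≤ ~0.3% of volume.

Mass uses the linear density model m = 0.9973·V + 6.778 (g, mL), refittable
by OLS. Grades use half-open bands C = [0, 350), B = [350, 400),
A = [400, ∞) g — the published band edges leave (350, 351) and (399, 400)
unassigned, and the half-open convention closes those gaps. Misshapen fruit
are rejected before sizing and carry no volume or mass in reports.

## Synthetic scenes: what they emulate

A fruit is a solid with elliptical cross-sections along its length; the
radius profile is √(1−t²)(1+τt) (taper τ ≈ 0.12), and misshapen fruit add
1–3 Gaussian lobes (nominal 4–9 mm, scaled by the local profile so they
vanish at the tips) to the top outline. True volume integrates the
cross-sections over 10 000 slices; true mass applies the density model
exactly. Silhouettes are projected through the same scale model the
calibration inverts, and rendered onto a white tray with colours placed so
the segmentation thresholds are exercised: fruit B ∈ (20, 90) top / < 100
side, stem B ≤ 20, shadow B ∈ [100, 120), specks as small dark components.

The default population (length ~ N(132, 10) mm clipped to [105, 150],
width ≈ 0.62·length, height ≈ 0.80·width) gives aspect ratios near 1.6 and
masses spanning roughly 280–470 g, so all three grades occur; the default
cohort split is 159 regular / 21 misshapen. The truth table also carries a
`measured_volume_ml` reference = exact volume + N(0, 5 mL) reading noise,
emulating the water-displacement measurement an agreement study compares
against: against an *exact* reference, a paired t-test at n = 50 resolves
biases of ~0.05 mL (0.01%), so any discretised estimator "fails" — the
meaningful validation, and the one mirrored here, is agreement between two
measurement methods.

What passing these tests does **not** show: robustness to real-world
lighting, specular highlights, skin-colour variation, defects, touching
fruit or tray misplacement. The generator has uniform colours and exact
geometry; real deployments must re-tune thresholds and retrain the
classifier on real labelled images.

## Problem sizes

Test and acceptance runs use desk-scale batches chosen to keep statistics
meaningful: 50 fruit for volume agreement (the size used in the original
calibration studies), 13 sizes across 80–140 mm for calibration linearity,
100 replicates for selection power, 60–80 fruit for classifier training.
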