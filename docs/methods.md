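# Methods

This note documents the models, numerical choices and limitations behind
`ovograde`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Measurement model

The freshness feature is the yolk projected area ratio
`S = S_SMALL / S_BIG × 100 %` per candling view, averaged over four
views a quarter-turn apart into `Sn`. The four-view mean exists because
the yolk floats eccentrically: a single projection over- or
under-states the yolk area depending on which side faces the camera,
and the modulation is (to first order) sinusoidal in the viewing angle,
so four views at 90° spacing cancel it. The package treats "B and
below" as one terminal class; nothing in the pipeline subdivides it.

Haugh Units are computed as `HU = 100·log10(H + 7.57 − 1.7·W^0.37)`
(H in mm, W in g). The formula's argument can go non-positive for very
flat albumen; this is reported as a domain error rather than clamped,
since such eggs are outside the formula's validity. A replicate helper
averages repeated H readings and flags relative standard deviation
≥ 5 %, mirroring the usual two-operator, three-replicate protocol.

The HU–Sn link is ordinary least squares, `HU = slope·Sn + intercept`
with the reference fit `−74.14 / 101.29`. **Sn enters as a fraction in
[0, 1].** With percent input the model produces absurd values
(−74.14 × 38.2 ≈ −2832), while the fraction reading maps the two grade
cut-points to ≈ 73.0 and ≈ 61.0 HU — consistent with the 72/60 grade
boundaries — so `predict_hu` rejects inputs outside [0, 1] outright.

## Whole-egg segmentation

Grayscale conversion uses fixed BT.601 luma weights
(0.2989/0.5870/0.1140); candling rigs shoot at fixed settings with no
color management, so conversion constants are a convention, not a
calibration. CIELAB conversion assumes sRGB primaries and D65.

The threshold search introduces the pixel-weight coefficient

```
ω(t) = (σ_b(t) / σ_t) · (N_b(t) / N_t(t))
```

with σ read as standard deviation, background = pixels ≤ t (the dark
box interior) and target = pixels > t (the trans-illuminated egg).
**Design choice:** the maximized objective is `σ_b²(t)·ω(t)` — ω as a
weight on the classical Otsu between-class criterion — not ω itself.
Maximizing ω directly is structurally degenerate: since σ_t is constant
in t, ω scales like `√(w0·w1)·|Δμ| · w0/w1 ∝ w1^(−1/2)` as the target
class shrinks, so its argmax collapses onto the brightest few pixels of
any image whose bright region has a continuous histogram; with sensor
noise that produces a speckle mask that morphological opening erases.
The weighted objective scales like `w1^(+1/2)` in the same limit, keeps
an interior maximum, and retains ω's intended bias toward thresholds
that separate a compact bright target from a large dark background.
The literal reading remains available (`objective="omega"`), and
`WeightedOtsuResult` always records the full ω(t) curve. Ties in the
objective (common on two-level images, where every threshold in the gap
is equivalent) break to the lower median of the argmax set, centering
the threshold between modes.

Morphological cleanup is opening then closing with a disk (default
radius 5 px) and removal of 8-connected components smaller than a
fraction (default 0.005) of the image; both are configurable since no
canonical values exist. After keeping the largest component the mask's
interior holes are filled: if the threshold lands between the yolk and
albumen gray levels the raw egg mask is an annulus, and a radius-5
closing cannot fill a yolk-sized hole. Hole filling makes `S_BIG`
insensitive to which histogram gap the threshold selects. Pixel areas
are plain integer counts throughout — weighted-pattern area estimators
are deliberately not used, because S is a ratio and the estimator
choice cancels to first order.

## Yolk segmentation

Enhancement composes, in order: a linear stretch mapping the
[p, 1−p] quantiles to full range (p = 0.01), global histogram
equalization (64 bins), and CLAHE (8×8 tiles, clip 0.01) — the three
standard contrast operators in their conventional composition, with the
conventional defaults. Constant images pass through unchanged.

Clustering runs on the egg-mask pixels only. The default feature space
is the chromatic pair (a*, b*): the radial illumination gradient of
transmission lighting lives almost entirely in L*, and dropping it
makes the three clusters (albumen, ghosting ring, yolk core)
shell-tint invariant. Full-Lab clustering is available; there the
enhanced lightness replaces L*, while chroma always comes from the
unenhanced image because histogram equalization distorts color ratios.
An alternative flag enhances the RGB channels before the Lab transform
(enhance-then-cluster order) for comparison.

K-means is written in-package because its contracts are part of the
method: K-means++ seeding (first center uniform, then D²-weighted),
Lloyd iterations, stop at 100 iterations or center shift < 1e−6, empty
clusters re-seeded to the globally farthest point (unspecified upstream;
chosen for robustness), and bit-identical results for identical seeds.
The elbow curve `sse_curve` warm-starts k from the converged centers of
k−1 plus one D²-sampled extra point, which guarantees SSE(k) is
non-increasing in k — plain restarts do not guarantee this at local
optima. scikit-learn's K-means serves as an independent cross-check in
the tests, never as the implementation.

The yolk cluster is selected by mean pixel distance to the egg-mask
centroid (the yolk projection is central), with ties going to the lower
mean transmitted intensity (the yolk is optically denser). The selected
cluster's largest connected component is hole-filled: the ghosting ring
can capture the core's rim, leaving an annular yolk cluster, and the
area feature needs the solid projection. The yolk mask is intersected
with the egg mask, so yolk ⊆ egg always holds.

## Threshold calibration

Candidate cut-points are midpoints between consecutive sorted unique Sn
values (no canonical search grid exists). The B boundary maximizes the
Youden index for B-and-below vs rest (predicted B when Sn ≥ t) subject
to B sensitivity ≥ a floor (default 0.95) — the concrete form chosen
for the "prioritize detection of inedible eggs" safety constraint; ties
take the lower threshold, again for safety. If no candidate meets the
floor, the unconstrained optimum is returned with a warning flag. The
AA boundary then maximizes J for AA vs rest among candidates below the
B boundary. On cohorts resampled from the reference binned
distribution, the recovered B boundary lands near 54.3 % but the
AA-boundary optimum lands near 43.6 % rather than the published 38.2 %;
the binned data simply do not reproduce the published AA Youden value,
so only the B boundary is treated as a recoverable quantity.

## Phantom generator

The phantom is a stylized photometric model, not light transport: a
dark box background, a tinted elliptical egg (blue-green or white shell
presets that differ in chroma, reflecting the small transmittance
difference under a 10 W/5500 K cool-white source) with a mild radial
bloom (intensity range ≈ 0.88–1.0 of the tint), a darker (0.82×)
chromatically shifted yolk ellipse, a ghosting annulus at intermediate
attenuation (1.22× the yolk radii), a low-order harmonic wobble of the
yolk outline (default 3 % amplitude, approximating the yolk's irregular
contour; area effect ≈ amp²/2, negligible), and additive Gaussian
channel noise. Yolk semi-axes are solved from the target area fraction
exactly, so the rasterized truth-mask ratio matches the target to
within rasterization error (≲ 0.5 % relative at the default 176×240
geometry). Eccentricity rotates with the viewing angle, modulates the
per-view area sinusoidally (zero-mean over the four views), and adds
optional per-view jitter.

Storage cohorts draw per-egg random intercepts around a linear
Sn-vs-day trend (defaults: Sn = 0.33 + 0.0075·day, egg SD 0.02 over
days 0–36 in steps of 4), chosen so day 0 grades AA and day 36 grades
B-and-below under the HU link, with all grades represented in between —
the qualitative structure of a refrigerated-free storage trial at
26 °C/60 % RH. HU and grade follow the linear model exactly (the model
is the generative link), so cohort truth is self-consistent; a separate
sampler adds Gaussian HU noise for regression-recovery benchmarks, and
a bin-table resampler reproduces the reference Sn-by-grade distribution
for calibration tests.

What passing phantom tests show — and do not show: they verify the
algorithmic chain (thresholding, clustering, selection, area ratios,
calibration) end to end against exact ground truth, but the phantom has
no shell texture, dirt, cracks, specular structure or vignetting, so
phantom IoU values say nothing quantitative about real candling images.
Published real-image accuracies require the physical rig and are not
reproducible here; the test suite checks property-based stand-ins
(segmentation quality on phantoms, parameter recovery, boundary
consistency) instead.

## Problem sizes and tolerances

Default phantom geometry is 176×240 px (egg semi-axes 96×66), chosen so
a full segment-and-grade pass takes ~0.1 s and the standard 60-phantom
evaluation suite (30 per shell tint, noise σ = 8) runs in seconds.
Floating-point ties in threshold search use a 1e−12 relative band;
K-means SSE monotonicity is asserted to 1e−9 relative. The exhaustive
K-means oracle enumerates all 3⁹ assignments of 9-point sets.

## Known limitations

* Whole-egg segmentation assumes one dominant bright blob; touching
  eggs or heavy occlusion are out of scope.
* Near-rupture yolks with diffuse boundaries degrade the K-means
  segmentation; deep-learning segmentation is deliberately out of scope.
* The generator's tint presets are illustrative; real shell-color
  transmittance differences are only qualitatively emulated.
* Device control (rollers, motors, cameras) and GUI hosting are out of
  scope; the CLI operates on image files.
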