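# Methods

## The measurement model

A confocal z-stack of a cleared 3D culture is modeled as a 4-D array
`(channel, z, y, x)` with lateral pixel size and axial step in μm. Slice 0
is the first-acquired (shallowest) section; the physical depth of slice
*k* is *k·z_step*. All analyses treat depth attenuation as approximately
exponential, *I(d) ≈ I₀·e^(−d/L)*, with a channel-specific attenuation
length *L* that lumps scattering and absorption. This is an idealization:
in real samples *L* varies laterally and with local composition, and the
shallowest sections can be dimmer than the maximum (entering the sample),
which is why crossing searches start at the profile maximum rather than at
slice 0.

## Morphometry and depth normalization

The spheroid mask is obtained from a maximum z-projection by Otsu
thresholding, keeping the largest connected component and filling holes.
The diameter is the mean of the mask's extents along its two principal
axes through the centroid (+1 px to correct the pixel-center bias) — an
automated analogue of measuring a diameter twice at perpendicular angles.
Relative size change is `100·(post/pre − 1)`; negative means shrinkage.

Depths are normalized by **dividing** by the post/pre size ratio. A sample
shrunken to 55% has its measured depths expanded by 1/0.55, so the
normalized depth of a deep feature can exceed the physical stack depth;
this direction makes attenuation metrics comparable across protocols on
the pre-fixation length scale. The opposite convention (multiplication)
would compress instead, and was rejected because censored cutoffs are
naturally reported as "deeper than the (expanded) stack range".

## Decay depths and the Rose criterion

The z-profile is the mean intensity inside one fixed circular ROI (default
diameter 100 μm, centered on the projection-mask centroid). *d₅₀*/*d₉₀*
are the first normalized depths at or beyond the profile maximum where
intensity falls to 50%/10% of the maximum, linearly interpolated between
bracketing sections and censored at the deepest section when never
reached. Both are invariant under uniform intensity rescaling.

SNR per section is μ_SIGNAL/σ_BACKGROUND. μ_SIGNAL is the mean raw
intensity inside an automatic per-section Otsu mask (after a radius-1
median filter), restricted to the central ROI. σ_BACKGROUND is a single
scalar: the SD of sub-Otsu-threshold voxels in the shallow sections
(default the first 10% of the stack), where scattering has not yet
contaminated the background; deep-section backgrounds are not re-estimated
for exactly that reason. Because the definition uses raw intensities, an
additive offset raises SNR through μ while leaving σ unchanged — a
documented asymmetry of the definition, not a bug. Note the corollary: the
background mean must sit well below 5σ or SNR can never fall below the
Rose threshold; the simulator defaults respect this.

The Rose cutoff is the end of the uninterrupted run of sections with
SNR > 5 (strict), anchored at the shallowest qualifying section so that
medium above the sample surface does not zero the result. A single dip to
≤ 5 or an undefined section (empty mask) ends the run; if it reaches the
last section the cutoff is censored and reported as "> depth". The
crossing is linearly interpolated. An optional moving-average window can
smooth the profile first; it is off by default.

## Nuclei segmentation

Per channel: median filter (lateral radius 3 px; axial radius scaled by
the voxel aspect ratio), min–max conversion to 8 bit, then local-mean
thresholding — a voxel is foreground when it exceeds the mean of its
21-px-wide neighborhood (2·range+1 with range 10 px) by an offset that
defaults to 3× the robust noise level (1.4826·MAD) of the residual, with
an absolute floor of 1 count. Holes are closed (radius 1) and filled.
Local-mean thresholding tolerates lateral illumination gradients but
hollows objects wider than the window, so the window must exceed the
nucleus diameter; with ~8 μm nuclei this holds for pixel sizes down to
~0.4 μm.

Seeds come from multi-scale Laplacian-of-Gaussian detection spanning blob
diameters 9–25 px (σ = d/(2√3), 5 log-spaced scales, axial σ scaled by the
voxel aspect). One extra scale is added below and above the range purely
as a rejection band: a blob whose scale-space optimum lands on a padding
scale is outside the configured size range and discarded. The detector
threshold (0.04 on the 8-bit-normalized response) is deliberately low so
that dim, deep nuclei still seed when their contrast survives; in
uncompensated stacks deep nuclei drop below it, which is the mechanism
behind the depth-dependent recall loss the z-compensation comparison
measures.

Watershed floods the inverted smoothed intensity (or, optionally, the
negated anisotropy-aware distance transform — useful for touching
spherical objects) restricted to the foreground mask, 26-connected, one
catchment per seed. Objects under `min_object_voxels` (default 30) are
removed and labels renumbered contiguously. Marker positivity is decided
by segmenting the marker channel independently and counting its objects
(the ratio KI67⁺/DRAQ5⁺ is a ratio of object counts, not a per-nucleus
intensity classification; the latter could be built from
`measure_objects` output but is not the default).

Evaluation matches predicted to true objects greedily by descending IoU
with a one-to-one constraint at IoU ≥ 0.5 and reports precision, recall
and F = 2PR/(P+R); `recall_by_depth` stratifies recall by truth-centroid
depth to expose depth-dependent failure.

## Group statistics

Size-type metrics (diameters, decay depths, cutoffs) are compared with
Kruskal–Wallis followed by Dunn's test — pairwise z statistics on
tie-corrected mean ranks with Bonferroni adjustment, implemented here
because no installed package provides it; the omnibus tests, Tukey's HSD
and the Lilliefors (estimated-parameter Kolmogorov–Smirnov) normality
screen come from scipy/statsmodels. Count-type metrics use one-way ANOVA +
Tukey. Groups need ≥ 3 samples; all-constant data is flagged degenerate
(NaN p-values) rather than crashing. α = 0.05.

## The simulator and what passing tests mean

The generator emulates: nuclei as hard spheres (radius 4 μm) rejection-
sampled in a ball with minimum separation 2·r·overlap_tolerance; a rim
shell (default 25 μm) in which a configurable fraction (default 0.8) of
nuclei carry the proliferation marker; per-voxel attenuation by depth;
isotropic shrinkage applied as a pure scaling of the same center layout
(nucleus radius is kept constant, so shrinkage densifies packing — the
mechanism by which shrinkage degrades segmentation); per-slice gain
`(1+slope)^k`, where `slope = e^(z_step/L) − 1` cancels attenuation
exactly; Gaussian PSF blur (default σ = 1.5/0.5/0.5 μm z/y/x); and
additive Gaussian background (offset 100, σ 50 counts on 16 bit) with
optional Poisson shot noise. Default amplitude 4000 puts the top-slice SNR
near 80, the scale reported for well-preserved nuclear stains. A `volume`
channel kind fills the whole spheroid uniformly (a CellTracker-like
cytoplasmic stain); combined with `center_depth=0` (stack starting at the
sample's equatorial plane) it yields an exactly exponential ROI profile,
which is what the analytic decay oracles require — discrete sparse nuclei
cannot give a depth-constant fill fraction.

Not emulated: nuclear texture and shape variability, spatially varying
attenuation, spectral bleed-through, detector nonlinearity, and real
optical PSFs. Passing tests therefore demonstrate correctness of the
measurement chain under the stated physics, not robustness to every
property of real data.

## Problem sizes and numerical choices

Test and example stacks are sized for a single-CPU run: segmentation uses
a 130-μm spheroid with 200 nuclei at 0.8 μm pixels (≈ 3.5 M voxels), which
keeps the nucleus diameter (~10 px) inside the 9–25 px seed range — the
scale-relevant quantity — while a full 300-μm spheroid at the native
~0.57 μm pixel size would behave identically at ~25× the voxel count.
Decay oracles use a 1000-μm uniformly stained hemisphere at 3 μm pixels so
the d₉₀ crossing for L = 200 μm stays inside the stack. Determinism: all
randomness flows through one `numpy` Generator seeded from the config;
identical configs give bit-identical stacks, and segmentation is seedless
and deterministic. Ties and degenerate inputs: constant profiles censor
rather than crash; empty masks flag NaN SNR; blank projections, empty
background masks, zero-variance backgrounds, unplaceable nucleus counts
and seedless watersheds raise informative errors.

## Known limitations

- The diameter estimator assumes one dominant, roughly convex object;
  debris or twin spheroids in the field will bias it.
- σ_BACKGROUND from shallow sections assumes those sections contain
  genuine background; a field fully covered by sample needs an explicit
  `background_slices` override.
- The raw-intensity SNR definition bounds SNR below by μ_bg/σ_bg; with
  high detector offsets the Rose criterion can become unreachable from
  below (see above).
- Local-mean thresholding hollows objects larger than its window; set
  `local_threshold_range_px` above the largest object radius in pixels.
- Dunn's test uses the large-sample normal approximation; for very small
  groups (n = 3–4) its p-values are approximate.
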