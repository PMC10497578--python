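# Methods

`pvswidth` quantifies the width of the perivascular space (PVS) around
spinal-cord arterioles in 2-D multi-channel fluorescence sections: the
vessel wall is stained for α-smooth-muscle actin (SMA) and the outer PVS
border is formed by GFAP-positive astrocytic endfeet. This note documents
the model behind each stage, the parameters that matter, what the synthetic
phantoms do and do not emulate, and the numerical choices made where the
design was open.

## Segmentation model

**Ratio image.** Each channel is divided by a more heavily blurred copy of
itself: `R = G(σ_small)∗I / max(G(σ_large)∗I, ε)` with σ_small = 1 px and
σ_large = 4 px. Background, whatever its absolute brightness, maps to
R ≈ 1; locally bright structures (wall rings, endfoot sheaths) map to
R > 1. The guard ε = 1e−6 × max(I) is applied as a *floor* on the
denominator rather than an additive term, so a constant image yields R = 1
exactly and the ratio is exactly invariant to global multiplicative
rescaling (gain changes between acquisitions). Blurring uses reflective
boundary handling; the border band of width 3·σ_large is flagged
unreliable and excluded from thresholding statistics.

**Threshold.** The ratio histogram (256 equal-width bins over the interior
[min, max], smoothed with a 3-bin moving average to stabilize the modal
bin against shot noise) is scanned rightward from the background peak; the
threshold is the left edge of the first bin whose count falls *strictly*
below 77% of the peak count. This rule is deliberately permissive — it
hugs the background peak and admits essentially everything locally bright —
because the object-level filters, not the threshold, are meant to reject
noise. On a pathological histogram with no qualifying bin (e.g. a single
spike) the function raises rather than fabricating a threshold.

**Object filters.** Connected components (8-connectivity, so thin diagonal
wall segments do not fragment) are annotated with area, mean raw-channel
intensity, and boundary contrast (mean |ΔI| across the object boundary,
averaged per boundary pixel over its background 8-neighbors). Defaults keep
only the area floor (20 px) active; intensity and contrast cut-offs are
per-image settings, as staining contrast varies between sections. Manual
include/exclude overrides are declarative (config lists), applied last, and
always win.

**Vessel closing.** Staining gaps in a wall ring are closed by morphological
dilation-then-erosion with a disk of radius 2 px. Closing is idempotent, so
the escalation ladder applies *i* dilations followed by *i* erosions
(i = 1…5) to the original mask until the wall forms a single component
enclosing a lumen; otherwise the object errors out as a candidate for
manual exclusion. The wall filled with its lumen defines "inside".

**Perimeter and normals.** The outer boundary is traced with Moore-neighbor
tracing augmented so that the chain covers *every* wall pixel with a
background 8-neighbor: plain Moore tracing cuts corners past
diagonally-exposed pixels, so on each diagonal step the skipped shared
4-neighbor is inserted (it is provably 8-exposed). One caveat: a pixel in a
one-pixel-thick neck is traversed from both sides but listed once, which
locally breaks chain adjacency; such degenerate geometry is also excluded
from normal estimation. Outward normals come from central differences over
a ±4-pixel chain window, rotated 90° and signed to point into the
background. The window is ±4 rather than ±3 because the corner-inclusive
chain samples the boundary more densely near 45°, and ±3 there spans too
short an arc (up to 12° radial error on a 20-px circle; ±4 keeps it under
10°). Pixels with a degenerate tangent (window neighbors coincide, e.g. a
1-px protrusion tip) are flagged and skipped.

## Width measurement

A Euclidean distance map (scipy's exact EDT, scaled to µm) is built from
the union of all closed vessel masks. GFAP objects whose closest perimeter
pixel lies within 2.5 µm of a vessel are auto-selected as endfeet; wider
PVSs require explicit manual inclusion by object id, reproducing the
original semi-automated workflow as replayable configuration.

From each perimeter pixel three rays are cast — the outward normal and its
±10° rotations — marched in 0.5-px steps with bilinear interpolation of the
endfoot mask (occupancy threshold 0.5) up to 10 µm (well above any
plausible PVS width at this scale; configurable). If any ray hits a
selected endfoot, the pixel is a *facing edge* and its width is the
distance-map value at the first endfoot pixel hit, minimized over the three
rays; the first-hit-minimum convention targets the *inner* surface of the
endfoot sheath. Pixels with no hit carry no width and are excluded from all
averages (only facing pixels enter denominators).

**Summaries.** Per vessel: the mean width over facing pixels, and the means
of the five quintiles of the sorted widths using floor-index slicing
(quintile k covers sorted indices ⌊(k−1)n/5⌋ … ⌊kn/5⌋). Floor slicing is
deterministic and, when n is divisible by 5, makes the mean of the five
quintile means reproduce the overall mean to machine precision — a free
invariant used in testing. Vessels with fewer than 5 facing pixels keep
their mean but are flagged and excluded from quintile analyses.

**Overlay.** The perimeter is rendered color-coded by width: red at 0 µm,
interpolating to green at 0.78 µm, to blue at 1.56 µm, clamped blue above;
non-facing pixels are grey. Anchors are configurable.

## Spatial mapping

High-resolution fields are placed into the tiled overview by a pure
translation computed from stage metadata (same stage, same section — no
rotation or scale), optionally refined by a manually supplied residual
offset because the sample can shift on the holder. A vessel's distance to
the reference region — the syrinx outline for injured animals, the central
canal for controls — is the minimum distance from its facing perimeter
pixels to the reference polygon, in µm; points on or inside the polygon are
at distance zero (boundary counts as inside). Using the facing pixels
(rather than the centroid) measures from the PVS itself.

## Statistics

The statistics layer consumes only the per-vessel record table (CSV
schema: vessel_id, animal_id, group, level, mean width, q1…q5) — no images.

1. **Pooling check**: Welch two-sample t-test on per-vessel mean widths
   between the two animals within each group × level; zero-variance
   samples are special-cased (identical ⇒ p = 1). Cells with one animal
   are flagged, not errors.
2. **Group × level**: two-way ANOVA with type-II sums of squares (robust to
   unbalanced vessel counts) on per-vessel means, then Tukey HSD over the
   six group:level cells; the control-vs-syrinx contrast within each level
   is extracted.
3. **Quintiles**: per level, a linear mixed model of the five quintile
   means (repeated measures per vessel) with fixed effects group, quintile
   and group×quintile and a random intercept per animal, fitted by REML.
   The per-quintile group contrasts are Sidak-adjusted over the family of
   five. With fewer than two animals per group, or when the REML fit is
   singular because the between-animal variance is effectively zero, the
   model falls back to fixed-effects OLS with a warning.

## Synthetic phantoms

**Sections** are rendered as annular walls (SMA channel) and endfoot
sheaths at a constant radial gap (GFAP channel) — the gap *is* the true PVS
width, one number per vessel — with optional wall gap arcs to exercise
closing, partial angular coverage to exercise facing detection, and
Poisson shot + Gaussian read noise. Defaults: 0.156 µm/px, structures at
100 counts over background 20, read noise sd 10 (SNR 10). Annulus masks use
the half-open radial convention [R−t, R), whose pixel count is the
difference of two disk counts; discretization error is a few percent and
fluctuates with lattice resonances (worst ≈ 5% near R = 12 px for a 3-px
wall), which is why the area invariant is checked at representative radii
rather than claimed uniformly. The half-coverage (180°) facing-fraction
check uses a 16-px-radius vessel so the ~2-px discretization at each sheath
end, plus the ±10° ray overshoot, stays small against the perimeter.

**Cohorts** mirror the study design — 2 groups × 3 spinal levels × 2
animals × 25 vessels, 100 width samples per vessel — with a two-level
log-normal width model: vessel medians log-normal around a population
median of 0.57 µm (σ_vessel = 0.35), widths log-normal within a vessel
(σ_within = 0.9). These values put the quintile spread (≈0.2 µm narrowest
to ≈2 µm widest around a ≈0.85 µm mean) at the scale reported for
arteriolar PVSs in cleared rodent spinal cord. The between-animal effect
defaults to zero, matching the pooled design the statistics assume. An
injected effect multiplies widths in one group × level cell, either
wholesale or restricted to chosen quintiles of each vessel's sorted widths.

**What the phantoms do not emulate**: tortuous and irregular vessel
cross-sections, spatially varying gaps around one vessel (a sinusoidal-gap
stretch fixture exercises quintile logic only), anti-PECAM endothelium,
staining heterogeneity, optical blur/PSF, and 3-D structure. Passing the
recovery tests therefore demonstrates correctness of the measurement
geometry and statistics under known ground truth, not robustness to every
property of real tissue.

## Numerical choices and limitations

- Anisotropic pixel calibration is rejected, not approximated.
- Ray marching at 0.5-px steps with bilinear occupancy ≥ 0.5; width read at
  the nearest pixel of the first hit. Recovery error on phantoms is ≤ 0.6 px
  across gaps 0.5–3 µm at SNR 10.
- Quintile ties break by stable sort order.
- Boundary counts as inside for point-in-polygon (distance 0).
- Determinism: every stochastic element (phantom noise, cohort draws) is
  driven by an explicit seed; CLI reruns with equal config + seed produce
  byte-identical CSVs, and each output directory carries a provenance JSON
  (config hash, package version, seed).
- Simulation sizes in the validation suite (200 null replicates, 100 power
  replicates per design) were chosen to estimate rejection rates to a few
  percent while keeping the full suite fast.
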