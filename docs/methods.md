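# Methods

## Data model and geometry

All images are polar, shape `(n_alines, n_depth)`: axis 0 is the catheter
rotation angle, axis 1 depth along the beam. A-line index 0 points along
`angle_origin` (default 0 rad) and indices increase counter-clockwise.
Cartesian coordinates are micrometres with the origin on the catheter
rotation axis: `r = catheter_offset + depth_index · axial_pitch`,
`θ = angle_origin + 2π · angle_index / n_alines`.

`axial_pitch` is a required metadata field with no default. The absolute
`catheter_offset` cancels in radial thickness differences but not in oblique
distances, so it is always explicit (default 0, i.e. the first depth pixel on
the rotation axis). `axial_pitch` is interpreted as already expressed in
tissue micrometres; no refractive-index correction is applied. Typical
acquisition values: 1024 A-lines per frame and a 0.2 mm frame pitch
(100 rotations/s at 20 mm/s pullback).

NaN is the missing-value sentinel in every polarimetric channel (guidewire
shadow, low-SNR regions) and is excluded from all thresholds and means.

## Per-frame cap segmentation

**Plaque delineation.** An A-line belongs to the plaque if it carries at
least one plaque-shadow pixel (label 5) — the class marking loss of the
normal intima/media/adventitia layering.

**Lumen contour.** Per A-line, the surface is the first depth index carrying
a tissue label (intima, media or plaque shadow); A-lines that are entirely
lumen/background or fully shadowed have no contour.

**Incidence angle.** The surface tangent is estimated by central differences
of neighbouring contour points in Cartesian coordinates after circular
smoothing; the incidence angle is the unsigned acute angle between tangent
and the radial beam direction (90° = perpendicular). The contour is smoothed
with a circular *quadratic Savitzky–Golay* filter (window 11 A-lines) rather
than a plain moving average: a moving average is biased wherever the contour
curves (up to ~1.2° of incidence error on an eccentric ellipse at window 11),
while the quadratic fit is exact for locally parabolic contours and keeps the
same noise suppression. Smoothing feeds tangent estimation only; boundary
points use the raw contour.

**Exclusions.** Plaque A-lines with incidence ≤ 5° (grazing beam: low
backscatter, artifactually high depolarization) or undefined incidence, and
A-lines containing guidewire-shadow pixels, are removed from the measurable
region.

**Cap criterion.** A pixel below the surface on a measurable A-line is cap
iff `depolarization < 0.2` **or** `reflectance > 35 dB`, both strict
inequalities, exactly as stated; NaN pixels never qualify. The
depolarization cut-off reflects histology-derived signatures of lipid-rich
tissue; the reflectance branch rescues genuinely bright cap tissue in
low-polarization-contrast areas.

**Boundaries.** Per measurable A-line whose surface pixel is cap: the inner
point is the lumen–cap intersection; the outer point is the deepest pixel of
the *surface-anchored contiguous run* of cap pixels. A literal "deepest
cap-positive pixel anywhere" reading would let isolated deep pixels that pass
the threshold spuriously inflate the cap, so run contiguity is the default;
`min_run_gap` (pixels of tolerated gap, default 0) exposes the alternative.

**Minimum cap thickness.** The exhaustive minimum Euclidean distance over
all inner×outer point pairs, in µm, with ties broken lexicographically on
(inner index, outer index) for deterministic regression behaviour. Frames
are processed independently; no inter-frame smoothing.

Degenerate inputs never raise in `measure_frame`: a frame without plaque or
without surface cap pixels yields an absent MCT with an explanatory status.

## Volumetric analysis

Lumen area is the shoelace polygon area of the Cartesian lumen contour
(absent angles interpolated circularly; flagged unreliable above 25% absent).
The MLA is the minimum-area frame (ties to the lowest index). The lesion
segment is either analyst-supplied (primary, mirroring expert practice) or
automatic: extend from the MLA in both directions until 3 consecutive frames
have plaque angular extent below 30/360 of the circumference, including the
first such minimally diseased frame; clamped at pullback ends with a
`no_healthy_reference` flag.

Lesion aggregates: `mean_mct` averages per-frame MCTs over frames with a
measurable cap (absent values excluded rather than imputed, count reported);
`overall_mct` is their minimum. Cap birefringence and depolarization means
are pixel-weighted pools over the whole cap volume (birefringence restricted
to cap pixels with depolarization < 0.2, where the polarization state is
reliable); per-frame-then-average pooling is available as an option.

## Agreement statistics

Pairing schemes for triplicate readings: intra-observer pairs each reading
with the other two (3 pairs/case); manual-vs-automated pairs each manual
reading with the single automated value (3 pairs/case); inter-observer
pairing between two manual observers is not uniquely defined by practice, so
both by-repetition-index (default, 3 pairs/case) and all-crossings (9
pairs/case) are implemented.

Bland–Altman: differences first − second; bias = mean, limits of agreement
bias ± 1.96 × sample SD (n−1). No repeated-measures correction is applied —
within-case correlation of triplicates slightly narrows the LoA; this is a
documented limitation, matching common practice. The two-sample
Kolmogorov–Smirnov test uses the exact method when the smaller sample has
≤ 10 observations and the asymptotic distribution otherwise (cohort sizes of
a few dozen sit comfortably in the asymptotic regime). Thin-cap fractions
use strict `<` at each cut-off (65/80/95/100 µm). No multiple-testing
correction is applied.

## The phantom

The generator emulates what the acquisition system and segmentation network
deliver — not OCT physics. Tissue is laid out radially per A-line: lumen to
`r_L(θ)`; within the plaque arc a cap of thickness `t(θ)` over a lipid core;
a normal intima/media wall elsewhere. Reflectance decays linearly in dB with
depth at a per-class attenuation slope; birefringence and depolarization are
per-class Gaussian draws clipped to valid ranges. Default optics straddle
the pipeline thresholds the way real tissue does: cap 40 dB / Δn 4.5·10⁻⁴ /
depolarization 0.05; lipid core 25 dB / no defined birefringence (NaN) /
depolarization 0.40; default noise SDs 2 dB, 0.5·10⁻⁴ and 0.03. Plaque-arc
A-lines carry the plaque-shadow label from the surface down (the lumen keeps
its label so the contour remains defined); guidewire-arc A-lines are labelled
guidewire over their full depth with NaN polarimetry. Deep tissue beyond
media/core maps to background, as only discernible layers are labelled.

Ground truth stores the analytic inner/outer cap boundaries densely sampled
at 10× A-line density; the true MCT is the exhaustive minimum pairwise
distance over those samples (KD-tree accelerated, exact for point sets).
Convergence versus 100× sampling is below 0.5 µm on harmonic cap profiles.
Caps thinner than one axial pixel set a `resolution_warning` flag rather
than raising.

Not modelled, hence not validated by passing tests: speckle, catheter sheath
reflections, NURD/motion artefacts, flush artefacts, and realistic
segmentation-network error modes (masks are rule-perfect). Phantom results
bound pipeline correctness, not clinical performance.

## Problem sizes and tolerances

Tests and the acceptance script use 256–512 A-lines × ~320–1750 depth pixels
at 2.5–5 µm pitch, 5–21-frame pullbacks, and 15-lesion groups — small enough
to run in minutes on one core while keeping the arc step (≈ r·2π/n) and the
axial pixel the dominant, quantifiable error terms. Geometry-recovery
tolerances follow from discretization: one axial pixel plus one lateral arc
step for noiseless phantoms; two axial pixels median error under default
noise. Byte-level determinism is guaranteed by seeding all randomness
through `numpy.random.SeedSequence`, drawing phantom noise fields before
class assignment, and fixed 6-significant-digit float formatting in writers.
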