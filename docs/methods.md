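# Methods

`rhizopore` quantifies how a growing root restructures the soil around it,
from 3-D X-ray micro-CT grayscale volumes. This note describes the models and
procedures the package implements, the choices made where the design was
genuinely open, and what the synthetic validation does and does not
demonstrate.

## The measurement protocol

The pipeline reproduces an in-situ rhizosphere quantification protocol for
isotropic micro-CT volumes (12 µm voxels by default):

1. **Median filtering.** A radius-3 median filter with a *spherical* footprint
   (123 voxels) and reflecting boundaries removes point noise while preserving
   structural borders. The spherical footprint follows the "3 pixel radius"
   wording literally; a cubic 7×7×7 footprint would anisotropically widen the
   neighborhood along diagonals.
2. **Surface-calibration thresholding.** The solid threshold is
   `mean(background) + 0.5·(mean(reference) − mean(background))`, where the
   background box samples air and the reference box samples an aluminium
   insert present in every scan. Because the threshold is defined relative to
   two materials imaged in the same scan, it transfers across samples and
   days. Solid = filtered gray ≥ threshold.
3. **Root segmentation.** Adaptive region growing from user-supplied seed
   voxels: breadth-first accretion over face-connected (6-neighborhood)
   voxels whose gray falls within `µ ± k·σ`, where µ and σ are running
   statistics of the accepted region. The statistics are recomputed every
   1000 accepted voxels and frozen after 10 000, which makes the result
   monotone in `k` under a frozen schedule and guarantees termination; σ is
   floored at 2 % of the gray range so a single seed can bootstrap under
   noise. Default `k` = 2.5. The commercial tool the protocol originally
   used does not publish its acceptance rule, so this rule is a documented
   stand-in with the same interface (seeds, tolerance).
   The grown mask is then regularized: a morphological opening (spherical
   element, radius 2.5 voxels) finds the root body, a one-voxel collar of
   the raw mask around the body is restored, internal holes are filled, and
   only seed-containing components are kept. The collar restore makes the
   operation the identity on an already-smooth mask (verified: zero voxels
   changed on noise-free digital roots) while removing the thin tendrils
   the grower otherwise leaves in blurred pore space — tendrils matter
   because every downstream distance shell is measured from the root
   surface.
4. **Partial-volume margin.** All voxels within one voxel (Euclidean) of the
   root surface are excluded from the solid and pore masks and from the
   analysis region. EDT-based exclusion keeps the margin isotropic; a box
   structuring element would not.
5. **Edge crop.** Voxels near the container wall are removed (3 mm for
   25 mm cylindrical columns; for the box-shaped synthetic volumes the crop
   applies to the four lateral faces and defaults to 0.24 mm — a box volume
   3 mm across cannot give up 3 mm per side).
6. **Phase partition.** Within the analysis region every voxel is exactly one
   of root / solid / pore; the reference insert is excluded from all soil
   metrics. The partition is asserted after segmentation, not assumed.

### Distance shells

Soil around the root is partitioned into 17 concentric regions by binning the
Euclidean distance transform from the root mask into half-open intervals
`(inner, outer]` in voxel units: two-voxel steps to 20 voxels (24–240 µm),
five-voxel steps to 50 voxels (240–600 µm), and a final region to 1 mm
(83 voxels at 12 µm; the physical outer bound recorded in outputs is 996 µm).
EDT binning replaces iterated morphological dilation — it is isotropic,
reproducible, and needs no structuring-element convention; this is the one
deliberate algorithmic substitution in the pipeline.

The innermost interval, (1, 2] voxels = 12–24 µm, abuts the partial-volume
margin. It is kept as region 1 of the 17 but flagged *margin-adjacent* and
excluded from the named-region summaries and the gradient fit, which start at
24 µm. `ShellSchedule.default(include_margin_band=False)` switches to the
alternative 16-region accounting for users who read the region count the
other way.

Two named distance bands summarise the profile: **root surface** = 24–120 µm
(regions 2–5) and **bulk soil** = 480–600 µm (regions 15–16). Porosity is
`pore / (pore + solid)` voxel counts; discrete and cumulative (24–48, 24–72,
24–96 µm, …) tables are emitted, and the cumulative values equal the
volume-weighted means of the discrete shells by construction.

Voxel-lattice caveat: individual two-voxel shells show a persistent ±5–13 %
banding against the continuum annulus volume `π(b_out² − b_in²)L`, because
sqrt-of-integer EDT values cluster unevenly inside 2-voxel bins. The banding
cancels in unions (the ten 2-voxel shells together match the continuum within
3 %) and does not affect porosity, which is a ratio within each shell.

### Depth profiles

For every two-voxel (24 µm) slab along the root axis and each region, the
pipeline reports mean cross-sectional pore and solid areas (defined as voxel
volume divided by slab thickness, so `area × thickness` integrates exactly
back to region volume), slab porosity, and per-object areas of the slab's
projected 2-D pore and solid images (8-connected labeling) — the slice-wise
particle-analysis output.

### Local thickness and pore classes

Local thickness at a pore voxel is the diameter of the largest sphere wholly
contained in the pore space that contains the voxel (maximal inscribed
sphere). It is computed by distance transform followed by descending-radius
sphere painting; with `radius_step` set, radii are floored to that step,
trading a bounded downward bias for far fewer distance transforms on large
volumes. Volume faces count as phase boundary, except in root morphometrics,
where the mask is continued axially before the transform — the imaged root is
a section of a longer root, and cut ends must not read as root surface.
Diameter is 2·radius in continuous µm; no odd/even-voxel diameter convention
is applied.

Pore classes by local diameter: **macropores** strictly > 72 µm,
**mesopores** 24–72 µm inclusive on both bounds (72 µm is a mesopore,
24 µm is a mesopore), **sub-resolution** < 24 µm (two voxels — the
resolution floor; root hairs at 15–18 µm are invisible at this voxel size).
Sub-resolution pore space stays in porosity figures but is excluded from
component counts. The default classification splits the pore space voxelwise
by thickness and labels 26-connected components per class within each region;
the alternative (`strategy="component_max"`: label whole pores first, classify
each by its maximum thickness) is implemented for comparison, since "isolated
based on their corresponding pore thickness" supports either reading. Density
denominators are region *soil* volume (pore + solid, excluding root and
margin), in mm³.

### Comparative summaries

Percent change between an early and a late day is `(late − early)/early ×
100`, reported to the nearest whole percent. Surface-vs-bulk contrast is the
signed difference of the two named-region porosities in percentage points,
plus their ratio. Replicate aggregation reports mean, `sd/√n` standard error
and n; model fitting (repeated-measures REML and the like) is deliberately
out of scope — the long-format `study_summary.csv` is the interface to
external statistics packages.

## The synthetic-scan generator

No scan data are publicly deposited, so every stage is validated against
generated volumes with known ground truth.

**Soil texture.** A seeded standard-normal field is band-pass filtered
(difference of Gaussians at `grain_length_scale` and twice that) and
thresholded at the quantile that yields the target bulk porosity — exact by
construction, up to one voxel of count rounding. The band-pass matters:
thresholded *low-pass* noise carries long-wavelength porosity drift of
several points per millimetre, whereas uniformly packed granular media are
statistically homogeneous above the grain scale; desk-scale distance shells
cannot average such drift away, and the homogeneity the analysis assumes
would be silently violated.

**Root.** A tapered cylinder along z (linear radius interpolation), centred
laterally, with optional lateral branches attached to the axis; the exact
voxel mask is returned as ground truth. Placement requires the root plus a
1 mm annulus to fit inside the lateral extent.

**Porosity gradient.** Within every one-voxel EDT band from the root surface,
the pore fraction is raised to `bulk + amplitude·exp(−d/λ)` (band midpoint
distance `d`, decay length λ, capped at 1) by flipping solid voxels to pore
in order of the underlying texture-field value — i.e. the band's pore
threshold is raised, so added porosity *enlarges existing pores at the grain
scale*. Uniform-random voxel flips were rejected after measurement: they
sprinkle isolated single-voxel pores that the protocol's own median filter
erases, making up to a third of the imposed near-root porosity invisible to
the measurement chain. Bands already above target are never densified, so
bulk statistics outside the annulus are untouched. The exponential form
mirrors the observed decay of rhizosphere porosity to bulk within ~1 mm;
amplitude and decay are free parameters.

**Rendering.** Phase-mean grays (pore 20, solid 140, root 70, reference 200
by default — the calibration midpoint of pore and reference, 110, then falls
between root and solid as the protocol requires), Gaussian PSF, additive
Gaussian noise, an aluminium-like insert (nominally 5 × 3 × 0.5 mm, shrunk to
fit desk-scale volumes) and an air pocket placed in lateral corners clear of
the root's 1 mm annulus. The insert and pocket provide the reference and
background calibration boxes, inset past the blur. The default PSF is
sub-voxel (σ = 3 µm at 12 µm voxels), modelling a scan whose blur is minimal
relative to the voxel size; σ = 6 µm (half a voxel) is used in the
segmentation stress tests. Not simulated: beam hardening, ring artifacts,
projection/reconstruction physics, root growth dynamics.

**Artificial-root control.** A straight constant-radius rod in gradient-free
soil, mirroring a nylon-wire control experiment: the true porosity profile is
flat, so any measured surface-vs-bulk contrast is pipeline artifact.

### Phantom conditions

Two frozen phantom configurations drive validation
(`gradient_phantom_spec`, `control_phantom_spec`): a straight 300 µm-radius
rod in a 2.3 × 2.7 × 2.7 mm volume (192 × 224 × 224 voxels), bulk porosity
0.40, amplitude 0.30, decay 100 µm, texture grain 60 µm for gradient
recovery and 18 µm for the control. The grain scales balance two failure
modes measured during design: coarse texture (~96 µm) leaves so few
independent grains per shell that shell porosities fluctuate by several
points (and the exponential fit's offset–decay trade-off destabilises),
while very fine texture is partially erased by the radius-3 median filter.
The control uses the finest workable grain because its question — does the
pipeline impose a spurious gradient? — is asked of the thin near-surface
shells, where texture-sampling noise is largest; control experiments average
four replicates, as the study design this emulates did.

### What passing validation does and does not show

The phantoms demonstrate that the measurement chain recovers imposed
gradients (decay within ±20 %, amplitude within ±0.03), stays flat on
gradient-free controls (within 2 points), segments at ≥ 0.97 voxel accuracy
and ≥ 0.95 root Dice under half-voxel blur and noise at 10 % of the
pore–solid gray gap, and is exact when noise-free. They do not demonstrate
performance on real scans: real soil has mineralogical gray-level variation
within the solid phase, water films, reconstruction artifacts, and roots
whose gray overlaps the water-filled pore signal — none of which the
generator emulates. Desk-scale volumes (≈ 7–10 M voxels) also carry more
texture-sampling noise per shell than full-column scans; the chosen problem
sizes keep the full validation suite and the acceptance script within a few
minutes on one CPU while leaving every recovery margin wide.

A residual measured bias worth knowing about: the adaptive grower accepts
blurred root–pore mixtures more readily than root–solid ones, so the root
mask extends slightly further into pore contacts; with the one-voxel margin
this under-samples pore just outside the surface by ≈ 0.5–1 porosity point
(visible as a small negative control contrast). The margin absorbs most of
it; larger margins would trade resolution for the remainder.

## Numerical conventions

- Voxels are isotropic; all physical outputs are µm, mm², mm³ via the voxel
  size; porosity is a fraction, contrasts are percentage points.
- Half-open `(inner, outer]` intervals resolve all distance-bin ties; the
  1 mm bound is floored to whole voxels (83 at 12 µm).
- Thickness classes compare in µm with a 1e-9 guard; exactly 72 µm is a
  mesopore, exactly 24 µm is a mesopore.
- Pore connectivity is 26-neighborhood (solid complement 6-neighborhood);
  region growing uses 6-neighborhood; 2-D slab objects use 8-neighborhood.
- Every stochastic step derives a named substream from the master seed;
  identical spec + seed reproduces volumes bit-for-bit and tables
  byte-for-byte. Seeds are recorded in the run manifest with SHA-256
  checksums of every output.
- Degenerate inputs: empty root masks, zero-soil regions and non-positive
  early values in percent change yield errors or explicit nulls with
  warnings, never silent zeros.

## Known limitations

- The adaptive region-growing rule approximates an unpublished commercial
  algorithm; only its interface (seeds, tolerance) is shared.
- Synthetic volumes are boxes, not cylindrical columns; the cylindrical
  crop is implemented but exercised only on synthetic cylinders.
- Scans at different days are treated independently (no registration), as
  the emulated protocol also did.
- The generator's gray model is four-phase with Gaussian noise; no partial
  volume beyond the PSF, no artifacts.
- Individual 2-voxel shells inherit EDT lattice banding (above); analyses
  needing continuum-accurate single-shell volumes should use the 5-voxel
  shells or unions.
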