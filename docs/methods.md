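# Methods

`ihcmap` computes n-gene protein-expression signature maps from digitized
serial-section slides: one H&E reference carrying pathologist annotations,
plus one IHC slide per marker stained with a brown DAB chromogen and a blue
hematoxylin counterstain. This note documents the model, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## Coordinate conventions and transforms

All images use 0-based pixel indices with `x` = column (rightward), `y` =
row (downward), origin at the top-left; continuous coordinates refer to
pixel centers. A slide-to-slide transform is

1. a **dihedral pre-operation** — one of the eight flip/90-degree symmetries
   of the image rectangle (sections are placed on glass in arbitrary flip
   and quarter-turn orientations), then
2. a **continuous rotation** `theta` (degrees, positive = clockwise as
   displayed) about the center of the post-dihedral rectangle,
   `((w'-1)/2, (h'-1)/2)`, then
3. a **translation** `(tx, ty)` in pixels.

Rotation pivot and sign convention are package choices (they are exposed in
the transform JSON); the center pivot keeps the coarse and fine stages
commutative with downsampling. Inverses are exact: the dihedral part
conjugates the rotation (theta negates unless the dihedral op contains a
reflection) and the residual translation is solved numerically; round-trip
error is < 1e-12 px in practice, tested against a 1e-6 px contract. No
shear, affine or deformable component is modeled.

Physical scale is one global microns-per-pixel scalar per image, read from
TIFF/PNG resolution metadata where present, 0.5 um/px (a 20x whole-slide
scan) otherwise.

## Registration

Each IHC image is aligned to the reference in two steps.

**Coarse (dihedral) alignment** evaluates all eight symmetries on grayscale
thumbnails (longest side 128 px). Because the sections also differ by a
residual rotation and shift, raw thumbnail MSE misranks ops for off-center
tissue, so each op's cost is taken after a short bounded Powell refinement
of (theta, tx, ty) at thumbnail scale; the op with the lowest refined cost
wins. A manual mode accepts a user-chosen op instead, preserving the
eyeball-alignment workflow. Constant-intensity inputs return identity with
a warning.

**Fine rigid registration** minimizes the mean squared grayscale difference
(Rec. 601 luminance, 0.299 R + 0.587 G + 0.114 B) over the overlap region,
with rotation and translation only. "Location error" is deliberately *not*
the optimization target — it is the independent evaluation metric (see
Landmarks below). The search runs coarse-to-fine over a factor-2 pyramid
(coarsest level <= 128 px, working resolution capped at 1024 px on the
longest side; both images are downscaled by one common factor so the result
rescales exactly to base resolution). Warping is bilinear; pixels mapping
outside the moving image are excluded and the cost is normalized by the
overlap count; an overlap below 25% of the reference flags failure. The
optimizer is Powell's derivative-free method per level (deterministic,
bounded: +-20 degrees, translation +-25% of the level size) with per-level
evaluation budgets; each level's solution initializes the next, and the
final result is never allowed to be worse than its initialization at the
finest level.

Two numerical facts worth knowing:

- On two *independently noised* copies of the same image, the expected MSE
  at the true alignment is `2 sigma^2`; the optimizer may report slightly
  less because a sub-pixel shift lets bilinear interpolation average noise.
  The recovered transform stays at the true alignment well within tolerance.
- Synthetic parameter recovery (any dihedral op, |theta| <= 10 degrees,
  |t| <= 10% of a 1024 px image) is accurate to ~0.01 px and ~0.005 degrees,
  far inside the 0.5-degree / 2-px acceptance tolerance; the binding risk is
  the coarse op choice, which the refined search makes reliable.

## Analysis grid and Monte Carlo filtering

A half-open, axis-aligned grid (default 250 x 250 um = 0.25 x 0.25 mm^2
cells) tiles the reference frame; edge cells are clipped. Cell retention is
decided by uniform random point sampling — default 500 points per cell,
threshold 50% — applied to three tests in order:

1. **tissue**: fraction of points on the tissue mask;
2. **annotation**: fraction inside a *single* annotation layer's polygons
   (the layer with the highest fraction labels the cell; ties go to the
   layer listed first, with a warning). Requiring the threshold within one
   layer gives every retained cell an unambiguous region label for
   per-region statistics;
3. **negative regions**: cells at or above threshold inside any negative-pen
   polygon — drawn on *any* slide; polygons from IHC slides are first mapped
   to the reference through that stain's registered transform — are excluded.

One point sample per cell is drawn from an RNG substream keyed by
`(seed, row, col)`, so decisions are reproducible and independent of
evaluation order; the same sample serves all three tests. Point-in-polygon
uses the even-odd (crossing) rule with boundary points counted inside, so
self-intersecting hand-drawn outlines are handled predictably. Against
exact polygon-rectangle intersection areas, a 500-point sample misclassifies
a cell whose true overlap is outside (0.40, 0.60) with probability < 1e-5.

The tissue mask is a pragmatic foreground heuristic (no recipe is standard):
a pixel is tissue when its luminance is below 235 *or* its HSV saturation
exceeds 0.05, followed by morphological closing (disk radius 5 px at a
working resolution of at most 2048 px). Both thresholds are configurable.

## Positive pixel count (DAB scoring)

Pixels are classified in HSI space: intensity `I = (R+G+B)/3`, saturation
`S = 1 - min(R,G,B)/I`, hue on the standard RGB hexagon (red = 0, as a
fraction of the color circle). A pixel is candidate-positive when its
circular hue distance to the brown center (0.10) is within half the hue
width (0.50), `S >= 0.04`, and `I <= 220`; candidates are binned strong
(`I <= 100`), moderate (`100 < I <= 175`), weak (otherwise). These defaults
mirror the widely published defaults of the commercial Positive Pixel Count
v9 brown-staining algorithm; all are configurable. The default cell score
is the positive fraction `(weak+moderate+strong)/total`; an
intensity-weighted index `(1w+2m+3s)/(3 total)` is also provided.

Scoring happens at full resolution in each IHC image's **native** frame:
no resampling of the IHC raster ever occurs. A native pixel belongs to a
grid cell when its center, mapped forward through the registered transform,
lands inside the half-open cell rectangle in the reference frame. This is
equivalent to testing the pixel against the inverse-transformed cell
quadrilateral, but the half-open semantics make membership unambiguous
(no pixel is ever counted in two cells, and dihedral-only transforms score
bit-identically to scoring a pre-rotated raster). Cells mapping entirely
off the IHC image are flagged empty and excluded downstream.

## Signature combination

With per-stain scores `gene_i(x)` on a common grid, the signature score is
the weighted vote `S(x) = sum_i w_i gene_i(x)`, `w_i = sign_i * magnitude_i`.
Signs encode up-/down-regulation with respect to the outcome of interest.
Magnitudes normalize mean staining intensity: with `m_i` the mean score of
stain i over retained annotated cells pooled across all provided cases,
`magnitude_i = m_ref / m_i`. The reference stain defaults to the one with
the largest mean — so the strongest stain gets magnitude exactly 1.0 and
weaker stains are scaled up — and can be overridden. Weights are computed
once, pooled across cases, and applied uniformly to every case. `S` is
defined only where *all* stains are measured; cells missing any stain are
dropped, never imputed. Per-region five-number summaries (min, Q1, median,
Q3, max) use linear interpolation between order statistics (numpy's default,
"type 7"), fixed so box-plot comparisons are bit-reproducible.

The markers in the bundled examples (ACPP down-regulated and high-intensity;
CD34, MKI67 up-regulated at medium/low intensity) illustrate the machinery;
deriving clinically validated weights from outcome data is out of scope.

## Landmark error assessment

Registration accuracy is quantified independently of the registration cost:
corresponding landmarks marked in the IHC-native and reference frames are
compared after mapping the native landmark through the stored transform;
the Euclidean distance times microns-per-pixel is the registration error.
Reports give per-stain and pooled medians/maxima, a histogram (25 um bins
by default), and equivalents in malignant-cell diameters (15 um nominal
diameter, rounded half away from zero — note 398/15 -> 27 and 88/15 -> 6,
while 114/15 = 7.6 rounds to 8 under this rule). The benchmark-vs-native
comparison scores the same cases twice — once with gold-standard transforms,
once with pipeline-recovered ones — and reports per-region relative
differences of the five summary statistics.

## Synthetic data: what it emulates and what it does not

`ihcmap.synthetic` generates the study conditions every test runs under:
1024 x 1024 px slides at 2.5 um/px (a downsampled whole-slide field of
~2.6 mm), a chiral two-lobe tissue blob with harmonic boundary noise on a
white background, shared macro texture and nuclei speckle between sections,
two annotated regions ("3+3" non-aggressive, "4+3" aggressive, radius ~15%
of the field), and three stains whose planted DAB-positive fractions carry
a 3x up-regulated / (1/3)x down-regulated contrast between the regions
(ACPP 0.45 vs 0.15, CD34 0.04 vs 0.12, MKI67 0.015 vs 0.045, around
intermediate background levels). Cohorts draw per-case seeds from
`(seed, case index)` and randomize each stain's ground-truth move (uniform
dihedral op, rotation within +-10 degrees, translation within +-8% of the
image) and jitter planted fractions by +-20%.

Three constructions make tests sharp:

- Brown pixels are planted on a deterministic 16 x 16 Bayer ordered-dither
  pattern, not sampled i.i.d., so any region's realized positive fraction is
  exact to one dither quantum (1/256).
- Native IHC rasters are produced by nearest-neighbour warping of the
  reference-frame stain content: stain colors stay pure (no interpolated
  color mixtures that would confuse the hue gate), and dihedral-only moves
  are bit-exact.
- Landmarks are emitted in both frames through the exact ground-truth
  transform, so landmark errors isolate registration error only.

Limitations to keep in mind when extrapolating to real slides: adjacent
sections are modeled as *identical* tissue under a rigid move — there is no
section-to-section content change, tissue compression, stretching, folds or
stain variability, and noise is i.i.d. Gaussian. Landmark errors on this
synthetic cohort are therefore sub-pixel (a few tenths of a micron), orders
of magnitude below what real serial sections produce; the synthetic studies
validate the *software* (algebra, scoring, filtering, optimization), not the
biological registration difficulty. Deformable registration, color
deconvolution, compartment segmentation, and 3-D reconstruction are out of
scope.

## Problem sizes used in the shipped studies

The registration-recovery trial uses 20 single-stain pairs at 1024 px; the
benchmark-vs-native study uses a 10-case, 3-stain cohort (30 registrations,
150 landmark pairs, ~10-12 retained cells per case at the 250 um grid).
These sizes were chosen so the full validation suite completes on a single
CPU in minutes while keeping every statistical check well-powered (e.g.
the Monte Carlo misclassification bound above).
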