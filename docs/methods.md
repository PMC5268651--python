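# Methods

This note records the models, numerical choices and limitations behind
`nucseg`, in the order the pipeline runs.

## Coordinate and unit conventions

Images are 2-D rasters `pixels[y, x]` with isotropic calibration
(µm/pixel); anisotropic data is rejected at read time because every
physical parameter (dilation distance, band width, profile width,
curvature step) is specified in µm and converted to whole pixels by a
single routine, `round(value_um / pixel_size_um)`.  Contours are closed
polygons on pixel centers, stored counter-clockwise; the outward normal is
derived from that orientation and used consistently by the straightening
and reconstruction steps.  Rasterization uses the pixel-center-inside
rule, which makes mask → contour → mask a fixed point for the blob-like
regions this pipeline produces.

## Preprocessing

Rolling-ball background subtraction (radius in µm; large radii are
estimated at a coarser scale and resized, since the background is smooth
by construction) followed by at most one smoothing filter per run.
Defaults disable both: the segmentation stages are themselves robust to
moderate noise, and every enabled step is one more parameter to justify.

## Two-pass segmentation

The global pass thresholds the whole image with one of eight
histogram-based auto-threshold methods (Huang, Isodata, Li, MaxEntropy,
Mean, Otsu, Triangle, Yen).  All methods operate on a 256-bin histogram
built over the min–max range of the supplied population regardless of bit
depth, for parity with the ImageJ auto-threshold family.  Otsu's
between-class variance is exactly flat across empty bins between
well-separated modes; the implementation takes the middle of the maximal
plateau, the only choice that is independent of summation order.

Seeds are grown by at most `dilation_um` (default 3 µm) under a Voronoi
constraint computed on the Euclidean distance transform of the seed
raster — nearest seed *region*, not nearest centroid, so elongated seeds
claim their own surroundings.  The local pass re-thresholds each dilated
region from that region's pixels only; a constant region falls back to
the global threshold value.  Hole filling and largest-component selection
run after each pass.  Default methods are Triangle (global) and Mean
(local), the settings reported to perform best on real dysmorphic-nucleus
data; the synthetic benchmark sweeps combinations instead of trusting any
single pair (below).

## Contour refinement

The peri-contour band (half-width 1 µm, rows at 1 px spacing, so
`q = 2·round(1 µm / pixel) + 1`) is sampled along outward normals of a
periodic cubic spline through the contour, at
`r = max(32, round(perimeter_px))` arc positions; cubic interpolation,
edge-clamped at image borders.  Light spline smoothing (≈ 0.25 px
residual) removes raster staircase before normals are taken.  The
vertical Sobel response is signed so bright-inside → dark-outside is
positive, and negative responses are clamped to zero before column
normalization — otherwise a dark→bright debris edge could attain a column
maximum and hijack the path.

**Path objective and solver.**  The boundary is the column-monotone path
maximizing strength = gain/loss, where a transition from row *k* to row
*i* between adjacent columns accrues the normalized intensities of the
vertical run cells (from *i* toward *k*, excluding *k*, in the previous
column) plus the landing cell, and a loss of one per cell traversed; a
straight path therefore has loss = r.  The classical per-element greedy
recursion — keep, for every matrix element, only the strongest incoming
path — does **not** have optimal substructure for a ratio objective: a
prefix with lower strength but higher accumulated loss can win once a
weak suffix follows, and on random matrices the greedy backtrace is
measurably suboptimal on roughly one instance in ten.  `nucseg` therefore
solves the ratio objective exactly by Dinkelbach iteration: repeatedly
maximize the additive surrogate `gain − λ·loss` (a true dynamic program)
and update λ to the winning path's ratio until no path beats it.  The
greedy recursion's S/G/L matrices are still computed and exposed for
diagnostics.  Tie-breaks (relevant because every normalized column
attains 1.0, so distinct paths can have identical gain and loss) prefer
the smallest vertical displacement, then the smaller row index, applied
backwards from the smallest optimal final row; the brute-force test
oracle applies the same rule, and score comparisons use a 1e-9 tolerance
because sums accumulated in different orders differ by ulps.

**Closure.**  The path model is an open left-to-right sweep but the band
is circular, so the first ⌈r/10⌉ columns are appended at the right edge
to give the path closure context; the duplicate is discarded and any
residual start/end mismatch is blended over the final 5% of columns.

**Reconstruction and iteration.**  Path rows map back through each
column's anchor and normal; collinear vertices are dropped.  Where
normals converge (concave crevices) the raw polygon can contain small
local self-intersecting loops; these are removed by polygon repair,
keeping the dominant ring.  A repair that loses more than half the area
is treated as failure and the pre-refinement contour is kept, with a
warning.  Refinement iterates until the maximum displacement in an
iteration falls below 0.5 px or 5 iterations — iteration is what lets the
contour walk into features deeper than the 1 µm half-band, at most
1 µm per iteration by construction.

## Conditional watershed

The watershed runs on the Gaussian-smoothed (σ = 1 px) distance transform
of the ROI, seeded from its regional maxima; smoothing suppresses
spurious plateau maxima.  Each separation line is an ordered pixel chain;
at every line pixel an intensity profile is sampled perpendicular to the
local direction (5-pixel window) across 2 × 1.5 µm at 0.5 px steps, and
the per-offset median over line pixels forms the median profile — the
median is what makes single bright specks on the line irrelevant.  A
split is accepted only if both fragments exceed the minimum area and
min/max of the median profile is ≤ the cut-off (default 0.75); ratios
strictly above the cut-off mean insufficient decay and the fragments are
merged back.  Lines are evaluated in ascending ratio order (deepest
valley first) so multi-fragment ROIs resolve deterministically; the size
rule is applied before the decay rule as the cheaper test.  Newly split
contours are re-refined, closing the pipeline loop.

## Validation metrics

AHD and NSI as defined in the README; contours are densely resampled
(≤ 0.5 px spacing) before distance computation so vertex density cannot
bias the average, and NSI is computed on rasterized masks.  For identical
regions the non-overlap form forces NSI = 0, which fixes the scaling:
non-overlapping area over the *sum* of areas with the intersection
counted twice.  The positive control averages over unordered observer
pairs (self-pairs would deflate it by a third and contradict its meaning
as inter-observer disagreement).  Automatic ↔ ground-truth correspondence
uses Hungarian assignment on the mask-overlap matrix; unmatched contours
are reported, not scored.  Records with a degenerate (zero) positive
control are flagged and excluded from summaries.

## Features

Shape features come from the polygon (shoelace area, polygon-length
perimeter) and from the second-order central moments of the rasterized
region (fitted ellipse).  Total curvature resamples the boundary at
0.5 µm — below typical bleb radii, above pixel noise — and sums absolute
turning angles; any convex contour gives 2π, protrusions add turning.

Elliptic Fourier descriptors use the Kuhl–Giardina chain formulation with
normalization for starting point, rotation and size by the first
harmonic; the per-harmonic amplitude is `√(a²+b²) + √(c²+d²)` and the
"summed EFD" adds harmonics 2..20 (harmonic 1 is the normalization
ellipse).  Twenty harmonics capture µm-scale blebs on 10–15 µm nuclei.
One property worth knowing: under the canonical arc-length
parametrization an *eccentric* ellipse retains a small odd-harmonic tail
(≈ 0.013 at aspect 0.95, ≈ 0.12 at 0.6) because arc speed is not uniform
in the elliptic angle; only a circle scores ≈ 0.  Blebbed shapes score an
order of magnitude above either, so the score's discriminative use is
unaffected, but "ellipse = exactly zero" is an idealization.

GLCM texture quantizes in-mask intensities to 64 levels over the
per-nucleus min–max range (so absolute brightness does not masquerade as
texture), builds symmetric co-occurrence matrices at distance 1 px for
0°/45°/90°/135°, excludes pairs touching the outside of the mask, and
averages ASM, contrast, correlation, homogeneity and entropy over the
four angles.  Entropy is the designated discriminator for chromatin
ruffling (intensity gradients across morphologically similar nuclei).

Border-touching nuclei are flagged at segmentation time and excluded from
feature tables by default — their shapes are truncated by the field of
view.

## Classification

Balanced sampling (majority class downsampled to the minority count),
stratified 2/3–1/3 split, stratified 10-fold CV for hyperparameter
selection on the training set only; z-scoring lives inside the CV
pipeline so no test statistics leak into the fit.  SVM-RBF tunes C and γ
over a small grid; the random forest exposes the reported real-data
defaults (500 trees, 3 features per split) in its grid.  FNR counts
dysmorphic nuclei predicted normal — the clinically relevant miss.
Retraining appends labelled rows and refits with the same protocol.

Exploratory clustering follows the stated recipe — Ward linkage on
Manhattan distances of z-scored features — even though Ward's objective
classically assumes squared Euclidean distances; the report carries this
caveat.  PCA is provided for exploration; no feature selection is applied
before classification, as a PC1-based subset did not help on real data.

## Synthetic data: what it emulates, and what it does not

Nuclei are rendered from analytic quasi-signed-distance fields (ellipse
body, circular blebs attached through necks with a crevice intensity dip,
low-frequency boundary roughness), composed with per-nucleus intensity
(90–200 on a background of 10 for segmentation fields), optional
chromatin-ruffling gradients and chromocenter spots, a planar
illumination ramp if requested, Gaussian optical blur (σ = 0.25 µm — the
ingredient that makes threshold choice matter, as in real optics), and
Poisson plus Gaussian (σ = 3) noise at 0.2 µm/pixel.  Ground-truth masks
come from the pre-blur geometry; for symmetric blur the 50% intensity
crossing sits on the true boundary, so the reference is unbiased.  The
valley depth between declared touching pairs is pre-compensated for the
blur so the rendered median-profile ratio matches the requested value.

Pseudo-observers perturb the true contours with 3–5-mode Fourier noise of
1–2 px amplitude along the normal, giving non-degenerate positive
controls with pairwise NSI ≈ 0.02–0.15, the right order for careful human
delineation.

What the generator does *not* emulate: a physical point-spread function
(the Gaussian blur has no Airy rings or defocus), depth structure (2-D
only), autofluorescence, debris, or mitotic figures.  Passing the
benchmark therefore demonstrates the algorithmic properties — dim-bleb
recovery, crevice tracing, split/merge discrimination, feature
separability — not performance on any particular microscope's data.

## Benchmark experiment design and problem sizes

* **Path-solver oracle**: 200 random bands, q ≤ 5, r ≤ 7, half of them
  column-normalized; exact strength agreement within 1e-12 and identical
  paths under the documented tie-break.
* **Threshold sweep**: 100 nuclei (50 normal, 50 dysmorphic) over 10
  fields; global methods {Otsu, Triangle, Mean} scored alone (1-pass) and
  crossed with the same three local methods (2-pass), before and after
  refinement, pooling integrated errors per condition — mirroring the
  method's own evaluation design, where conditions are compared as
  distributions over threshold combinations.  One-sided rank-sum tests
  compare adjacent conditions.
* **Bleb recovery**: 20 single-bleb nuclei at intensity fraction 0.3;
  recovery counts refined-contour pixels among the bleb pixels the global
  Otsu threshold missed.  Otsu is used as the global method here because,
  on this intensity distribution (dominant background mode, long bright
  tail), Triangle lands just above background and does not exhibit the
  global-threshold failure mode being measured.
* **Watershed battery**: 20 touching pairs (valley ratio 0.3–0.5) and 20
  bright-necked blebbed singles (profile ratio ≈ 0.9), decided at the
  default 0.75 cut-off with an 8 µm² minimum area so the intensity rule —
  not the size rule — is what is being tested.
* **Classifier benchmark**: 160 nuclei per class rendered singly;
  deliberate class overlap (rough-edged normals, small-bleb dysmorphics)
  reproduces the summed-EFD overlap real data shows, so error rates are
  small but not zero.
* **Retraining curve**: fixed stratified test third; per repeat, a random
  labelling order of the training pool, 20 initial labels plus 20 per
  round for 5 rounds, SVM-RBF refit each round; the reported curve is the
  across-repeat median of test MCR per round.  The median is taken over
  31 repeats because near the error floor (one to two misclassified test
  nuclei) a small-repeat median moves by a full 1/107 step; 31 repeats
  stabilize it while keeping the experiment under a few minutes.

Sizes were chosen so the full benchmark runs in roughly ten minutes on a
single desktop core.

## Known limitations

* The refinement band samples a fixed 1 µm half-width; structures thinner
  than ~2 px at the chosen magnification are below its resolution.
* The watershed evaluates separation lines pairwise; pathological
  many-way junctions (three or more nuclei meeting at a point) are
  resolved greedily in ratio order.
* The greedy S/G/L recursion is reported for inspection but is not the
  path actually used; the two coincide on ~90% of random instances.
* Contour CSV files are this repository's interchange convention; no
  binary ROI formats are read or written.
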