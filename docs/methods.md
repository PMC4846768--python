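# Methods

## Model curves

All reference shapes are closed plane curves sampled uniformly in the
parameter θ into polygons (default 720 vertices, < 0.01% area error
for every built-in; areas converge as O(1/n²)). Coordinates are
dimensionless; physical units enter only through image pixel size.

- **Cardioid** — r(θ) = a(1 + cos θ). The long axis lies along x with
  the lobe at x = 2a and the cusp at the origin. The cusp is always
  emitted as an exact vertex (for odd vertex counts the nearest grid
  sample is snapped onto θ = π). Area 3πa²/2.
- **Elongated cardioids** — the base cardioid stretched by the golden
  ratio Phi = (1+√5)/2 about its centroid along x or y. Whether the
  classical "x-elongated" seed models stretch along the cusp axis or
  perpendicular to it is not decidable from the literature's verbal
  description alone; here the convention is fixed (and documented, not
  attributed): x is the cardioid's own long/cusp axis. Elongation
  about the centroid keeps the transform translation-free.
- **Ellipse / circle** — (a cos θ, b sin θ); a = b degenerates to the
  circle.
- **Ovoid** — a Hügelschäffer-type egg: y² = b²(a² − x²)/(a² − 2wx + w²),
  with a the long semi-axis, b = aspect·a (default aspect 0.75, a
  typical egg-shaped seed proportion), and w = asymmetry·a,
  asymmetry ∈ [0, 1). asymmetry = 0 reduces vertex-for-vertex to the
  ellipse; the denominator is positive over the whole parameter range,
  so the curve is always simple. This is the smallest one-parameter
  asymmetric extension of the ellipse that spans the egg-shaped
  outlines the ellipse cannot capture.

## Silhouette extraction

Images are segmented with Otsu's between-class-variance threshold
(dark foreground by default, manual threshold and inverted polarity
available), connected components are labelled, holes filled (seed
silhouettes are solid), and components under `min_area_px` (default
50 px, a dust filter at the recommended ≥ 500 px/seed resolution) are
discarded.

Outlines are traced with marching squares at the 0.5 iso-level. Two
numerical choices matter here:

1. The binary mask is blurred slightly (Gaussian, σ = 1 px) before
   contouring. On a hard 0/1 mask the 0.5 iso-line is a 45° staircase
   that overestimates a disk's perimeter by ~5%, which would inflate
   rugosity and deflate circularity.
2. The traced contour is then smoothed with a circular moving average
   whose window is 1% of the contour length (minimum 3 vertices). The
   residual iso-line waviness has fixed pixel-scale amplitude, so
   without this step perimeter error would not vanish with increasing
   resolution; with it, the measured circularity of a rasterized disk
   converges monotonically to 1 (0.9959 → 0.99995 from 128 to 1024 px
   across) while area stays within 0.05%. The same smoothing bounds
   how much genuine sub-percent-wavelength boundary texture the
   perimeter can see; rugosity is accordingly a smoothed-outline
   measure.

Image coordinates (origin top-left, y down) are converted to y-up
mathematical coordinates before any model comparison, so silhouettes
and models share one chirality. L and W come from the minimum-area
rotated bounding rectangle (longer side = L); the fitted ellipse is
moment-matched — identical area-normalized second-order central
moments, computed exactly on the outline polygon by Green's-theorem
edge sums — with full-axis (diameter) lengths, so that aspect ratio
and roundness use the same axis convention.

## Shape indices

EI = L/W, AR = major/minor, FI = (L+W)/(2H), I = 4πA/Ps²,
R = 4A/(π·major²), rugosity = Ps/Pc. All are dimensionless and
scale-invariant. FI is three-dimensional: it is computed only from
explicit user-supplied L, W, H triples, never inferred from an image.
Raster discretization can push a bounded index marginally out of
range; excesses up to 10⁻³ are clamped with a logged warning, larger
ones are treated as upstream errors and rejected. Circularity uses
the raw (smoothed-outline) perimeter, not the convex perimeter.

## J index

J = C/(C+D) × 100 with C the intersection area and D the symmetric-
difference area, computed by exact polygon boolean operations
(shapely/GEOS). Since C + D equals the union area, J/100 is exactly
the Jaccard intersection-over-union; the identity is asserted
numerically on every call. Operands are put in a canonical order
first so J is exactly symmetric in its arguments.

**Alignment.** The model is scaled once so its area equals the seed's
(J measures shape, not size), centroids are matched, and principal
axes (second-moment eigenvectors) aligned. The principal axis leaves
a 180° ambiguity, and bilateral asymmetry a mirror ambiguity; the
four candidate poses (θ, θ+π) × (mirrored, not) are each scored by J
and the best kept. Optional refinement (default on for measurement
runs; off where bit-reproducibility across platforms matters more
than the last few hundredths of a J point) runs a Nelder–Mead search
over (rotation, dx, dy) from the best candidate; scale stays fixed by
the equal-area constraint. Rotationally degenerate seeds (near-equal
eigenvalues) default to axis angle 0 and rely on the J scoring.

**Regional J.** The plane is partitioned through the seed centroid
along and perpendicular to the alignment axis; Eq. J is applied to
the pieces of C and D clipped to each region, so regional C and D sum
exactly to the global values. Conventions, fixed here because the
field's usage does not pin them down: for cardioid models "right" is
the cusp side (the aligned model's −x direction); for other models
"right" is the aligned +x direction (the ovoid's blunt end). Q1 is
the upper-right quadrant, numbered counter-clockwise. A region
containing no seed area raises an error rather than returning a
meaningless 100.

**Morphotypes.** A: left ≥ 92 and right ≥ 80; B: left < 92,
right ≥ 80; C: left ≥ 92, right < 80; BC: both below. Thresholds are
parameters (other species will need other cutoffs). Boundary values
count as "above" so the four classes tile [0,100]² without an
unclassifiable measure-zero set. The classical verbal definition of
type BC contains an apparent left/right typo ("below 92 in the right
and below 80 in the right"); the self-consistent reading above is
used.

## Synthetic fixtures and the raster oracle

The generator emulates what a flatbed scan of a dark seed on a light
background looks like to the pipeline: a model polygon with smooth
radial noise, posed, rasterized with 4× supersampled anti-aliasing to
8-bit (background 230, foreground 25). Radial noise multiplies each
vertex radius about the centroid by 1 + δ(θ), δ a random Fourier
series over harmonics 2–8 with std σ; low-order harmonics keep
outlines smooth and simple (real seed outlines are smooth), and
multiplicative noise cannot push the radius negative at the cusp. If
a draw self-intersects, the harmonics are redrawn (error after 10
attempts). Every image is a pure function of its `FixtureSpec`
(single named RNG, no global state). Default noise σ = 0.02: a 2%
radial irregularity, the mid-range of what the generator's own noise
sweep (σ ∈ {0, 0.02, 0.05}) covers and commensurate with J values in
the mid-90s, the regime reported for well-matched real seed lots.

What the generator does **not** emulate: lighting gradients, shadows,
surface texture, touching seeds, camera distortion. Tests passing on
these fixtures validate the geometry and statistics of the pipeline,
not robustness to photographic artefacts.

`raster_j_oracle` recomputes J by brute force: both polygons are
sampled at pixel centers on a shared grid (even-odd scanline parity
fill — no polygon-clipping library anywhere in the code path) and
shared/unshared pixels are counted. It is the independent cross-check
for the exact boolean-geometry J; the two agree within 0.1 J points
at the default 2000-pixel grid on the standard fixture family.

## Problem sizes

Model polygons use 720 vertices by default; convergence checks use
10⁵. The test suite's Monte-Carlo sweeps use 50 oracle fixtures, 20
alignment poses, and 20 seeds per noise level at 300-pixel
resolution — sizes at which every distributional statement in the
suite is already stable at the asserted tolerances.

## Known limitations

- Touching seeds are not separated (no watershed); each connected
  component is one seed.
- FI requires calipered height; no 3-D inference.
- The perimeter estimator trades pixel-scale texture for convergence
  (see above); micro-rugosity below ~1% of the outline length is
  invisible by design.
- Alignment maximizes J greedily from four principal-axis candidates;
  pathological shapes with near-degenerate moments could in principle
  lock onto a local optimum, which refinement mitigates but does not
  provably eliminate.
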