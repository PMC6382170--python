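# Methods

This note records the conventions, numerical choices and known limitations
behind radfeat's feature values: radiomics results are only comparable across
implementations when these details are pinned down.

## Coordinate and mask conventions

Arrays are indexed `(z, y, x)` with `x` fastest; `spacing` and `origin` are
world-order `(dx, dy, dz)` / `(x0, y0, z0)` millimetres.  The voxel at index
`(k, j, i)` has its *center* at `origin + (i·dx, j·dy, k·dz)`; voxel extents
are half-open boxes around the centers.  Every inclusion rule in the package
(mask thresholding, sphere voxelization, RT-struct rasterization, peak
neighbourhoods) is a voxel-*center* rule; partial-volume fractions are never
used.

An ROI carries two masks.  The *morphological* mask is the delineated VOI
shape and feeds meshes, PCA axes and zone distances.  The *intensity* mask
starts equal to it and is shrunk — never grown — by re-segmentation and
outlier exclusion; it feeds every intensity-dependent feature.  The pipeline
order is fixed: interpolate → re-segment → exclude outliers → discretize.
Morphology, first-order statistics and local-intensity peaks always read the
un-discretized intensities.

## I/O

SimpleITK reads NIfTI, NRRD, Analyze and DICOM series (slices ordered by
spatial position, rescale slope/intercept applied on load; a directory with
more than one SeriesInstanceUID is rejected rather than guessed at).  Raw
voxel dumps require a JSON sidecar naming shape, dtype and spacing — "raw"
has no self-describing dialect.  Scalar masks are binarized by
`value ≥ ThresholdForVOI × max`, so an already-binary mask is invariant to the
threshold.  RT-struct contours are rasterized per slice by the even–odd rule
at voxel centers, with same-slice polygons unioned; whether the original
convention used centers or partial volumes is unknowable from the output
format, so the center rule is used and stated.

PET images can be scaled to SUV (`concentration × body mass / decayed
activity`, activity decayed as `A₀·2^(−Δt/T½)`, default T½ = 6586.2 s for
F-18), to SUL with the Janmahasatian sex-specific lean-body-mass formula
(current PET convention), or multiplied by an explicit factor that overrides
everything else.  Injected activity is assumed to be stated at injection
time; a configuration flag (`ActivityPreDecayed`) declares it pre-decayed,
because DICOM sources differ on this.

## Interpolation

Resampling aligns the output grid on the input physical center ("align by
center"), making results invariant under rigid translation of the origin, with
`n_out = ceil(n_in·s_in/s_out)` samples per axis.  Nearest and trilinear
interpolation clamp out-of-extent samples to the edge value; cubic splines use
mirror extension.  Slice-wise 2D mode resamples in-plane only and leaves the
slice axis untouched.  Interpolated masks are re-binarized at 0.5
(inclusive, configurable); note that a mask feature smaller than the target
spacing can legitimately dissolve below that threshold, which is reported as
an empty-VOI error rather than silently keeping a voxel.

## Discretization

FBN: `level = min(floor(Nb·(x − xmin)/(xmax − xmin)) + 1, Nb)` — bins are
half-open with a closed top bin, and a constant ROI maps to a single level.
FBN is invariant under positive affine intensity maps.  FBS:
`level = floor((x − b₀)/w) + 1`; the anchor `b₀` is the re-segmentation lower
bound when one is configured (keeping bins comparable across images) and the
ROI minimum otherwise.  With the bound anchor, discretizing before or after
range re-segmentation gives identical levels on surviving voxels.  The
intensity-volume histogram can be discretized independently; when no IVH rule
is set, a 1000-bin FBN grid approximates continuous intensities for the
fraction curves.

Outlier exclusion keeps values in `μ ± nσ` (default n = 3) with population σ
computed once on the incoming set — no iteration, so the operation is
idempotent only in the trivial sense and its order (after re-segmentation) is
fixed and documented.

## Morphology

The VOI surface is triangulated by marching cubes at iso-level 0.5 (Lewiner
case tables, i.e. asymptotic-decider disambiguation) on the binary field
padded by one background voxel so surfaces close at image borders.  The raw
iso-surface of a *binary* field carries a voxel staircase that biases surface
area upward by roughly 10% and the vertex cloud outward by half a voxel; the
mesh is therefore smoothed with Taubin's λ|μ schedule (uniform graph
Laplacian, λ = 0.5, μ = −0.53, 20 alternating passes), which removes the
staircase while approximately preserving enclosed volume.  Meshes with fewer
than 64 vertices are left unsmoothed — below that size the Laplacian contracts
the whole body (a single-voxel octahedron would collapse entirely).  On
voxelized spheres at the 3.1819 × 3.1819 × 2 mm PET spacing this brings
volume, area and sphericity within a few percent of the closed forms, the
accuracy regime expected of surface-based morphology at clinical voxel sizes.

Volume is the absolute signed-tetrahedron sum (divergence theorem); area the
triangle-area sum.  The serialized *maximum 3D diameter* is the largest
pairwise distance between ROI voxel centers — not mesh vertices — because the
mesh necessarily overshoots the true extent of a voxelized body by half a
voxel per side; the mesh-vertex variant is available separately.  Both scans
prune through the convex hull.

PCA axis lengths are `4√λₖ` from the population covariance of voxel centers;
vanished eigenvalues (planar/linear masks) give zero-length axes and zero
flatness, and only a rank-zero covariance is an error.  Densities use the
axis-aligned bounding box of the mesh and the PCA-aligned enclosing ellipsoid.
Centre-of-mass shift is the distance between the unweighted morphological
centroid and the intensity-weighted ROI centroid.  Integrated intensity uses
the mesh volume (choice documented; voxel-count volume is also reported as
`approximate volume`).

Moran's I and Geary's C use inverse-distance weights `w_ij = 1/d_ij` over all
ROI voxel pairs, exactly up to 20 000 voxels; larger ROIs are subsampled
deterministically (every k-th voxel in array order — spatially stratified and
free of any random state).  Constant ROIs have undefined statistics and
return NaN with a warning.

Intensity peaks average over a spherical neighbourhood of exactly 1 cm³
(r = (3000/4π)^{1/3} = 6.2035 mm) of voxel centers; the neighbourhood may
leave the mask but not the image, implemented as a ratio of two box
convolutions.  The local peak sits at the ROI maximum with ties resolved
toward the larger mean.

## Intensity features

First-order statistics use population moments (divide by N) and excess
kurtosis.  Percentiles interpolate linearly between order statistics (the
numpy `linear` rule); this choice is load-bearing for p10/p90, IQR and the
robust deviations and is therefore fixed.  "Median absolute deviation" is the
*mean* absolute deviation from the median, matching the IBSI sense of the
label.  Histogram gradients are central differences with one-sided ends; the
mode takes the lowest level on ties.

The IVH maps levels to intensity fractions `γ(i) = (i − imin)/(imax − imin)`
and uses the *strictly above* tail fraction for ν (the non-strict variant is a
flag; the two differ on small ROIs).  I10/I90 report the smallest intensity
whose tail fraction drops to 10%/90%, mapped back to original intensity units
when the source intensities are available.  A constant ROI has a degenerate
step curve: the fraction features are returned as zeros with a warning.

## Texture

All matrices use neighbourhood (Chebyshev) distance 1: 4 unique directions
per slice in 2D, 13 in 3D; NGTDM/NGLDM neighbourhoods are the 8/26 adjacent
voxels.  Neighbourhoods clip at ROI and image borders — partial
neighbourhoods are valid — which is what makes the NGLDM dependence count
percentage identically 1.  NGLDM's level-difference tolerance α defaults to
0 (exact level equality), matching run/zone equality.  GLCMs are symmetrized
(Haralick convention) before feature extraction.  Zones use 26-connectivity
in 3D and 8-connectivity in-plane; GLDZM zone distance is `1 +` the minimum
4-/6-connected step count to the first voxel outside the *morphological*
mask, with voxels beyond the image border counting as outside, so boundary
voxels have distance 1.  The grey-level axis spans 1..Ng with empty levels
retained (relevant for FBN and the non-uniformity features).

Aggregation: merging always sums count matrices *and their voxel scopes*
before normalization, so ratios such as run percentage stay in (0, 1] for
merged matrices.  Feature averaging skips empty matrices with a warning
rather than averaging in zeros.  For the one-matrix-per-slice families
(GLSZM, GLDZM, NGTDM, NGLDM) the direction-resolved 2D merge schemes
degenerate to the plain 2D merge, and only per-slice averaging, 2D merging
and the single 3D matrix are distinct; the 3D per-direction average is
undefined for them and rejected.  NGTDM coarseness is capped at 10⁶ where its
denominator vanishes (constant ROI).

## Synthetic data

The phantom module generates every test input.  `make_sphere` reproduces the
geometry of the NEMA image-quality phantom's fillable spheres (diameters
37–10 mm) voxelized by the center rule at the 3.1819 × 3.1819 × 2 mm PET
reconstruction spacing, with a 10:1 foreground:background intensity ratio
matching the phantom filling protocol; sphere centers sit on a voxel center
unless an offset is requested.  `make_grid` draws uniform integer levels
1..Ng from a seeded generator (full mask).  `make_digital_phantom` is a fixed
4×4×5-voxel grid with small integer levels and an irregular mask — a
synthetic, hand-checkable stand-in at the scale of the standard digital test
phantom, with reference values frozen from the brute-force oracle suite.

What these fixtures do *not* emulate: PET noise, point-spread-function blur,
partial-volume effects, or anatomically realistic texture.  Passing tests
demonstrate definition-correctness of the computations, not robustness to
scanner physics; on real scans the small-sphere morphology error is dominated
by partial-volume effects, which are out of scope here.

## Verification strategy

Every texture family is checked, matrix-by-matrix and feature-by-feature
under every aggregation scheme, against loop-level brute-force oracles
(exhaustive pair enumeration, run walking, BFS flood fill and distance maps,
per-voxel neighbourhood means) on seeded grids up to 6×6×4 with up to 4 grey
levels.  Moran/Geary are checked against the O(N²) double sum; mesh volume
and area against an independent mesh library; trilinear interpolation against
its exactness on affine fields; closed forms (checkerboard GLCM, constant-line
GLRLM, octahedron mesh, two-voxel Moran) are asserted directly.  Problem
sizes were chosen so the full suite runs in seconds while every code path is
exercised; the sphere suite uses the four largest NEMA diameters, where
voxelization error is small compared to the 5% reference band.

## Known limitations

- One image + one mask per invocation; multi-series DICOM folders and
  multi-label masks are rejected, and misaligned image/mask pairs are an
  error, not a resampling trigger.
- Texture distances > 1, Lloyd-max and histogram-equalization discretization
  are not implemented.
- Mesh smoothing is a global schedule; very thin (few-voxel-wide) structures
  above the 64-vertex guard may still lose more volume than convex bodies do.
- The IVH strict/non-strict choice and the FBS anchor choice change values on
  small ROIs; both are configurable and documented rather than hidden.
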