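# Methods

This note records the models, conventions and numerical choices behind
`cellshape3d`, and what the synthetic benchmarks do and do not show.

## Shape model and surface convention

Cells are voxel sets on an isotropic unit lattice (anisotropic voxel
sizes can be folded in through a scale triple before the spherical
conversion; default (1,1,1)). The surface is the *outer* one-voxel
shell: dilation with the full 3×3×3 structuring element
(26-connectivity) followed by removal of the original voxels,
S = (A ⊕ B) \ A. Two consequences worth knowing:

- The shell lies 0.5–1.7 voxels outside the true boundary, so the mean
  normalized radius of a voxel sphere is ≈ 1 + 1/R rather than exactly 1.
  This is a constant-offset bias that PCA's mean-centering absorbs; it
  matters only if absolute radii are interpreted.
- The dilation is a Minkowski sum on coordinates and is not clipped;
  cells touching the volume boundary are processed as-is with a warning.

An equivalent "inner shell" convention (A minus its erosion) exists; the
outer shell was chosen because it is defined for single-voxel cells and
keeps S disjoint from A.

## Spherical grid

θ runs 0..π inclusive in 53 equal rows (both poles present), φ runs
0..2π exclusive in 105 equal columns. Every grid node takes the radius
of the surface point whose *direction* is nearest on the unit sphere
(chordal nearest neighbor on unit vectors, which orders identically to
great-circle distance), ties broken toward the smaller radius by a
stable pre-sort. Pole rows replicate a single nearest point;
equiangular sampling oversamples the poles, which is accepted. The
sampling assumes star-shaped cells (one radius per direction); when a
node's nearest surface point is more than 15° away a warning flags a
sparse or non-star surface. Normalization divides by the
equivalent-sphere radius (3V/4π)^{1/3}, which makes the representation
exactly invariant to uniform scaling up to voxelization noise
(measured ≈ 4% mean deviation between R = 10 and R = 20 renderings of
one phenotype).

## Spherical-harmonic transform

Coefficients come from the analysis integral, not least squares:
f_lm = ∫ f conj(Y_lm) dΩ with Y_lm orthonormal and Condon–Shortley
phase (scipy's `sph_harm_y_all`). The θ integral uses Driscoll–Healy
weights on colatitudes θ_j = πj/n,

    w_j = (4/n) sin θ_j Σ_{k=0}^{n/2−1} sin((2k+1)θ_j)/(2k+1),

which integrate trigonometric polynomials of degree < n exactly; the φ
integral is a plain Riemann sum, exact for ≥ 2L+1 uniform samples. The
default 53×105 grid is *already* compliant for L = 25: its first 52
rows are precisely the DH nodes for n = 52 (the θ = π row has weight 0
and is dropped), and 105 ≥ 2L+1. The transform therefore runs directly
on the storage grid with no resampling, and analysis∘synthesis is exact
to machine precision on band-limited grids (measured ~5·10⁻¹⁵ relative
RMSE; the acceptance gate is 10⁻⁶). Grids with other row counts are
bilinearly resampled to a compliant geometry first, at interpolation-
level accuracy. Requesting L beyond what the grid can support raises
instead of silently aliasing.

Coefficient storage is complex, indexed (l, m) with negative m wrapped.
Two flattenings are provided: the complex ordering
[f₀₀, f₁,₋₁, f₁₀, f₁₁, …] and a real packing that exploits the
conjugate symmetry of real-valued sources (per degree: Re f_l0, then
Re/Im f_lm for m = 1..l), giving exactly (L+1)² = 676 real numbers at
L = 25. PCA on coefficient vectors uses the real packing, so the
harmonic feature dimension matches the printed coefficient count.

The per-degree power P(l) = Σ_m |f_lm|² satisfies Parseval
(Σ_l P(l) = ∫|f|² dΩ, checked against an independent Gauss–Legendre
oracle) and is invariant under rotation of the shape. For analytically
rotated band-limited functions the invariance is exact (10⁻¹⁴
measured); for *re-voxelized* rotations of a real cell, degrees whose
true power sits near the voxelization noise floor fluctuate at the
noise level (≈15% relative for a degree carrying <10% of the
deformation power at R ≈ 16) while dominant degrees stay within 5%.

## Eigen features

PCA is computed by SVD of the mean-centered data matrix; variables are
centered but not standardized because entries of one feature kind share
units. Component signs are fixed deterministically (largest-magnitude
entry positive) so bases reproduce across runs and platforms.
Projection uses the transpose of the orthonormal component matrix —
the Moore–Penrose inverse when K < d. Requested K is capped at
min(N−1, d) with a warning; an all-constant population yields a
zero-variance basis rather than an error. Bases serialize to JSON
(kind, mean, components, ratios) so new embryos can be projected onto a
previously fitted population basis. The eigenspectrum basis is fitted
by the same procedure on power spectra (dimension L+1); spectra cannot
be inverted back to a shape, which is the price of rotation invariance.

Static features are per-(cell, timepoint) weights; dynamic features are
their arithmetic mean over the cell's observed cell cycle (appearance
to division). Gaps inside a cell's observation window (failed
segmentation frames) are filled by componentwise linear interpolation;
extrapolation beyond the observed range is refused with a warning.

## Lineage analytics

Lineage names are systematic (child = parent name + one character;
founder relations P0→AB/P1, P1→EMS/P2, EMS→MS/E, P2→C/P3, P3→D/P4 are
configurable), so trees are rebuilt from cell tables by longest-prefix
matching; unresolvable non-founders attach to a virtual root with a
warning. The average lineage takes per-cell arithmetic means of first
and last observation across the embryos containing the cell, and
per-minute across-embryo means of a chosen weight component, kept only
inside the averaged range. Cells with observation gaps keep a single
[first, last] span.

Threshold recognition scores each cell by the mean |value| over minutes
≥ 100 (the stage clock anchors the last 4-cell stage at 0 min; most
differentiation follows the ~100-cell stage at ~100 min). The paper
convention of reporting at fixed thresholds is kept via
`threshold_sweep`; the pipeline's `recognize_cells` sweeps the score
range and reports the best-F1 row, since absolute weight scales depend
on the fitted basis and population. The reduction of per-minute values
to one score per cell (mean of absolutes) is a package choice; any
monotone alternative (max, median) gives the same calls on well-
separated populations.

## Clustering comparison

K-means, DBSCAN and hierarchical linkages (ward, average, complete —
elsewhere called "maximum" — and single) run on weight tables with the
Euclidean metric (scikit-learn backends). The silhouette coefficient
excludes DBSCAN noise points, which inflates DBSCAN's score — its rows
carry an `inflated` flag. Singleton clusters score 0 by the standard
convention. Because no cluster count is dictated by the data model,
the comparison harness sweeps k = 2..10 and reports each method's best
silhouette. K-means uses a fixed seed (default 0); DBSCAN's eps
defaults to the median 4-NN distance.

## Synthetic data: what it emulates, what it does not

The generator renders star-shaped cells as radial modulations of a
sphere — sphere, ellipsoid, equatorial ring depression (Gaussian in θ,
default depth 0.35, half-width 0.35 rad: the skin-cell phenotype), and
azimuthally lobed — plus seeded band-limited (l ≤ 4) radial noise
(default 3% RMS) so instances differ. Defaults mirror the study's
framing: a 220-minute window sampled every 5 min, 40 terminal cells in
a binary lineage with systematic names, one equal time band per
generation with ±2 min per-embryo jitter, 30%/70% skin/other fates on
the leaves, cell radius 10 ± 15% voxels. Cells pack on a lattice with a
2-voxel margin (placement only has to keep labels disjoint). Everything
is driven by seeds; the same seed regenerates an embryo bit for bit.
The in/out voxel decision evaluates the noise field only on the shell
of voxels a rigorous sup bound cannot decide — an optimization proven
output-identical in tests.

Not emulated: membrane mechanics and cell–cell contact deformation,
imaging PSF/noise, segmentation errors, anisotropic voxels, non-star
shapes, or division-timing biology. Passing benchmarks therefore show
that the *pipeline* recovers planted morphological structure under
voxelization and sampling noise — not that real hypodermal cells are
detectable at these rates; the headline dataset-dependent numbers of
the motivating study (population silhouettes, precision/recall tables,
explained-variance percentages) are reproduced qualitatively only.

## Problem sizes and degenerate inputs

Benchmarks use radius-10–16 cells (≈4·10³–1.7·10⁴ voxels), 20
band-limited fixtures, 20 rotations per fixture, a 40-leaf embryo
(~630 cell instances) and 24-instance clustering populations — sizes at
which every check runs in minutes on one CPU while keeping voxelization
error well below the planted effects. Degenerate inputs fail loudly:
empty clouds, surface points on the centroid, non-integer volumes,
double normalization, L beyond the grid's band limit, mixed-cell
dynamic averages, silhouette with one cluster.
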