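# cellshape3d

Quantification, reconstruction and lineage-aware analysis of 3D embryonic
cell shapes from labeled segmentation volumes.

During early embryogenesis (the *C. elegans* embryo from the 4- to
350-cell stage is the motivating system) cells deform in stereotyped,
fate-correlated ways — e.g. prospective skin (hypodermal) cells develop a
pronounced equatorial ring depression. Classical descriptors (volume,
surface area, mean curvature) are global and cannot reconstruct the shape
they summarize. `cellshape3d` turns each segmented cell into compact,
*reconstructable* feature vectors and provides the downstream analytics:
per-minute lineage trees averaged across embryos, threshold-based
cell-type recognition, and clustering comparisons. A seeded synthetic
embryo generator (voxelized phenotypes with known lineage and fates)
makes every step testable without microscopy data.

## Method

For a cell with voxel set *A* (volume *V* = |A|, centroid *c*):

1. **Surface extraction.** Dilate with the full 3×3×3 structuring
   element, *D* = *A* ⊕ *B*; the surface shell is *S* = *D* \ *A*.
2. **Spherical grid.** Each surface voxel maps to (r, θ, φ) about *c*;
   a 53×105 grid F(θᵢ, φⱼ) takes the radius of the nearest surface
   direction on the unit sphere and is normalized by the
   equivalent-sphere radius (3V/4π)^{1/3}, so a sphere ≈ 1 everywhere
   and size is removed.
3. **Spherical harmonics.** The grid is expanded in orthonormal complex
   harmonics (Condon–Shortley phase),
   f(θ,φ) = Σ_{l=0}^{L} Σ_{m=−l}^{l} f_lm Y_lm(θ,φ), with
   f_lm = ∫ f conj(Y_lm) dΩ evaluated by exact equiangular quadrature
   (Driscoll–Healy sampling theorem) rather than least squares. The
   default band limit L = 25 gives (L+1)² = 676 coefficients. The
   per-degree power spectrum P(l) = Σ_m |f_lm|² is invariant to rotation
   of the cell.
4. **Eigen features.** Mean-centered PCA over a cell population yields
   three weight-vector families: **eigengrid** (from flattened grids,
   d = 5565), **eigenharmonic** (from real-packed coefficient vectors,
   d = 676) and **eigenspectrum** (from power spectra, d = L+1). Weights
   w = Pᵀ(F − μ) reconstruct as F ≈ μ + Σ w_k p_k.
5. **Lineage analytics.** A cell at one timepoint gives a *static*
   feature; the mean over its cell cycle gives its *dynamic* feature.
   Trees from several embryos are averaged per cell name,
   Range(cell) = [mean start, mean end], with per-minute across-embryo
   averaged weights; thresholding |component 1| after ~100 min of
   development (4-cell stage = 0 min) calls deformation-marked cells,
   scored by precision/recall against a fate table.

## Worked example

`examples/01_single_cell_quantification.py` quantifies one synthetic
ring-depressed cell end to end:

```
cell voxels:            5643
surface shell voxels:   2734
grid shape:             (53, 105)  (values 0.77..1.23; a perfect sphere would sit near 1 everywhere)
SPHARM coefficients:    676  (degree <= 25)
reconstruction error:   0.0323 relative RMSE (voxelization roughness; band-limited shapes round-trip exactly)
dominant degrees:       [2, 4, 6]  (even zonal degrees carry the ring depression)
```

The grid dips to 0.77 at the equator — the planted depression — and the
even zonal degrees dominate the spectrum, as expected for a θ-symmetric
band. `examples/03_lineage_recognition.py` runs the full pipeline on a
generated embryo and sweeps the recognition threshold:

```
 threshold  n_predicted  precision  recall
      0.54           25      24.00  100.00
      2.92            6     100.00  100.00
best threshold 2.03: precision 100.0%  recall 100.0%
```

All six planted skin cells are recovered with no false positives once the
threshold clears the deformation gap. The other examples cover eigen-basis
fitting (`02`), the rotation-invariance advantage of eigenspectrum
clustering (`04`), and lineage heat-trees plus OBJ mesh export (`05`).

There is also a thin CLI mirroring the library
(`cellshape3d synth | surface | grid | spharm | spectrum | fit |
transform | dynamic | cluster | classify | plot-tree | mesh`).

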