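# biopsy3d

Label-free 3D reconstruction of optically cleared tissue punches from
multimodal focal-plane z-stacks.

Slide-free 3D pathology images an intact biopsy punch (~0.5–1 mm thick)
by optical sectioning instead of physical sectioning. A transmission
microscope records z-stacks in bright field (BF), dark field (DF) and two
epifluorescence channels (FL1/FL2, e.g. CK8-18 luminal and CK5 basal
epithelial markers). `biopsy3d` turns those stacks into a 3D model of the
tissue: its outer contour, its internal cavities — the duct and tubule
lumina whose architecture underlies prostate growth-pattern assessment —
and the registered scattering/fluorescence signal, composited into
transparent ray-cast renderings. It is aimed at researchers building or
evaluating transmission-based 3D biopsy scanners, and ships a synthetic
phantom generator so every stage can be validated end-to-end without
instrument data.

## Method

**Tissue detection from defocus physics.** In transmission imaging of
cleared tissue, structure far from the focal plane still contributes light,
but its high-spatial-frequency content is attenuated increasingly with
defocus distance. A position in a focal-plane image therefore carries
strong local high-frequency energy exactly when tissue sits *at* that
plane. The detector computes, per plane,

```
E(y, x) = Σ_{|u|,|v| ≤ r}  [ ∇²I ](y+u, x+v)²
```

with `∇²` the 3×3 discrete Laplacian and a square window of radius `r`
(default 7 px ≈ 15 µm at 1 µm/px). One global threshold — Otsu's split on
the pooled log-energy histogram — classifies every voxel as tissue or
not, and the thresholded mask is eroded with the same in-plane window to
undo the window's dilation of tissue support. Stacking the planes yields
the full 3D segmentation; 26-connected non-tissue components that do not
touch the volume boundary are internal cavities, reported with their
equivalent spherical diameter `(6·V/π)^(1/3)` and kept when ≥ 50 µm.

**Around the core detector:**

- *Flat-field calibration* divides each plane by a per-channel reference
  image (rescaled by its mean) to remove illumination non-uniformity.
- *Drift correction* estimates the translation between successive BF
  planes by zero-normalized cross-correlation with parabolic sub-pixel
  refinement, and resamples all channels onto plane 0's grid.
- *Deconvolution* estimates an experimental 3D PSF from a fluorescent-bead
  stack and sharpens DF/FL channels by Richardson–Lucy iteration
  (`e ← e · [(obs / (e⊛psf)) ⊛ psf*]`, 25 iterations by default).
- *Stitching* merges overlapping tiles via 3D difference-of-Gaussians
  keypoints with orientation-histogram descriptors, Lowe-ratio matching,
  RANSAC-style affine estimation and tri-linear fusion (reference tile
  wins in the overlap).
- *Rendering* casts orthographic rays with front-to-back alpha
  compositing, so interior lumina stay visible through the tissue surface.

The phantom module simulates all of this forward: a textured attenuating
slab with carved spherical/tubular cavities, per-plane Beer–Lambert BF
image formation with defocus-dependent Gaussian blur, gradient-magnitude
DF scattering, PSF-blurred FL channels, bead calibration stacks and sensor
noise — all bit-deterministic under a seed.

## Worked example

The built-in demo generates a phantom punch (48×160×160 voxels at
3×1×1 µm) containing a 50 µm and a 60 µm spherical cavity, simulates all
four channels plus a bead stack, injects per-plane drift, runs the full
pipeline and scores the result against the ground truth:

```bash
$ biopsy3d demo --seed 0 --out demo_out
{
  "cavity_precision": 1.0,
  "cavity_recall": 1.0,
  "n_detected_enclosed": 2,
  "n_truth_cavities": 2,
  "registration_residual_px": 0.021656822840377014,
  "tissue_dice": 0.9916005469762299
}
```

Reading the scorecard: both ground-truth cavities were recovered as
distinct enclosed components with no false positives (`recall` and
`precision` 1.0); the voxelwise Dice overlap between the detected tissue
mask and the truth is 0.99; and after drift correction the residual
plane-to-plane translation re-estimates to 0.02 px (the injected drift was
up to 3 px). `demo_out/run/` holds the segmentation and cavity-label
TIFFs, the cavity morphometry table, the shift table, deconvolved stacks,
rendered rotation frames and a manifest with per-output checksums.

The same stages are available on real data as `biopsy3d segment`,
`register`, `deconvolve` and `biopsy3d run <config.yaml>`; see
`biopsy3d --help`.

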