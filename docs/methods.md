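# Methods

This note documents the models, parameter choices and numerical decisions
behind `biopsy3d`, and what the synthetic-phantom validation does and does
not establish.

## Imaging model and conventions

A scan is one z-stack per modality (BF, DF, FL1, FL2): ordered 2D focal
planes with physical voxel spacing `(dz, dy, dx)` in µm. Conventions fixed
by this package (the acquisition geometry itself does not dictate them):

- `z_index` 0 is the plane nearest the objective; z increases into the
  sample.
- Voxel coordinates are 0-based `(z, y, x)`; the physical coordinate of a
  voxel center is `index × spacing`.
- Default spacing is `(3, 1, 1)` µm: 1 µm/px lateral sampling, and a 3 µm
  axial step — the axial sampling used by the confocal protocol that serves
  as this instrument class's benchmark; the actual axial step is always
  configurable.
- Flat-field correction divides by the reference image and rescales by the
  reference's spatial mean, so corrected intensities stay in the sensor's
  native range (downstream fixed thresholds remain meaningful) and a
  uniform reference is exactly the identity.

## Tissue segmentation

**Physics.** With increasing distance between a structure and the focal
plane, the structure's high-spatial-frequency contribution to the image is
attenuated increasingly; in-focus tissue texture is the dominant source of
local high-frequency energy. Thresholding that energy per position and per
plane yields a 3D tissue/no-tissue map without staining.

**Energy.** Windowed sum of the squared 3×3 discrete Laplacian (5-point
stencil) over a square window of radius `r` px. The Laplacian is the
minimal isotropic high-pass filter; a difference-of-Gaussians alternative
is selectable via `filter_id`. The energy is invariant to additive
intensity offsets and scales quadratically with gain, so the threshold is
the only intensity-dependent quantity. Borders are handled by edge
reflection. Default `r = 7` (15×15 px ≈ 15 µm at 1 µm/px): larger than
cell-scale texture, well below the 50 µm cavity scale.

**Threshold.** `"auto"` applies Otsu's bimodal split to the pooled 3D
energy volume *on a log axis*. Windowed squared-filter energy is
multiplicative and heavy-tailed: on a linear axis the broad tissue mode
dominates the histogram and Otsu's criterion splits inside it; on a log
axis both the noise-floor mode and the tissue mode are compact and the
split lands in the valley between them. A fixed numeric threshold and
per-plane thresholding remain available as options.

**Window-dilation compensation.** The windowed energy at a position
responds to tissue anywhere inside the window, so the raw threshold mask
over-extends tissue boundaries laterally by up to `r` px — equivalently,
cavities are eroded by up to `r` px per side, which biases every cavity's
equivalent diameter low by ~2`r` µm. Two corrective steps (enabled by
default, `window_compensation=True`) restore boundary localization:

1. non-tissue components smaller than one window area `(2r+1)²` voxels are
   filled — the detector cannot genuinely assert tissue absence over a
   region smaller than its own window, and step 2 would otherwise inflate
   single-voxel false holes to window size;
2. the tissue mask is eroded per-plane with the same `(2r+1)×(2r+1)`
   square window (volume faces are treated as tissue so the erosion does
   not consume tissue at the field edge).

This is a boundary-bias correction intrinsic to the detector, distinct
from the optional morphological cleanup (`cleanup_radius_px`, default
off). On phantoms it moves measured cavity diameters from ~10 µm below
truth to ~3 µm above truth.

**Cavities.** Non-tissue voxels are grouped by 26-connected labeling.
Components touching any volume face are surrounding medium
(`enclosed=False`); internal components are cavities. Size is summarized
as the equivalent spherical diameter `(6·N·dz·dy·dx/π)^(1/3)`, chosen
because it is closed-form testable; components under `min_diameter_um`
(default 50 µm) are dropped. Segmentation operates per-plane on 2D energy
with no axial smoothing, mirroring the plane-by-plane acquisition.

## Drift correction

The sample rests in imaging fluid; only the objective moves during a scan,
so small lateral drift can accumulate between exposures. The translation
of each BF plane relative to its predecessor is the argmax of
zero-normalized cross-correlation over integer shifts in
`[-max_shift, max_shift]²` (default 32 px), each evaluated on the actual
overlap region, refined per axis by a parabolic fit through the three
correlations around the peak (clamped to ±0.5 px). Ties break toward the
smallest shift magnitude, then smallest dy, then dx. Successive shifts are
composed cumulatively to plane 0 and undone by bilinear resampling; border
pixels exposed by the resampling take the plane's background median, so no
artificial high-contrast edge is created for the energy detector to see.
Only translation is modeled; in-fluid rotation between consecutive planes
is assumed negligible over one z-step.

## PSF estimation and Richardson–Lucy deconvolution

Bead stacks (3 µm polystyrene beads in an index-matched fluid) provide the
experimental PSF: local maxima at least 5 noise SDs above background (with
a floor of 5% of the dynamic range, so noiseless synthetic stacks do not
admit numerical residue as peaks) are accepted as beads if separated by at
least the patch diameter; patches are background-subtracted (border
median), aligned on their intensity centroid, averaged, clipped to ≥0 and
normalized to unit sum. The estimate is the *bead image* — true PSF
convolved with the 3 µm sphere — the standard experimental approximation.

Richardson–Lucy uses the multiplicative update
`e ← e · [(obs / max(e⊛psf, ε)) ⊛ psf-flipped]` with `e₀ = obs`,
`ε = 1e-12`, reflective boundary padding of half the PSF support, and
FFT-based convolution (direct convolution for kernels with ≤27 nonzero
voxels, which makes the delta-PSF fixed point exact to floating point —
the `max(·, ε)` guard rather than an additive `+ε` is what keeps
`obs/obs = 1` exact). Default 25 iterations with early stop when the
relative L1 change drops below 1e-4; the classical guarantees
(non-negativity, flux conservation with a unit-sum PSF, monotone
non-increase of the Kullback–Leibler divergence between the data and the
re-blurred estimate) are verified numerically in the test suite. A PSF
that does not sum to one is refused rather than silently renormalized.
One PSF is shared across DF/FL channels by default. BF is never
deconvolved — the segmentation's defocus physics *is* the BF model.

## Tile stitching

Keypoints are extrema of a difference-of-Gaussians stack over space and
scale. Scales are expressed in micrometres and converted to per-axis voxel
sigmas, so detection is isotropic in physical space on anisotropic grids.
The ladder starts at 1.2 µm (below the texture grain, so texture blobs
land in interior scales) with 3 steps per octave and 2 octaves by default;
a single-resolution stack is used rather than a downsampled pyramid —
simpler, and adequate at tile sizes of a few hundred voxels. Candidates
below `contrast_threshold = 0.01` (on range-normalized volumes) are
dropped, and edge-like responses are rejected when the spatial Hessian's
eigenvalue magnitudes spread by more than 10×. Descriptors are
Gaussian-weighted 3D gradient-orientation histograms (8 azimuth × 4
elevation bins), normalized, clipped at 0.2 and renormalized. They are not
rotation-invariant: tiles from a stage that translates in y (plus small
drift) do not rotate relative to each other.

Matching is nearest-neighbour with a 0.8 Lowe ratio and mutual-best
filtering. The affine is estimated robustly even though descriptor
matching on clean phantoms is already mostly correct: 500 minimal samples
of 4 non-coplanar correspondences, closed-form least-squares solve,
consensus at `inlier_tol_voxels` (default 1), then an iterated refit on
the consensus set; deterministic under the given seed. Fusion resamples
the moving tile tri-linearly onto the union bounding box (expanded only
where the moving tile overhangs by at least half a voxel) and keeps the
reference tile's voxels wherever both are defined — deterministic and
seam-visible for QC; a linear blend is available behind a flag. A
provenance mask (empty/reference/moving) accompanies the fused volume.

## Rendering

Orthographic rays, front-to-back compositing: per sample, channel
opacities (piecewise-linear transfer on intensity) add into a combined
alpha clipped at 1 with an opacity-weighted color; accumulation uses
`C += T·a·c`, `T *= 1-a`, terminating once accumulated opacity reaches
0.99 everywhere. Sample opacity is corrected for the ray step
(`a_step = 1-(1-a)^step`) so the image converges as the step shrinks;
default step 0.5 lateral voxels, tri-linear sampling on a camera-aligned
grid that coincides exactly with the voxel grid at zero rotation and unit
step (closed-form compositing tests rely on this). Azimuth rotates about
the image-vertical axis, elevation about the horizontal axis. Default
palette: segmentation white, DF green, FL1 green, FL2 red.

## Pipeline

Stage order: calibrate → register → segment → cavities → deconvolve →
stitch → render. Segmentation always runs on drift-corrected BF, never on
deconvolved data; deconvolution applies to DF/FL only; drift correction is
per tile, before stitching. Stages whose inputs are absent (no bead stack,
no second tile, no FL channels) are skipped and recorded. One global seed
fans out to per-stage seeds. The manifest records version, parameters,
seed and per-output SHA-256 checksums and deliberately contains no
wall-clock data, so identical runs produce bit-identical manifests.

## The phantom: what it emulates, and what it does not

The generator reproduces the features the pipeline's claims depend on:

- a light-attenuating tissue slab with band-limited Gaussian random
  texture (default grain σ = 1.5 µm — cellular-scale structure);
- carved spherical/tubular cavities, with luminal-marker truth (FL1) as a
  3 µm shell lining each cavity and basal/peripheral truth (FL2) as a
  3 µm shell at the outer tissue surface;
- BF formation as a Beer–Lambert projection: mean optical depth 1.0
  through the slab plus a *signed* per-plane texture modulation of
  amplitude 0.08 OD (bright-field refractive contrast redirects light both
  out of and into the collection aperture, so in-focus texture is
  symmetric about the local mean; the modulation amplitude is deliberately
  not tied to the mean absorption, which is divided across all planes);
- defocus as a lateral Gaussian blur growing linearly with distance:
  σ(Δz) = 0.5 µm + 0.45 µm/µm·|Δz|, the geometric blur cone of an NA 0.45
  objective — two interpretable parameters that reproduce exactly the
  frequency-attenuation property the detector measures, implemented in the
  frequency domain with periodic lateral boundaries;
- DF as the defocus-projected gradient magnitude of the tissue density
  (scattering proxy); FL as 3D-PSF-blurred label truth; bead stacks as
  3 µm spheres convolved with the PSF;
- additive Gaussian sensor noise, default SD 1.0 count against a
  full-scale of ~1000 (a 0.1% read-noise camera).

These photometric defaults are simulator conditions chosen once to emulate
a cleared punch on a decent CMOS camera; they are not measured instrument
values. Default phantom volumes are 64×256×256 voxels (desk-scale), not
the instrument's full 200×1080×1920 field.

Not emulated: wave-optical diffraction and depth-varying PSFs, refractive
index mismatch, clearing-induced shrinkage, photobleaching, multiple
scattering, or anatomically realistic duct trees. Passing phantom tests
therefore establishes the *algorithmic* claims (detection limit geometry,
registration/deconvolution/stitching recovery, determinism) under
controlled image formation — not performance on real tissue, where
contrast, texture statistics and aberrations differ.

## Validation scales and results computed by this repository

- Cavity detection limit (`scripts/acceptance.py`, also an acceptance
  test): 10 seeded phantoms, cavities graded 30–100 µm, default
  parameters; the limit is the smallest diameter class with 100% recovery
  (distinct enclosed component, centroid within 10 µm of truth) across all
  seeds and all larger classes.
- Oracle equivalence: on ≤ 8×16×16 volumes the segmentation matches a
  scalar per-voxel reimplementation bit-exactly (same floating-point
  summation order by construction).
- Registration: integer circular shifts exactly; 0.5 px interpolated
  shifts within 0.25 px; corrected stacks re-estimate to < 0.3 px mean
  residual.
- Richardson–Lucy: delta-PSF identity exact; flux drift < 0.1% per 10
  iterations; KL divergence non-increasing on a 32³ volume.
- Stitching: outlier-free affine to 1e-6; 30% outliers → inlier residual
  < 0.5 voxel over 20 seeds; two-tile phantom stitch correlates > 0.98
  with the unsplit volume in the overlap.
- Rendering: two-sample compositing matches the closed form to 1e-6.
- Determinism: the full demo re-run with the same seed is bit-identical
  (manifest and every output file).

## Known limitations

- The compensation erosion assumes tissue regions wider than one window;
  sheets thinner than ~15 µm laterally would be thinned or lost.
- A single global threshold assumes spatially uniform noise and texture
  statistics; strong depth-dependent signal loss would need the per-plane
  threshold option.
- Cavities separated from the medium or from each other by less than the
  window radius can merge after compensation.
- Descriptor matching is not rotation-invariant (acceptable for
  translation-stage tiling).
- NCC drift estimation needs textured planes; it raises on zero-variance
  planes (e.g. empty field of view).
- Equivalent spherical diameter under-represents the length of elongated
  tubules; the labeled cavity volume is exported so other morphometrics
  can be computed downstream.
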