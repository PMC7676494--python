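"""Synthetic tissue-punch phantoms with modality-specific image formation.

The generator emulates what the microscope sees when optically sectioning a
cleared tissue punch: a textured, light-attenuating tissue slab containing
internal cavities (tubule lumina), imaged as ~200 focal planes in bright
field (BF), dark field (DF) and two fluorescence channels.  The one physical
property the downstream segmentation relies on is reproduced explicitly:
with increasing distance between a structure and the focal plane, the
high-spatial-frequency content it contributes to the image is attenuated
increasingly.  Defocus is modeled as a distance-dependent Gaussian lateral
blur whose width grows linearly with defocus distance — the geometric blur
cone of a low-NA objective — rather than a full wave-optics PSF; two
interpretable parameters are enough to produce the frequency attenuation the
tissue detector measures.

Image formation models, per modality:

* **BF** — Beer–Lambert attenuation projection.  Every tissue plane carries
  an attenuation field (mean absorption plus band-limited texture); each
  source plane contributes to a focal-plane image after lateral Gaussian
  blur of width ``sigma(z) = blur_sigma_at_focus + blur_growth * |z - z0|``.
  Cavities and surrounding medium attenuate nothing, so they appear as
  bright, untextured transmission.
* **DF** — scattering proxy: source signal proportional to the local
  gradient magnitude of the tissue texture, projected with the same defocus
  blur rule (additive rather than attenuating).
* **FL** — the labeled structures (cavity-lining shells for the luminal
  marker, tissue periphery for the basal marker) blurred with the system's
  3D PSF.

All simulators draw noise from ``numpy.random.default_rng(seed)`` and are
bit-deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

from .deconvolution import PSFModel
from .volume_io import ChannelStack

# Default photometric / texture conditions of the simulator.  These are
# simulator parameters chosen to emulate a cleared punch on a CMOS camera
# (full-scale ~1000 counts, percent-level in-focus texture contrast,
# 0.1%-of-full-scale read noise); they are not measured instrument values.
DEFAULT_INTENSITY = 1000.0
DEFAULT_ATTENUATION = 1.0          # mean optical depth through the full slab
DEFAULT_TEXTURE_OD_SD = 0.08       # per-plane signed OD modulation by texture
DEFAULT_TEXTURE_CONTRAST = 1.0     # relative texture modulation (DF source)
DEFAULT_NOISE_SD = 1.0             # sensor noise SD in counts
DEFAULT_TEXTURE_GRAIN_UM = 1.5     # Gaussian correlation length of the texture


class CavitySpec(BaseModel):
    """One internal cavity: a sphere or an axis-aligned tube (cylinder)."""

    center_um: tuple[float, float, float]
    shape: Literal["sphere", "tube"] = "sphere"
    diameter_um: float = Field(gt=0)
    axis: Literal["z", "y", "x"] = "y"
    length_um: float | None = None  # tubes only; None = span the tissue extent


class DefocusModel(BaseModel):
    """Linear defocus blur law: lateral Gaussian sigma vs defocus distance.

    ``blur_growth_per_um`` defaults to 0.45 px/um, the geometric half-cone
    of an NA 0.45 objective (blur radius ~ NA * defocus distance).
    """

    blur_sigma_at_focus_um: float = Field(default=0.5, ge=0)
    blur_growth_per_um: float = Field(default=0.45, ge=0)

    def sigma_px(self, defocus_um: float, lateral_px_um: float = 1.0) -> float:
        """Lateral blur sigma in pixels at a given defocus distance."""
        sigma_um = self.blur_sigma_at_focus_um + self.blur_growth_per_um * abs(defocus_um)
        return sigma_um / lateral_px_um


class PhantomSpec(BaseModel):
    """Geometry, texture and noise of a synthetic tissue punch."""

    volume_shape: tuple[int, int, int] = (64, 256, 256)
    spacing_um: tuple[float, float, float] = (3.0, 1.0, 1.0)
    tissue_extent: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None
    cavities: list[CavitySpec] = Field(default_factory=list)
    texture_grain_um: float = Field(default=DEFAULT_TEXTURE_GRAIN_UM, gt=0)
    noise_sd: float = Field(default=DEFAULT_NOISE_SD, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _default_extent(self) -> "PhantomSpec":
        if self.tissue_extent is None:
            # leave a 2-voxel rind of surrounding medium along z only; the
            # punch fills the lateral field like a tissue slab under the lens
            nz, ny, nx = self.volume_shape
            self.tissue_extent = ((2, nz - 2), (0, ny), (0, nx))
        for (lo, hi), n in zip(self.tissue_extent, self.volume_shape):
            if not (0 <= lo < hi <= n):
                raise ValueError(f"tissue_extent {self.tissue_extent} outside volume {self.volume_shape}")
        return self

    @model_validator(mode="after")
    def _cavities_inside(self) -> "PhantomSpec":
        if self.tissue_extent is None:
            return self
        for cav in self.cavities:
            r_um = cav.diameter_um / 2.0
            for ax, ((lo, hi), d, c) in enumerate(
                zip(self.tissue_extent, self.spacing_um, cav.center_um)
            ):
                if cav.shape == "tube" and "zyx"[ax] == cav.axis:
                    continue
                if c - r_um < lo * d or c + r_um > hi * d:
                    raise ValueError(
                        f"cavity at {cav.center_um} um (d={cav.diameter_um} um) "
                        f"extends outside the tissue extent"
                    )
        return self


@dataclass
class PhantomTruth:
    """Ground-truth volumes against which every pipeline stage is scored."""

    tissue_mask: np.ndarray          # bool, True = tissue
    cavity_labels: np.ndarray        # int, 0 = not a cavity
    fl1_truth: np.ndarray            # luminal label density (cavity linings)
    fl2_truth: np.ndarray            # basal/peripheral label density
    texture: np.ndarray              # unit-variance band-limited field
    spacing_um: tuple[float, float, float] = (3.0, 1.0, 1.0)
    spec: PhantomSpec | None = field(default=None, repr=False)


def _band_limited_field(
    shape: tuple[int, int, int],
    sigma_vox: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian random field with Gaussian correlation, unit variance."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    return smooth


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build ground-truth tissue, cavity and fluorescence-label volumes.

    Tissue fills ``tissue_extent``; cavities are carved out of it.  The
    luminal fluorescence truth (FL1) is a ~3 um shell of tissue lining each
    cavity, emulating CK8-18-positive luminal cells; the basal/peripheral
    truth (FL2) is a shell of tissue at the punch's outer surface, emulating
    CK5-positive basal cells.  Deterministic given ``spec.seed``.
    """
    nz, ny, nx = spec.volume_shape
    dz, dy, dx = spec.spacing_um
    rng = np.random.default_rng(spec.seed)

    tissue = np.zeros(spec.volume_shape, dtype=bool)
    (z0, z1), (y0, y1), (x0, x1) = spec.tissue_extent
    tissue[z0:z1, y0:y1, x0:x1] = True

    zz = np.arange(nz)[:, None, None] * dz
    yy = np.arange(ny)[None, :, None] * dy
    xx = np.arange(nx)[None, None, :] * dx

    cavity_labels = np.zeros(spec.volume_shape, dtype=np.int32)
    for label, cav in enumerate(spec.cavities, start=1):
        cz, cy, cx = cav.center_um
        r = cav.diameter_um / 2.0
        if cav.shape == "sphere":
            inside = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        else:
            axes = {"z": (yy - cy, xx - cx), "y": (zz - cz, xx - cx), "x": (zz - cz, yy - cy)}
            a, b = axes[cav.axis]
            inside = a**2 + b**2 <= r**2
            if cav.length_um is not None:
                along = {"z": zz - cz, "y": yy - cy, "x": xx - cx}[cav.axis]
                inside = inside & (np.abs(along) <= cav.length_um / 2.0)
        inside = inside & tissue
        cavity_labels[inside] = label
    tissue[cavity_labels > 0] = False

    shell_um = 3.0  # one epithelial cell layer
    shell_vox = tuple(max(1, int(round(shell_um / d))) for d in spec.spacing_um)
    ball = _ellipsoid_structure(shell_vox)

    cavity_mask = cavity_labels > 0
    fl1 = (ndimage.binary_dilation(cavity_mask, structure=ball) & tissue).astype(np.float64)

    outside = ~tissue & ~cavity_mask
    fl2 = (ndimage.binary_dilation(outside, structure=ball) & tissue).astype(np.float64)

    sigma_vox = tuple(spec.texture_grain_um / d for d in spec.spacing_um)
    texture = _band_limited_field(spec.volume_shape, sigma_vox, rng)

    return PhantomTruth(
        tissue_mask=tissue,
        cavity_labels=cavity_labels,
        fl1_truth=fl1,
        fl2_truth=fl2,
        texture=texture,
        spacing_um=spec.spacing_um,
        spec=spec,
    )


def _ellipsoid_structure(radius_vox: tuple[int, int, int]) -> np.ndarray:
    rz, ry, rx = radius_vox
    z, y, x = np.ogrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    return (z / rz) ** 2 + (y / ry) ** 2 + (x / rx) ** 2 <= 1.0


def _defocus_project(
    source: np.ndarray,
    defocus: DefocusModel,
    focal_planes: int,
    spacing_um: tuple[float, float, float],
) -> np.ndarray:
    """Sum source planes into focal-plane images with distance-dependent blur.

    Each source plane z contributes to the image at focal plane z0 after a
    lateral Gaussian blur of sigma(|z - z0| * dz).  Implemented in the
    frequency domain (one rFFT per source plane, one inverse per focal
    plane), with periodic lateral boundaries — adequate for phantoms whose
    texture statistics are stationary.
    """
    nz, ny, nx = source.shape
    dz, dy, dx = spacing_um
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.rfftfreq(nx)[None, :]
    freq_sq = fy**2 + fx**2

    source_hat = np.fft.rfft2(source, axes=(-2, -1))
    # Gaussian transfer functions for every possible |z - z0| plane distance
    max_dist = max(nz, focal_planes)
    filters = np.empty((max_dist, ny, nx // 2 + 1))
    for d in range(max_dist):
        sigma = defocus.sigma_px(d * dz, lateral_px_um=dx)
        filters[d] = np.exp(-2.0 * np.pi**2 * sigma**2 * freq_sq)

    out = np.empty((focal_planes, ny, nx))
    acc = np.empty((ny, nx // 2 + 1), dtype=np.complex128)
    for z0 in range(focal_planes):
        acc[:] = 0
        for z in range(nz):
            acc += source_hat[z] * filters[abs(z - z0)]
        out[z0] = np.fft.irfft2(acc, s=(ny, nx))
    return out


def simulate_bf_stack(
    truth: PhantomTruth,
    defocus: DefocusModel | None = None,
    focal_planes: int | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
    intensity: float = DEFAULT_INTENSITY,
    attenuation: float = DEFAULT_ATTENUATION,
    texture_od_sd: float = DEFAULT_TEXTURE_OD_SD,
) -> ChannelStack:
    """Simulate the bright-field z-stack of a phantom.

    Transmission imaging with Beer-Lambert attenuation: every tissue plane
    carries a mean absorption (``attenuation`` spread over the volume depth)
    plus a *signed* refractive-contrast modulation of amplitude
    ``texture_od_sd`` — in bright field, index inhomogeneities redirect
    light both out of and into the collection aperture, so in-focus texture
    appears as symmetric bright/dark contrast about the local mean.
    Cavities and medium are transparent and untextured.  High spatial
    frequencies of the texture reach a focal-plane image only from source
    planes near focus.
    """
    defocus = defocus or DefocusModel()
    if focal_planes is None:
        focal_planes = truth.tissue_mask.shape[0]
    if focal_planes < 1:
        raise ValueError("focal_planes must be >= 1")
    noise_sd = truth.spec.noise_sd if (noise_sd is None and truth.spec is not None) else (noise_sd or 0.0)

    nz = truth.tissue_mask.shape[0]
    per_plane = attenuation / nz
    absorb = (per_plane + texture_od_sd * truth.texture) * truth.tissue_mask

    optical_depth = _defocus_project(absorb, defocus, focal_planes, truth.spacing_um)
    images = intensity * np.exp(-optical_depth)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        images = images + rng.normal(0.0, noise_sd, size=images.shape)
    np.clip(images, 0.0, None, out=images)
    return ChannelStack.from_array(images, channel="BF", spacing_um=truth.spacing_um)


def simulate_df_stack(
    truth: PhantomTruth,
    defocus: DefocusModel | None = None,
    focal_planes: int | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
    gain: float = 200.0,
    texture_contrast: float = DEFAULT_TEXTURE_CONTRAST,
) -> ChannelStack:
    """Simulate the dark-field z-stack: scattering by tissue inhomogeneities.

    The scattering source is the local gradient magnitude of the tissue
    texture (plus the strong index step at tissue borders), projected with
    the same distance-dependent defocus blur as bright field but additively
    — only scattered light reaches the objective.
    """
    defocus = defocus or DefocusModel()
    if focal_planes is None:
        focal_planes = truth.tissue_mask.shape[0]
    if focal_planes < 1:
        raise ValueError("focal_planes must be >= 1")
    noise_sd = truth.spec.noise_sd if (noise_sd is None and truth.spec is not None) else (noise_sd or 0.0)

    density = truth.tissue_mask * (1.0 + texture_contrast * truth.texture)
    gz, gy, gx = np.gradient(density, *truth.spacing_um)
    scatter = np.sqrt(gz**2 + gy**2 + gx**2)

    images = gain * _defocus_project(scatter, defocus, focal_planes, truth.spacing_um)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        images = images + rng.normal(0.0, noise_sd, size=images.shape)
    np.clip(images, 0.0, None, out=images)
    return ChannelStack.from_array(images, channel="DF", spacing_um=truth.spacing_um)


def simulate_fl_stacks(
    truth: PhantomTruth,
    psf: PSFModel,
    noise_sd: float | None = None,
    seed: int = 0,
    gain: float = 500.0,
) -> tuple[ChannelStack, ChannelStack]:
    """Simulate the two fluorescence z-stacks by 3D PSF blurring.

    FL1 images the luminal (cavity-lining) label truth, FL2 the
    basal/peripheral label truth.  Image formation is linear: the label
    density is convolved with the system PSF, scaled and noised.
    """
    from scipy.signal import fftconvolve

    noise_sd = truth.spec.noise_sd if (noise_sd is None and truth.spec is not None) else (noise_sd or 0.0)
    rng = np.random.default_rng(seed)
    stacks = []
    for channel, label_truth in (("FL1", truth.fl1_truth), ("FL2", truth.fl2_truth)):
        blurred = fftconvolve(label_truth, psf.kernel, mode="same")
        images = gain * blurred
        if noise_sd > 0:
            images = images + rng.normal(0.0, noise_sd, size=images.shape)
        np.clip(images, 0.0, None, out=images)
        stacks.append(ChannelStack.from_array(images, channel=channel, spacing_um=truth.spacing_um))
    return stacks[0], stacks[1]


def simulate_bead_stack(
    bead_positions: Sequence[tuple[float, float, float]],
    psf: PSFModel,
    shape: tuple[int, int, int],
    noise_sd: float = 0.0,
    seed: int = 0,
    bead_diameter_um: float = 3.0,
    amplitude: float = 1000.0,
    spacing_um: tuple[float, float, float] | None = None,
) -> ChannelStack:
    """Simulate a fluorescent-bead calibration stack.

    Beads are rendered as solid spheres of ``bead_diameter_um`` at the given
    voxel positions, convolved with the PSF, scaled and noised.  Positions
    must be separated by at least four PSF support radii so individual bead
    images do not overlap.
    """
    from scipy.signal import fftconvolve

    spacing = spacing_um or psf.spacing_um
    spacing_arr = np.asarray(spacing)
    support_radius_um = max(
        (s // 2) * d for s, d in zip(psf.kernel.shape, psf.spacing_um)
    )
    positions = [np.asarray(p, dtype=float) for p in bead_positions]
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            gap = np.linalg.norm((positions[i] - positions[j]) * spacing_arr)
            if gap < 4.0 * support_radius_um:
                raise ValueError(
                    f"beads {i} and {j} are {gap:.1f} um apart; need >= "
                    f"{4.0 * support_radius_um:.1f} um (4x PSF support radius)"
                )

    grids = np.meshgrid(*[np.arange(n) * d for n, d in zip(shape, spacing)], indexing="ij")
    density = np.zeros(shape, dtype=np.float64)
    r = bead_diameter_um / 2.0
    for pos in positions:
        pos_um = pos * spacing_arr
        dist_sq = sum((g - c) ** 2 for g, c in zip(grids, pos_um))
        density[dist_sq <= r**2] = 1.0

    images = amplitude * fftconvolve(density, psf.kernel, mode="same")
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        images = images + rng.normal(0.0, noise_sd, size=images.shape)
    np.clip(images, 0.0, None, out=images)
    return ChannelStack.from_array(images, channel="FL1", spacing_um=spacing)


def graded_cavity_spec(
    seed: int,
    diameters_um: Sequence[float] = (30.0, 50.0, 70.0, 90.0),
    volume_shape: tuple[int, int, int] = (64, 256, 256),
    spacing_um: tuple[float, float, float] = (3.0, 1.0, 1.0),
    noise_sd: float = DEFAULT_NOISE_SD,
) -> PhantomSpec:
    """Standard test phantom: a tissue slab with graded spherical cavities.

    Up to four cavities are centered on a 2x2 lateral grid at the slab's
    mid-depth; cavity diameters span the detection-limit study range.
    """
    if len(diameters_um) > 4:
        raise ValueError("at most 4 cavities fit the 2x2 layout")
    nz, ny, nx = volume_shape
    dz, dy, dx = spacing_um
    cz = (nz / 2.0) * dz
    centers = [
        (cz, ny * dy * 0.25, nx * dx * 0.25),
        (cz, ny * dy * 0.25, nx * dx * 0.75),
        (cz, ny * dy * 0.75, nx * dx * 0.25),
        (cz, ny * dy * 0.75, nx * dx * 0.75),
    ]
    cavities = [
        CavitySpec(center_um=center, shape="sphere", diameter_um=d)
        for center, d in zip(centers, diameters_um)
    ]
    return PhantomSpec(
        volume_shape=volume_shape,
        spacing_um=spacing_um,
        cavities=cavities,
        noise_sd=noise_sd,
        seed=seed,
    )
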