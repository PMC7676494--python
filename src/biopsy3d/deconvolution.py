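"""Experimental PSF estimation from bead stacks and Richardson-Lucy deconvolution.

The point-spread function (PSF) of the imaging system describes the sensor
response to a point source anywhere in the scanned volume.  Because
fluorescent beads dissolve in the clearing medium, the PSF is measured by
scanning 3-um polystyrene beads in an index-matched fluid; bead images are
detected, extracted, aligned and averaged into a single normalized 3D
kernel.  Scattering (DF) and fluorescence (FL) stacks are then deblurred by
Richardson-Lucy iteration, the standard multiplicative maximum-likelihood
scheme for Poisson-like imaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .volume_io import ChannelStack

#: Tolerance on "kernel sums to one".
_UNIT_SUM_TOL = 1e-6


@dataclass
class PSFModel:
    """Normalized 3D blur kernel.

    Attributes
    ----------
    kernel
        Non-negative 3D array summing to 1 (unit flux).
    spacing_um
        Physical voxel spacing (dz, dy, dx) of the kernel grid.
    center
        Voxel index (z, y, x) of the kernel peak.
    """

    kernel: np.ndarray
    spacing_um: tuple[float, float, float]
    center: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        if self.kernel.ndim != 3:
            raise ValueError("PSF kernel must be 3D")
        if np.any(self.kernel < 0):
            raise ValueError("PSF kernel must be non-negative")
        total = float(self.kernel.sum())
        if not np.isclose(total, 1.0, rtol=0, atol=_UNIT_SUM_TOL):
            raise ValueError(f"PSF kernel must sum to 1, got {total}")
        if self.center is None:
            self.center = tuple(int(i) for i in np.unravel_index(np.argmax(self.kernel), self.kernel.shape))

    def save(self, path: str | Path) -> Path:
        """Save kernel as multi-page TIFF with a JSON sidecar for metadata."""
        import tifffile

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(str(path), self.kernel.astype(np.float32), photometric="minisblack")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"spacing_um": list(self.spacing_um), "center": list(self.center)})
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PSFModel":
        import tifffile

        path = Path(path)
        kernel = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
        kernel = kernel / kernel.sum()
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        return cls(kernel=kernel, spacing_um=tuple(meta["spacing_um"]), center=tuple(meta["center"]))


def gaussian_psf(
    shape: tuple[int, int, int] = (15, 15, 15),
    spacing_um: tuple[float, float, float] = (3.0, 1.0, 1.0),
    sigma_um: tuple[float, float, float] = (4.0, 1.5, 1.5),
) -> PSFModel:
    """Synthetic anisotropic Gaussian PSF (axial blur wider than lateral).

    Used as the phantom's ground-truth optical model and as a fallback when
    no bead stack is available.
    """
    grids = [
        (np.arange(n) - (n - 1) / 2.0) * d
        for n, d in zip(shape, spacing_um)
    ]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    sz, sy, sx = sigma_um
    kernel = np.exp(-0.5 * ((zz / sz) ** 2 + (yy / sy) ** 2 + (xx / sx) ** 2))
    kernel /= kernel.sum()
    return PSFModel(kernel=kernel, spacing_um=tuple(float(s) for s in spacing_um))


def _detect_beads(volume: np.ndarray, min_distance_vox: tuple[int, int, int]) -> np.ndarray:
    """Local-maximum bead candidates at least 5 noise SDs above background."""
    from skimage.feature import peak_local_max

    background = float(np.median(volume))
    noise_sd = 1.4826 * float(np.median(np.abs(volume - background)))
    # floor at 5% of the dynamic range so a noiseless stack (MAD ~ 0) does
    # not admit numerical residue as "peaks"
    threshold = background + max(5.0 * noise_sd, 0.05 * float(np.ptp(volume)))
    smoothed = ndimage.gaussian_filter(volume, sigma=1.0)
    peaks = peak_local_max(
        smoothed,
        min_distance=int(max(min_distance_vox)),
        threshold_abs=threshold,
        exclude_border=False,
    )
    return peaks


def estimate_psf(
    bead_stack: ChannelStack,
    bead_diameter_um: float = 3.0,
    patch_radius_um: tuple[float, float, float] = (21.0, 10.0, 10.0),
) -> PSFModel:
    """Estimate the PSF by averaging aligned bead images.

    Bead centroids are detected as local maxima well above background, a
    patch is extracted around each, background (patch border median) is
    subtracted, patches are aligned on their intensity centroid, averaged,
    clipped to non-negative and normalized to unit sum.

    The returned kernel is the image of a bead, i.e. the true PSF convolved
    with the bead's finite diameter; for beads small relative to the PSF
    this is the standard experimental approximation.
    """
    volume = bead_stack.to_array().astype(np.float64)
    spacing = bead_stack.spacing_um
    radius_vox = tuple(max(1, int(round(r / d))) for r, d in zip(patch_radius_um, spacing))

    peaks = _detect_beads(volume, radius_vox)
    if len(peaks) == 0:
        raise ValueError("no beads detected in stack")
    # overlapping beads would corrupt the average
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            gap_um = np.linalg.norm((peaks[i] - peaks[j]) * np.asarray(spacing))
            if gap_um < 2.0 * max(patch_radius_um):
                raise ValueError("beads closer than the patch diameter; cannot extract clean PSF")

    patches = []
    pad = radius_vox
    padded = np.pad(volume, [(p, p) for p in pad], mode="reflect")
    for peak in peaks:
        lo = [peak[a] for a in range(3)]
        patch = padded[
            lo[0] : lo[0] + 2 * pad[0] + 1,
            lo[1] : lo[1] + 2 * pad[1] + 1,
            lo[2] : lo[2] + 2 * pad[2] + 1,
        ].copy()
        border = np.concatenate([patch[0].ravel(), patch[-1].ravel(), patch[:, 0].ravel(), patch[:, -1].ravel()])
        patch -= np.median(border)
        np.clip(patch, 0, None, out=patch)
        if patch.sum() <= 0:
            continue
        # sub-voxel centroid alignment
        com = ndimage.center_of_mass(patch)
        target = tuple((s - 1) / 2.0 for s in patch.shape)
        offset = [t - c for t, c in zip(target, com)]
        patch = ndimage.shift(patch, offset, order=1, mode="constant", cval=0.0)
        np.clip(patch, 0, None, out=patch)
        patches.append(patch)
    if not patches:
        raise ValueError("no usable bead patches")

    kernel = np.mean(patches, axis=0)
    np.clip(kernel, 0, None, out=kernel)
    kernel /= kernel.sum()
    return PSFModel(kernel=kernel, spacing_um=spacing)


def _convolve(volume: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size convolution; direct for tiny kernels (exact for deltas)."""
    if np.count_nonzero(kernel) <= 27:
        return ndimage.convolve(volume, kernel, mode="reflect")
    pad = [min(s // 2, v) for s, v in zip(kernel.shape, volume.shape)]
    padded = np.pad(volume, [(p, p) for p in pad], mode="reflect")
    out = fftconvolve(padded, kernel, mode="same")
    sl = tuple(slice(p, p + n) for p, n in zip(pad, volume.shape))
    return out[sl]


def richardson_lucy(
    observed: ChannelStack,
    psf: PSFModel,
    iterations: int = 25,
    epsilon: float = 1e-12,
    rel_tol: float = 1e-4,
) -> ChannelStack:
    """Richardson-Lucy deconvolution of a non-negative stack.

    Multiplicative update ``e <- e * ((observed / max(e * psf, epsilon)) * psf_flipped)``
    starting from ``e = observed``, with reflective boundary handling.  A
    delta PSF is a fixed point of the update, the estimate stays
    non-negative, and with a unit-sum PSF total flux is conserved away from
    boundaries.  Iteration stops early once the relative change of the
    estimate drops below ``rel_tol``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    total = float(psf.kernel.sum())
    if not np.isclose(total, 1.0, rtol=0, atol=_UNIT_SUM_TOL):
        raise ValueError(f"PSF must be unit-sum (got {total}); refusing to renormalize silently")

    observed_arr = observed.to_array().astype(np.float64)
    if np.any(observed_arr < 0):
        raise ValueError("observed stack must be non-negative")
    kernel = psf.kernel
    kernel_flipped = kernel[::-1, ::-1, ::-1]

    estimate = observed_arr.copy()
    for _ in range(iterations):
        blurred = _convolve(estimate, kernel)
        ratio = observed_arr / np.maximum(blurred, epsilon)
        update = _convolve(ratio, kernel_flipped)
        new_estimate = estimate * update
        np.clip(new_estimate, 0, None, out=new_estimate)
        denom = float(np.abs(estimate).sum())
        change = float(np.abs(new_estimate - estimate).sum()) / denom if denom > 0 else 0.0
        estimate = new_estimate
        if change < rel_tol:
            break

    return ChannelStack.from_array(estimate, channel=observed.channel, spacing_um=observed.spacing_um)
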