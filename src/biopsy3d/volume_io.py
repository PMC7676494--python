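"""Multimodal z-stack data model, multi-page TIFF I/O and flat-field calibration.

A scan of one optically cleared tissue punch consists of one z-stack per
imaging modality: bright field (BF), dark field (DF) and up to two
epifluorescence channels (FL1, FL2).  Each stack is an ordered series of 2D
focal-plane images acquired by optical sectioning; page order in the TIFF
file equals z order.  Plane ``z_index`` 0 is the plane nearest the objective
and z increases into the sample.  Voxel coordinates are 0-based ``(z, y, x)``
and the physical coordinate of a voxel center is ``index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

#: Recognized imaging modalities.
MODALITIES = ("BF", "DF", "FL1", "FL2")

#: Default physical voxel spacing (dz, dy, dx) in micrometres.  Lateral
#: sampling of the instrument is 1 um/px; the axial step defaults to 3 um.
DEFAULT_SPACING_UM = (3.0, 1.0, 1.0)


@dataclass
class ImagePlane:
    """One focal-plane image of a single modality.

    Parameters
    ----------
    pixels
        2D array of non-negative, finite intensities.
    z_index
        Position of the plane in its stack (0 = nearest the objective).
    modality
        One of ``BF``, ``DF``, ``FL1``, ``FL2``.
    wavelength_nm
        Illumination/emission wavelength, if known.
    """

    pixels: np.ndarray
    z_index: int
    modality: str
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"plane pixels must be 2D, got ndim={self.pixels.ndim}")
        if self.z_index < 0:
            raise ValueError("z_index must be >= 0")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("plane contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValueError("plane contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ChannelStack:
    """Ordered focal planes of one modality with physical voxel spacing."""

    planes: list[ImagePlane]
    spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM
    channel: str = "BF"

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("a ChannelStack needs at least one plane")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing_um must be three positive numbers (dz, dy, dx)")
        shape0 = self.planes[0].shape
        for i, p in enumerate(self.planes):
            if p.shape != shape0:
                raise ValueError(f"plane {i} shape {p.shape} differs from {shape0}")
            if p.modality != self.channel:
                raise ValueError(f"plane {i} modality {p.modality!r} != channel {self.channel!r}")
            if p.z_index != i:
                raise ValueError(f"plane {i} has z_index {p.z_index}; expected consecutive from 0")

    @classmethod
    def from_array(
        cls,
        volume: np.ndarray,
        channel: str = "BF",
        spacing_um: Sequence[float] = DEFAULT_SPACING_UM,
        wavelength_nm: float | None = None,
    ) -> "ChannelStack":
        """Build a stack from a (nz, ny, nx) array."""
        volume = np.asarray(volume)
        if volume.ndim != 3:
            raise ValueError("volume must be 3D (nz, ny, nx)")
        planes = [
            ImagePlane(volume[z], z_index=z, modality=channel, wavelength_nm=wavelength_nm)
            for z in range(volume.shape[0])
        ]
        return cls(planes=planes, spacing_um=tuple(spacing_um), channel=channel)

    def to_array(self) -> np.ndarray:
        """Stack planes into a (nz, ny, nx) array (a copy)."""
        return np.stack([p.pixels for p in self.planes], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        ny, nx = self.planes[0].shape
        return (len(self.planes), ny, nx)

    def __len__(self) -> int:
        return len(self.planes)


@dataclass
class FlatFieldReference:
    """Per-channel reference image for illumination flat-field correction.

    The reference is acquired without a sample (or, for FL, from a uniform
    fluorescent slide) and captures illumination non-uniformity plus pixel
    response non-uniformity of the sensor.  It must be strictly positive so
    division is safe everywhere.
    """

    reference: np.ndarray
    channel: str = "BF"

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=np.float64)
        if self.reference.ndim != 2:
            raise ValueError("flat-field reference must be 2D")
        if self.channel not in MODALITIES:
            raise ValueError(f"unknown modality {self.channel!r}")
        if not np.all(np.isfinite(self.reference)) or np.any(self.reference <= 0):
            raise ValueError("flat-field reference must be strictly positive and finite")


def read_stack(
    path: str | Path,
    channel: str,
    spacing_um: Sequence[float] = DEFAULT_SPACING_UM,
    wavelength_nm: float | None = None,
) -> ChannelStack:
    """Read a single-channel multi-page TIFF into a :class:`ChannelStack`.

    Page order is interpreted as z order.  Spacing is not read from TIFF
    metadata; supply it explicitly (sidecar config or flags).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tif:
        pages = [page.asarray() for page in tif.pages]
    if not pages:
        raise ValueError(f"{path} contains no pages")
    shape0 = pages[0].shape
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise ValueError(f"{path} page {i} is not a 2D grayscale image")
        if page.shape != shape0:
            raise ValueError(f"{path} page {i} shape {page.shape} differs from {shape0}")
    planes = [
        ImagePlane(page, z_index=z, modality=channel, wavelength_nm=wavelength_nm)
        for z, page in enumerate(pages)
    ]
    return ChannelStack(planes=planes, spacing_um=tuple(spacing_um), channel=channel)


def write_stack(stack: ChannelStack, path: str | Path) -> Path:
    """Write a stack as a multi-page grayscale TIFF (page order = z order).

    Integer dtypes round-trip bit-exactly; float stacks are stored as their
    native float dtype.
    """
    path = Path(path)
    volume = stack.to_array()
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), volume, photometric="minisblack")
    return path


def flat_field_correct(stack: ChannelStack, ref: FlatFieldReference) -> ChannelStack:
    """Divide every plane by the flat-field reference, preserving global scale.

    Each plane is divided pixelwise by the reference and multiplied by the
    reference's spatial mean, so a perfectly uniform reference leaves the
    stack unchanged and corrected intensities stay in the sensor's native
    range (important for downstream fixed thresholds).
    """
    if ref.reference.shape != stack.planes[0].shape:
        raise ValueError(
            f"reference shape {ref.reference.shape} does not match plane shape "
            f"{stack.planes[0].shape}"
        )
    scale = float(ref.reference.mean())
    gain = scale / ref.reference
    planes = [
        ImagePlane(
            np.asarray(p.pixels, dtype=np.float64) * gain,
            z_index=p.z_index,
            modality=p.modality,
            wavelength_nm=p.wavelength_nm,
        )
        for p in stack.planes
    ]
    return ChannelStack(planes=planes, spacing_um=stack.spacing_um, channel=stack.channel)
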