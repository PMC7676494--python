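"""Ray-casting volume renderer with transparency for multimodal composites.

The reconstructed data sets (tissue segmentation, dark field, two
fluorescence channels) are combined into one 3D visualization by casting
parallel orthographic rays through the volume and compositing color and
opacity front to back.  Because every voxel is rendered partially
transparent, internal structures — duct and tubule lumina — remain visible
through the outer tissue surface.

Each channel contributes a color and a piecewise-linear opacity transfer
function mapping voxel intensity to alpha.  At a sample point the channel
alphas combine into a premultiplied color, and samples accumulate along the
ray:

    C <- C + T * a * c        T <- T * (1 - a)

with early termination once the accumulated opacity reaches 0.99
everywhere.  The renderer is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

RGB = tuple[float, float, float]

#: Default channel palette: segmentation white, DF green, FL1 (luminal)
#: green, FL2 (basal) red.
DEFAULT_PALETTE: dict[str, RGB] = {
    "segmentation": (1.0, 1.0, 1.0),
    "DF": (0.0, 1.0, 0.0),
    "FL1": (0.0, 1.0, 0.0),
    "FL2": (1.0, 0.0, 0.0),
}


def opacity_transfer(points: Sequence[tuple[float, float]]) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise-linear intensity -> alpha transfer function.

    ``points`` is a sorted list of (intensity, alpha) control points; values
    outside the range take the terminal alphas.  All alphas must lie in
    [0, 1].
    """
    pts = sorted(points)
    xs = np.array([p[0] for p in pts], dtype=np.float64)
    ys = np.array([p[1] for p in pts], dtype=np.float64)
    if np.any(ys < 0) or np.any(ys > 1):
        raise ValueError("alpha control points must lie in [0, 1]")

    def transfer(values: np.ndarray) -> np.ndarray:
        return np.interp(values, xs, ys)

    return transfer


def linear_transfer(vmax: float, max_alpha: float = 0.1) -> Callable[[np.ndarray], np.ndarray]:
    """Simple ramp: alpha rises linearly from 0 at 0 to ``max_alpha`` at ``vmax``."""
    return opacity_transfer([(0.0, 0.0), (float(vmax), float(max_alpha))])


@dataclass
class RenderChannel:
    """One volume with its color and opacity transfer function."""

    volume: np.ndarray
    color: RGB
    transfer: Callable[[np.ndarray], np.ndarray]


@dataclass
class RenderSettings:
    """Camera and sampling settings for the orthographic ray caster.

    Azimuth rotates the sample about the image-vertical (y) axis, elevation
    about the horizontal (x) axis; at (0, 0) rays run along +z.  The ray
    step is expressed in lateral voxel units.
    """

    azimuth_deg: float = 0.0
    elevation_deg: float = 0.0
    step_voxels: float = 0.5
    background: RGB = (0.0, 0.0, 0.0)
    early_termination_alpha: float = 0.99


def _rotation_matrix(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Sample-to-camera rotation in physical (z, y, x) coordinates."""
    az = np.deg2rad(azimuth_deg)
    el = np.deg2rad(elevation_deg)
    # rotate about y (azimuth): mixes z and x
    r_az = np.array([[np.cos(az), 0.0, np.sin(az)], [0.0, 1.0, 0.0], [-np.sin(az), 0.0, np.cos(az)]])
    # rotate about x (elevation): mixes z and y
    r_el = np.array([[np.cos(el), np.sin(el), 0.0], [-np.sin(el), np.cos(el), 0.0], [0.0, 0.0, 1.0]])
    return r_el @ r_az


def _camera_grid(
    shape: tuple[int, int, int],
    spacing: np.ndarray,
    settings: RenderSettings,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int, int]]:
    """Affine map from camera-grid indices to volume voxel indices.

    Returns (matrix, offset, out_shape) for ``ndimage.affine_transform``.
    The camera grid spans the rotated volume's bounding box; lateral pixel
    pitch equals the volume's lateral spacing, the ray step is
    ``step_voxels`` lateral units.  At zero rotation with unit step the grid
    coincides exactly with the voxel grid.
    """
    rot = _rotation_matrix(settings.azimuth_deg, settings.elevation_deg)
    half_phys = (np.asarray(shape, dtype=np.float64) - 1.0) * spacing / 2.0
    half_cam = np.abs(rot) @ half_phys

    du = float(spacing[2])  # lateral pixel pitch in um
    dt = settings.step_voxels * du
    if dt <= 0:
        raise ValueError("ray step must be positive")
    steps = np.array([dt, du, du])
    out_shape = tuple(int(np.floor(2.0 * h / s)) + 1 for h, s in zip(half_cam, steps))

    # camera coords of out index k: (k - (K-1)/2) * step; volume index =
    # S^-1 R^-1 cam + center
    center_idx = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    scale_cam = np.diag(steps)
    matrix = np.diag(1.0 / spacing) @ rot.T @ scale_cam
    origin_cam = -(np.asarray(out_shape, dtype=np.float64) - 1.0) / 2.0 * steps
    offset = np.diag(1.0 / spacing) @ rot.T @ origin_cam + center_idx
    return matrix, offset, out_shape


def render(
    channels: Sequence[RenderChannel],
    settings: RenderSettings | None = None,
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Render a multimodal composite as an RGB image in [0, 1].

    All channel volumes must share one shape (and voxel spacing).  Rays are
    cast front to back; per sample, channel opacities add into a combined
    alpha (clipped at 1) and an opacity-weighted color.  Sample opacity is
    corrected for the ray step so the composite converges as the step
    shrinks.
    """
    if not channels:
        raise ValueError("at least one channel required")
    settings = settings or RenderSettings()
    shape = channels[0].volume.shape
    for ch in channels:
        if ch.volume.shape != shape:
            raise ValueError("all channel volumes must share one shape")
        if np.asarray(ch.volume).ndim != 3:
            raise ValueError("channel volumes must be 3D")

    spacing = np.asarray(spacing_um, dtype=np.float64)
    matrix, offset, out_shape = _camera_grid(shape, spacing, settings)
    identity = (
        settings.azimuth_deg % 360.0 == 0.0
        and settings.elevation_deg % 360.0 == 0.0
        and np.allclose(matrix, np.eye(3))
        and np.allclose(offset, 0)
        and out_shape == shape
    )

    resampled = []
    for ch in channels:
        vol = np.asarray(ch.volume, dtype=np.float64)
        if identity:
            resampled.append(vol)
        else:
            resampled.append(
                ndimage.affine_transform(
                    vol, matrix, offset=offset, output_shape=out_shape, order=1,
                    mode="constant", cval=0.0, prefilter=False,
                )
            )

    n_steps, height, width = out_shape
    colors = [np.asarray(ch.color, dtype=np.float64) for ch in channels]
    accum = np.zeros((height, width, 3))
    transmit = np.ones((height, width))
    t_floor = 1.0 - settings.early_termination_alpha

    for k in range(n_steps):
        alpha_sum = np.zeros((height, width))
        premult = np.zeros((height, width, 3))
        for ch, vol, color in zip(channels, resampled, colors):
            alpha_c = np.clip(ch.transfer(vol[k]), 0.0, 1.0)
            alpha_sum += alpha_c
            premult += alpha_c[..., None] * color
        alpha = np.clip(alpha_sum, 0.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sample_color = np.where(alpha_sum[..., None] > 0, premult / np.maximum(alpha_sum, 1e-300)[..., None], 0.0)
        if settings.step_voxels != 1.0:
            alpha = 1.0 - (1.0 - alpha) ** settings.step_voxels
        accum += (transmit * alpha)[..., None] * sample_color
        transmit = transmit * (1.0 - alpha)
        if transmit.max() < t_floor:
            break

    background = np.asarray(settings.background, dtype=np.float64)
    accum += transmit[..., None] * background
    return np.clip(accum, 0.0, 1.0)


def render_rotation_series(
    channels: Sequence[RenderChannel],
    settings: RenderSettings | None = None,
    n_frames: int = 36,
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[np.ndarray]:
    """Render frames at evenly spaced azimuths (full 360 degrees).

    Frame k sits at ``base_azimuth + 360 * k / n_frames``; frame 0 equals a
    single render at the base azimuth.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    settings = settings or RenderSettings()
    frames = []
    for k in range(n_frames):
        frame_settings = RenderSettings(
            azimuth_deg=settings.azimuth_deg + 360.0 * k / n_frames,
            elevation_deg=settings.elevation_deg,
            step_voxels=settings.step_voxels,
            background=settings.background,
            early_termination_alpha=settings.early_termination_alpha,
        )
        frames.append(render(channels, frame_settings, spacing_um=spacing_um))
    return frames


def save_frames(frames: Sequence[np.ndarray], directory: str | Path, prefix: str = "frame") -> list[Path]:
    """Write frames as 8-bit PNGs; returns the written paths."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, frame in enumerate(frames):
        path = directory / f"{prefix}_{k:03d}.png"
        iio.imwrite(path, (np.clip(frame, 0, 1) * 255).astype(np.uint8))
        paths.append(path)
    return paths
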