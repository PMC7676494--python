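"""Drift correction between successive focal planes by normalized cross-correlation.

During a z-scan only the objective moves, but the sample rests in imaging
fluid and can drift laterally between exposures.  The translation of each
bright-field plane relative to its predecessor is estimated by
zero-normalized cross-correlation (ZNCC) over an integer search window,
refined to subpixel precision with a parabolic fit, and the cumulative
shifts are undone by bilinear resampling onto the first plane's grid.
Shifts estimated on BF may be applied to the other channels of the same
acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume_io import ChannelStack, ImagePlane

DEFAULT_MAX_SHIFT_PX = 32


@dataclass
class PlaneShift:
    """Translation of plane k+1 relative to plane k (positive = content moved +)."""

    dy_px: float
    dx_px: float
    peak_ncc: float


def _zncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalized cross-correlation of two equal-shape arrays."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _parabolic_offset(left: float, center: float, right: float) -> float:
    """Subpixel offset of the vertex of a parabola through three samples."""
    denom = left - 2.0 * center + right
    if denom >= 0:  # not a maximum; keep the integer peak
        return 0.0
    offset = 0.5 * (left - right) / denom
    return float(np.clip(offset, -0.5, 0.5))


def estimate_plane_shift(
    ref: ImagePlane | np.ndarray,
    mov: ImagePlane | np.ndarray,
    max_shift_px: int = DEFAULT_MAX_SHIFT_PX,
) -> PlaneShift:
    """Estimate the (dy, dx) translation of ``mov`` relative to ``ref``.

    Exhaustive ZNCC over integer shifts in ``[-max_shift, max_shift]^2``
    evaluated on the overlapping region, then 1D parabolic refinement around
    the peak in each axis.  Ties are broken toward the smallest shift
    magnitude, then smallest dy, then smallest dx.  A positive (dy, dx)
    means the moving plane's content sits at +dy/+dx relative to the
    reference.
    """
    a = (ref.pixels if isinstance(ref, ImagePlane) else np.asarray(ref)).astype(np.float64)
    b = (mov.pixels if isinstance(mov, ImagePlane) else np.asarray(mov)).astype(np.float64)
    if a.shape != b.shape:
        raise ValueError(f"plane shapes differ: {a.shape} vs {b.shape}")
    if max_shift_px < 0:
        raise ValueError("max_shift_px must be >= 0")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance plane: normalized cross-correlation is undefined")
    ny, nx = a.shape
    m = int(min(max_shift_px, ny - 1, nx - 1))

    size = 2 * m + 1
    ncc = np.full((size, size), -np.inf)
    for iy, dy in enumerate(range(-m, m + 1)):
        # mov content sits at +dy relative to ref: compare ref[y] vs mov[y + dy]
        ya0, ya1 = max(0, -dy), min(ny, ny - dy)
        yb0, yb1 = max(0, dy), min(ny, ny + dy)
        for ix, dx in enumerate(range(-m, m + 1)):
            xa0, xa1 = max(0, -dx), min(nx, nx - dx)
            xb0, xb1 = max(0, dx), min(nx, nx + dx)
            sub_a = a[ya0:ya1, xa0:xa1]
            sub_b = b[yb0:yb1, xb0:xb1]
            if sub_a.size == 0:
                continue
            ncc[iy, ix] = _zncc(sub_a, sub_b)

    best = np.max(ncc)
    candidates = np.argwhere(ncc >= best - 1e-12)
    shifts = candidates - m
    order = np.lexsort((shifts[:, 1], shifts[:, 0], np.abs(shifts).sum(axis=1)))
    iy, ix = candidates[order[0]]
    dy, dx = int(iy) - m, int(ix) - m

    sub_dy = sub_dx = 0.0
    if 0 < iy < size - 1 and np.isfinite(ncc[iy - 1, ix]) and np.isfinite(ncc[iy + 1, ix]):
        sub_dy = _parabolic_offset(ncc[iy - 1, ix], ncc[iy, ix], ncc[iy + 1, ix])
    if 0 < ix < size - 1 and np.isfinite(ncc[iy, ix - 1]) and np.isfinite(ncc[iy, ix + 1]):
        sub_dx = _parabolic_offset(ncc[iy, ix - 1], ncc[iy, ix], ncc[iy, ix + 1])

    return PlaneShift(dy_px=dy + sub_dy, dx_px=dx + sub_dx, peak_ncc=float(ncc[iy, ix]))


def estimate_stack_shifts(stack: ChannelStack, max_shift_px: int = DEFAULT_MAX_SHIFT_PX) -> list[PlaneShift]:
    """Successive-plane shifts for a whole stack (length = planes - 1)."""
    arr = stack.to_array()
    return [estimate_plane_shift(arr[k], arr[k + 1], max_shift_px) for k in range(len(arr) - 1)]


def correct_stack_drift(
    stack: ChannelStack,
    shifts: Sequence[PlaneShift] | str = "estimate",
    max_shift_px: int = DEFAULT_MAX_SHIFT_PX,
) -> ChannelStack:
    """Undo per-plane drift by resampling every plane onto plane 0's grid.

    Successive-plane shifts are composed cumulatively relative to plane 0
    and each plane is bilinearly resampled; pixels exposed at the border are
    filled with the plane's background median (avoiding spurious
    high-frequency edges that would fool the tissue detector).  All-integer
    shifts reduce to exact index shifts.
    """
    arr = stack.to_array().astype(np.float64)
    if isinstance(shifts, str):
        if shifts != "estimate":
            raise ValueError("shifts must be a sequence or the string 'estimate'")
        shifts = estimate_stack_shifts(stack, max_shift_px)
    if len(shifts) != len(arr) - 1:
        raise ValueError(f"need {len(arr) - 1} successive shifts, got {len(shifts)}")

    out = np.empty_like(arr)
    out[0] = arr[0]
    cum_dy = cum_dx = 0.0
    for k, s in enumerate(shifts, start=1):
        cum_dy += s.dy_px
        cum_dx += s.dx_px
        fill = float(np.median(arr[k]))
        out[k] = ndimage.shift(
            arr[k], shift=(-cum_dy, -cum_dx), order=1, mode="constant", cval=fill, prefilter=False
        )
    return ChannelStack.from_array(out, channel=stack.channel, spacing_um=stack.spacing_um)


def write_shift_table(shifts: Sequence[PlaneShift], path: str | Path) -> Path:
    """Export successive-plane shifts as a tab-separated QC table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["z\tdy_px\tdx_px\tpeak_ncc"]
    for k, s in enumerate(shifts, start=1):
        lines.append(f"{k}\t{s.dy_px:.4f}\t{s.dx_px:.4f}\t{s.peak_ncc:.6f}")
    path.write_text("\n".join(lines) + "\n")
    return path
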