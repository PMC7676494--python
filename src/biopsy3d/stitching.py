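"""Two-tile volume stitching via 3D scale-invariant landmarks and affine fusion.

A biopsy longer than one field of view is scanned as overlapping z-stack
tiles.  Tiles are merged by (1) detecting scale-space blob landmarks in both
bright-field volumes — difference-of-Gaussians extrema with edge-response
suppression and gradient-orientation-histogram descriptors, the volumetric
analogue of SIFT; (2) matching descriptors with a Lowe ratio test and
mutual-best filtering; (3) robustly estimating the 12-parameter 3D affine
transform from the correspondences (consensus over minimal 4-point samples,
then a least-squares refit on the inliers); and (4) resampling the moving
tile into the reference frame by tri-linear interpolation, keeping the
reference tile's voxels wherever both tiles cover a voxel.

Anisotropic voxels are handled by expressing detection scales in physical
micrometres (per-axis Gaussian sigmas in voxels are scale/spacing), while
positions and transforms stay in voxel coordinates of the reference tile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import ChannelStack

DEFAULT_CONTRAST_THRESHOLD = 0.01
DEFAULT_EDGE_RATIO = 10.0
DEFAULT_RATIO_THRESHOLD = 0.8


@dataclass
class Keypoint3D:
    """A scale-space landmark with a unit-norm orientation-histogram descriptor."""

    position: np.ndarray  # (z, y, x) in voxels, float
    scale: float          # detection scale in micrometres
    descriptor: np.ndarray


@dataclass
class Correspondence:
    a: Keypoint3D
    b: Keypoint3D
    distance: float


@dataclass
class AffineTransform3D:
    """Voxel-coordinate mapping ``x_ref = matrix @ x_mov + translation``."""

    matrix: np.ndarray      # 3x3 linear part
    translation: np.ndarray  # 3-vector

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform3D":
        return cls(matrix=np.eye(3), translation=np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform3D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform3D(matrix=inv, translation=-inv @ self.translation)

    def save(self, path: str | Path) -> Path:
        """Serialize as 12 numbers, row-major 3x4 (linear part | translation)."""
        path = Path(path)
        mat34 = np.hstack([self.matrix, self.translation[:, None]])
        path.write_text(" ".join(repr(float(v)) for v in mat34.ravel()) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "AffineTransform3D":
        values = np.array([float(v) for v in Path(path).read_text().split()])
        if values.size != 12:
            raise ValueError("expected 12 numbers (row-major 3x4)")
        mat34 = values.reshape(3, 4)
        return cls(matrix=mat34[:, :3], translation=mat34[:, 3])


def _scale_space_dogs(
    volume: np.ndarray,
    spacing: np.ndarray,
    n_octaves: int,
    base_sigma_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Difference-of-Gaussians stack over a geometric scale ladder.

    Scales are defined in micrometres and converted to per-axis voxel sigmas,
    so blobs are detected isotropically in physical space even on
    anisotropic grids.  Returns (dogs, sigmas_um) with dogs shaped
    (n_scales-1, nz, ny, nx).
    """
    steps_per_octave = 3
    n_scales = steps_per_octave * n_octaves + 2
    sigmas = base_sigma_um * 2.0 ** (np.arange(n_scales) / steps_per_octave)
    smoothed = np.stack(
        [ndimage.gaussian_filter(volume, sigma=tuple(s / spacing), mode="reflect") for s in sigmas]
    )
    dogs = smoothed[1:] - smoothed[:-1]
    return dogs, sigmas


def _passes_edge_test(dog_scale: np.ndarray, z: int, y: int, x: int, edge_ratio: float) -> bool:
    """Reject ridge/edge responses via the spatial Hessian's eigenvalue spread."""
    h = np.empty((3, 3))
    v = dog_scale
    h[0, 0] = v[z + 1, y, x] - 2 * v[z, y, x] + v[z - 1, y, x]
    h[1, 1] = v[z, y + 1, x] - 2 * v[z, y, x] + v[z, y - 1, x]
    h[2, 2] = v[z, y, x + 1] - 2 * v[z, y, x] + v[z, y, x - 1]
    h[0, 1] = h[1, 0] = 0.25 * (v[z + 1, y + 1, x] - v[z + 1, y - 1, x] - v[z - 1, y + 1, x] + v[z - 1, y - 1, x])
    h[0, 2] = h[2, 0] = 0.25 * (v[z + 1, y, x + 1] - v[z + 1, y, x - 1] - v[z - 1, y, x + 1] + v[z - 1, y, x - 1])
    h[1, 2] = h[2, 1] = 0.25 * (v[z, y + 1, x + 1] - v[z, y + 1, x - 1] - v[z, y - 1, x + 1] + v[z, y - 1, x - 1])
    eig = np.linalg.eigvalsh(h)
    mags = np.abs(eig)
    if mags.min() <= 1e-12:
        return False
    return bool(mags.max() / mags.min() <= edge_ratio)


def _descriptor(
    gradients: tuple[np.ndarray, np.ndarray, np.ndarray],
    center: tuple[int, int, int],
    radius_vox: tuple[int, int, int],
    n_azimuth: int = 8,
    n_elevation: int = 4,
) -> np.ndarray:
    """Gaussian-weighted 3D gradient-orientation histogram, unit-normalized."""
    gz, gy, gx = gradients
    shape = gz.shape
    sl = tuple(
        slice(max(0, c - r), min(n, c + r + 1)) for c, r, n in zip(center, radius_vox, shape)
    )
    pz, py, px = (g[sl].ravel() for g in (gz, gy, gx))
    mag = np.sqrt(pz**2 + py**2 + px**2)

    grids = np.meshgrid(
        *[np.arange(s.start, s.stop) - c for s, c in zip(sl, center)], indexing="ij"
    )
    dist_sq = sum((g / max(r, 1)) ** 2 for g, r in zip(grids, radius_vox))
    weight = np.exp(-0.5 * dist_sq.ravel() * 4.0)

    azimuth = np.arctan2(py, px)  # [-pi, pi]
    with np.errstate(invalid="ignore", divide="ignore"):
        elevation = np.where(mag > 0, np.arcsin(np.clip(pz / np.maximum(mag, 1e-30), -1, 1)), 0.0)
    az_bin = np.clip(((azimuth + np.pi) / (2 * np.pi) * n_azimuth).astype(int), 0, n_azimuth - 1)
    el_bin = np.clip(((elevation + np.pi / 2) / np.pi * n_elevation).astype(int), 0, n_elevation - 1)

    hist = np.zeros(n_azimuth * n_elevation)
    np.add.at(hist, el_bin * n_azimuth + az_bin, mag * weight)
    norm = np.linalg.norm(hist)
    if norm > 0:
        hist /= norm
        np.clip(hist, 0, 0.2, out=hist)  # SIFT-style illumination robustness
        norm = np.linalg.norm(hist)
        if norm > 0:
            hist /= norm
    return hist


def detect_keypoints(
    volume: ChannelStack | np.ndarray,
    n_octaves: int = 2,
    contrast_threshold: float = DEFAULT_CONTRAST_THRESHOLD,
    base_sigma_um: float = 1.2,
    edge_ratio: float = DEFAULT_EDGE_RATIO,
    spacing_um: tuple[float, float, float] | None = None,
    max_keypoints: int = 2000,
) -> list[Keypoint3D]:
    """Detect 3D scale-space blob landmarks with descriptors.

    Extrema of the difference-of-Gaussians stack over space and scale,
    thresholded on contrast and filtered for edge-like responses through the
    spatial Hessian eigenvalue ratio.  A constant volume yields no
    keypoints.
    """
    if isinstance(volume, ChannelStack):
        spacing = np.asarray(volume.spacing_um)
        arr = volume.to_array().astype(np.float64)
    else:
        arr = np.asarray(volume, dtype=np.float64)
        spacing = np.asarray(spacing_um if spacing_um is not None else (1.0, 1.0, 1.0))
    if arr.ndim != 3:
        raise ValueError("volume must be 3D")
    if min(arr.shape) < 16:
        raise ValueError("volume must be at least 16 voxels per axis")

    ptp = np.ptp(arr)
    if ptp == 0:
        return []
    arr = (arr - arr.min()) / ptp

    dogs, sigmas = _scale_space_dogs(arr, spacing, n_octaves, base_sigma_um)
    n_dog = dogs.shape[0]

    footprint = np.ones((3, 3, 3, 3), dtype=bool)
    maxima = (dogs == ndimage.maximum_filter(dogs, footprint=footprint, mode="nearest"))
    minima = (dogs == ndimage.minimum_filter(dogs, footprint=footprint, mode="nearest"))
    extrema = (maxima | minima) & (np.abs(dogs) > contrast_threshold)
    extrema[0] = extrema[-1] = False
    for axis in range(1, 4):
        extrema[(slice(None),) * axis + (0,)] = False
        extrema[(slice(None),) * axis + (-1,)] = False

    candidates = np.argwhere(extrema)
    if len(candidates) > max_keypoints:
        order = np.argsort(np.abs(dogs[tuple(candidates.T)]))[::-1]
        candidates = candidates[order[:max_keypoints]]

    gradients = np.gradient(arr, *spacing)
    keypoints: list[Keypoint3D] = []
    for s, z, y, x in candidates:
        if not _passes_edge_test(dogs[s], z, y, x, edge_ratio):
            continue
        sigma_um = float(np.sqrt(sigmas[s] * sigmas[s + 1]))
        radius_vox = tuple(max(2, int(round(3.0 * sigma_um / d))) for d in spacing)
        desc = _descriptor(tuple(gradients), (z, y, x), radius_vox)
        if not np.any(desc):
            continue
        keypoints.append(
            Keypoint3D(position=np.array([z, y, x], dtype=np.float64), scale=sigma_um, descriptor=desc)
        )
    return keypoints


def match_landmarks(
    kp_a: list[Keypoint3D],
    kp_b: list[Keypoint3D],
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
) -> list[Correspondence]:
    """Nearest-neighbour descriptor matching with Lowe ratio and mutual-best tests."""
    from scipy.spatial import cKDTree

    if not kp_a or not kp_b:
        raise ValueError("both keypoint lists must be non-empty")
    desc_a = np.stack([k.descriptor for k in kp_a])
    desc_b = np.stack([k.descriptor for k in kp_b])

    tree_b = cKDTree(desc_b)
    k_query = min(2, len(kp_b))
    dist_ab, idx_ab = tree_b.query(desc_a, k=k_query)
    dist_ab = np.atleast_2d(dist_ab.T).T
    idx_ab = np.atleast_2d(idx_ab.T).T

    tree_a = cKDTree(desc_a)
    _, best_for_b = tree_a.query(desc_b, k=1)

    matches: list[Correspondence] = []
    for i in range(len(kp_a)):
        j = int(idx_ab[i, 0])
        d1 = float(dist_ab[i, 0])
        if k_query == 2:
            d2 = float(dist_ab[i, 1])
            if d2 > 0 and d1 >= ratio_threshold * d2:
                continue
        if int(best_for_b[j]) != i:  # mutual best
            continue
        matches.append(Correspondence(a=kp_a[i], b=kp_b[j], distance=d1))
    return matches


def _solve_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform3D:
    """Least-squares affine mapping src -> dst (closed form)."""
    n = len(src)
    design = np.hstack([src, np.ones((n, 1))])
    params, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return AffineTransform3D(matrix=params[:3].T, translation=params[3])


def estimate_affine(
    correspondences: list[Correspondence] | tuple[np.ndarray, np.ndarray],
    inlier_tol_voxels: float = 1.0,
    seed: int = 0,
    n_iterations: int = 500,
) -> AffineTransform3D:
    """Robustly estimate the affine transform mapping B positions into A's frame.

    Repeated minimal samples of 4 correspondences, closed-form solve,
    consensus counting at ``inlier_tol_voxels``, and a final least-squares
    refit on the largest consensus set.  Deterministic given ``seed``.
    """
    if isinstance(correspondences, tuple):
        dst, src = (np.asarray(c, dtype=np.float64) for c in correspondences)
    else:
        dst = np.stack([c.a.position for c in correspondences])
        src = np.stack([c.b.position for c in correspondences])
    n = len(src)
    if n < 4:
        raise ValueError(f"need at least 4 correspondences, got {n}")

    def residuals(t: AffineTransform3D) -> np.ndarray:
        return np.linalg.norm(t.apply(src) - dst, axis=1)

    rng = np.random.default_rng(seed)
    best_inliers: np.ndarray | None = None
    for _ in range(n_iterations):
        sample = rng.choice(n, size=4, replace=False)
        pts = src[sample]
        # non-coplanar check: volume spanned by the 4 points
        vol = abs(np.linalg.det(pts[1:] - pts[0]))
        if vol < 1e-9:
            continue
        try:
            t = _solve_affine(pts, dst[sample])
        except (np.linalg.LinAlgError, ValueError):
            continue
        inliers = residuals(t) <= inlier_tol_voxels
        if best_inliers is None or inliers.sum() > best_inliers.sum():
            best_inliers = inliers
    if best_inliers is None or best_inliers.sum() < 4:
        raise ValueError("no consistent affine found (degenerate or insufficient correspondences)")

    # final refit, iterated once so borderline inliers settle
    for _ in range(2):
        t = _solve_affine(src[best_inliers], dst[best_inliers])
        best_inliers = residuals(t) <= inlier_tol_voxels
        if best_inliers.sum() < 4:
            break
    return t


def stitch_volumes(
    ref: ChannelStack | np.ndarray,
    mov: ChannelStack | np.ndarray,
    t: AffineTransform3D,
    fill_value: float = 0.0,
    blend: bool = False,
) -> tuple[ChannelStack | np.ndarray, np.ndarray]:
    """Fuse a moving tile into the reference frame under a known affine.

    The output grid is the union bounding box of both tiles in the reference
    frame.  Reference voxels are copied verbatim; the moving tile is
    resampled by tri-linear interpolation.  Where both tiles are defined the
    reference voxel wins (the moving contribution is removed), unless
    ``blend`` averages the two.  Returns the fused volume and a provenance
    mask (0 = empty, 1 = reference, 2 = moving).
    """
    is_stack = isinstance(ref, ChannelStack)
    ref_arr = ref.to_array().astype(np.float64) if is_stack else np.asarray(ref, dtype=np.float64)
    mov_arr = mov.to_array().astype(np.float64) if isinstance(mov, ChannelStack) else np.asarray(mov, dtype=np.float64)

    corners = np.array([[z, y, x] for z in (0, mov_arr.shape[0] - 1)
                        for y in (0, mov_arr.shape[1] - 1)
                        for x in (0, mov_arr.shape[2] - 1)], dtype=np.float64)
    mapped = t.apply(corners)
    # expand the union grid only where the moving tile extends at least half
    # a voxel beyond it; sub-half-voxel overhangs carry no resolvable content
    lo = np.floor(np.minimum(mapped.min(axis=0) + 0.5, 0)).astype(int)
    hi = np.ceil(np.maximum(mapped.max(axis=0) - 0.5, np.asarray(ref_arr.shape) - 1)).astype(int)
    out_shape = tuple(hi - lo + 1)

    out = np.full(out_shape, fill_value, dtype=np.float64)
    provenance = np.zeros(out_shape, dtype=np.uint8)

    # resample the moving tile: pull coordinates through the inverse map
    t_inv = t.inverse()
    grids = np.meshgrid(*[np.arange(l, h + 1, dtype=np.float64) for l, h in zip(lo, hi)], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    mov_coords = t_inv.apply(pts).T.reshape(3, *out_shape)
    inside = np.ones(out_shape, dtype=bool)
    for axis in range(3):
        inside &= (mov_coords[axis] >= 0) & (mov_coords[axis] <= mov_arr.shape[axis] - 1)
    resampled = ndimage.map_coordinates(mov_arr, mov_coords, order=1, mode="constant", cval=fill_value)
    out[inside] = resampled[inside]
    provenance[inside] = 2

    ref_sl = tuple(slice(-l, -l + n) for l, n in zip(lo, ref_arr.shape))
    if blend:
        both = inside[ref_sl]
        region = out[ref_sl]
        region[both] = 0.5 * (region[both] + ref_arr[both])
        region[~both] = ref_arr[~both]
    else:
        out[ref_sl] = ref_arr  # reference wins in the overlap
    provenance[ref_sl] = 1

    if is_stack:
        return ChannelStack.from_array(out, channel=ref.channel, spacing_um=ref.spacing_um), provenance
    return out, provenance


def stitch_pair(
    ref: ChannelStack,
    mov: ChannelStack,
    n_octaves: int = 2,
    contrast_threshold: float = DEFAULT_CONTRAST_THRESHOLD,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    inlier_tol_voxels: float = 1.0,
    seed: int = 0,
) -> tuple[ChannelStack, np.ndarray, AffineTransform3D]:
    """Full two-tile chain: detect -> match -> estimate -> stitch (on BF data)."""
    kp_ref = detect_keypoints(ref, n_octaves=n_octaves, contrast_threshold=contrast_threshold)
    kp_mov = detect_keypoints(mov, n_octaves=n_octaves, contrast_threshold=contrast_threshold)
    matches = match_landmarks(kp_ref, kp_mov, ratio_threshold=ratio_threshold)
    t = estimate_affine(matches, inlier_tol_voxels=inlier_tol_voxels, seed=seed)
    fused, provenance = stitch_volumes(ref, mov, t)
    return fused, provenance, t
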