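import numpy as np
import pytest

from biopsy3d import segmentation
from biopsy3d.segmentation import (
    equivalent_diameter_um,
    extract_cavities,
    local_highfreq_energy,
    segment_tissue,
    TissueSegmentation,
)
from biopsy3d.volume_io import ChannelStack


def naive_energy(pixels, r):
    """Independent per-pixel oracle: reflect-pad, scalar Laplacian, scalar window sums."""
    pixels = np.asarray(pixels, dtype=np.float64)
    ny, nx = pixels.shape
    p = np.pad(pixels, 1, mode="symmetric")
    lap = np.empty((ny, nx))
    for y in range(ny):
        for x in range(nx):
            c = p[y + 1, x + 1]
            lap[y, x] = (p[y, x + 1] + p[y + 2, x + 1]) + (p[y + 1, x] + p[y + 1, x + 2]) - 4.0 * c
    sq = lap * lap
    sp = np.pad(sq, r, mode="symmetric")
    energy = np.empty((ny, nx))
    for y in range(ny):
        for x in range(nx):
            acc = 0.0
            for dy in range(2 * r + 1):
                for dx in range(2 * r + 1):
                    acc += sp[y + dy, x + dx]
            energy[y, x] = acc
    return energy


class TestEnergyMap:
    def test_constant_plane_has_zero_energy(self):
        em = local_highfreq_energy(np.full((20, 20), 37.0), window_radius_px=3)
        assert np.all(em.energy == 0)

    def test_impulse_energy_equals_squared_coefficient_sum(self):
        """Laplacian of a unit impulse has coefficients (-4, 1, 1, 1, 1): sum of squares 20."""
        plane = np.zeros((21, 21))
        plane[10, 10] = 1.0
        em = local_highfreq_energy(plane, window_radius_px=3)
        assert em.energy[10, 10] == pytest.approx(20.0)
        amp = 2.5
        em2 = local_highfreq_energy(plane * amp, window_radius_px=3)
        assert em2.energy[10, 10] == pytest.approx(20.0 * amp**2)

    def test_checkerboard_beats_low_frequency_sinusoid(self):
        y, x = np.mgrid[:64, :64]
        checker = 50.0 + 10.0 * ((-1.0) ** (y + x))
        sine = 50.0 + 10.0 * np.sin(2 * np.pi * x / 32.0)
        e_checker = local_highfreq_energy(checker, 7).energy.mean()
        e_sine = local_highfreq_energy(sine, 7).energy.mean()
        assert e_checker > e_sine

    def test_offset_invariance_and_quadratic_gain_scaling(self, rng):
        plane = rng.random((32, 32)) * 40
        e0 = local_highfreq_energy(plane, 5).energy
        e_shifted = local_highfreq_energy(plane + 123.0, 5).energy
        e_scaled = local_highfreq_energy(plane * 3.0, 5).energy
        np.testing.assert_allclose(e_shifted, e0, atol=1e-6)
        np.testing.assert_allclose(e_scaled, 9.0 * e0, rtol=1e-9)

    @pytest.mark.parametrize("r", [1, 2, 3])
    def test_matches_naive_per_pixel_oracle_bit_exactly(self, rng, r):
        plane = rng.random((12, 14)) * 100
        em = local_highfreq_energy(plane, window_radius_px=r)
        np.testing.assert_array_equal(em.energy, naive_energy(plane, r))

    def test_window_larger_than_plane_rejected(self):
        with pytest.raises(ValueError, match="window"):
            local_highfreq_energy(np.zeros((8, 8)), window_radius_px=5)


def naive_segment(volume, r, threshold):
    """Brute-force reimplementation: naive energy, threshold, speckle fill, window erosion."""
    nz, ny, nx = volume.shape
    mask = np.zeros((nz, ny, nx), dtype=bool)
    for z in range(nz):
        mask[z] = naive_energy(volume[z], r) > threshold
    # fill 26-connected non-tissue components smaller than one window (BFS)
    seen = np.zeros_like(mask)
    for z0 in range(nz):
        for y0 in range(ny):
            for x0 in range(nx):
                if mask[z0, y0, x0] or seen[z0, y0, x0]:
                    continue
                comp, queue = [], [(z0, y0, x0)]
                seen[z0, y0, x0] = True
                while queue:
                    z, y, x = queue.pop()
                    comp.append((z, y, x))
                    for dz in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                zz, yy, xx = z + dz, y + dy, x + dx
                                if (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx
                                        and not mask[zz, yy, xx] and not seen[zz, yy, xx]):
                                    seen[zz, yy, xx] = True
                                    queue.append((zz, yy, xx))
                if len(comp) < (2 * r + 1) ** 2:
                    for z, y, x in comp:
                        mask[z, y, x] = True
    out = np.zeros_like(mask)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                keep = True
                for dy in range(-r, r + 1):
                    for dx in range(-r, r + 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < ny and 0 <= xx < nx and not mask[z, yy, xx]:
                            keep = False
                            break
                    if not keep:
                        break
                out[z, y, x] = keep
    return out


class TestSegmentTissue:
    def test_matches_brute_force_oracle_bit_exactly(self, rng):
        volume = rng.random((8, 16, 16)) * 50
        stack = ChannelStack.from_array(volume, spacing_um=(3, 1, 1))
        thr = 400.0
        seg = segment_tissue(stack, window_radius_px=2, threshold=thr)
        np.testing.assert_array_equal(seg.mask, naive_segment(volume, 2, thr))

    def test_raising_threshold_never_adds_tissue(self, rng):
        volume = rng.random((6, 20, 20)) * 50
        stack = ChannelStack.from_array(volume, spacing_um=(3, 1, 1))
        masks = [segment_tissue(stack, 3, threshold=t).mask for t in (100.0, 400.0, 1600.0)]
        for lo, hi in zip(masks[:-1], masks[1:]):
            assert not np.any(hi & ~lo)

    def test_pure_noise_below_threshold_gives_empty_mask(self, rng):
        volume = 100.0 + rng.standard_normal((6, 24, 24))
        stack = ChannelStack.from_array(np.clip(volume, 0, None), spacing_um=(3, 1, 1))
        seg = segment_tissue(stack, 3, threshold=1e9)
        assert not seg.mask.any()

    def test_constant_stack_cannot_auto_threshold(self):
        stack = ChannelStack.from_array(np.full((4, 24, 24), 5.0), spacing_um=(3, 1, 1))
        with pytest.raises(ValueError, match="threshold"):
            segment_tissue(stack, 3, threshold="auto")

    def test_phantom_cavity_recovered_with_good_dice(self, small_phantom, small_bf):
        """End-to-end: a textured slab with 50/60 um cavities segments cleanly."""
        from biopsy3d.evaluation import dice_coefficient, match_cavities

        seg = segment_tissue(small_bf)
        assert dice_coefficient(seg.mask, small_phantom.tissue_mask) > 0.95
        report = extract_cavities(seg)
        matches = match_cavities(small_phantom, report)
        assert all(m is not None for m in matches.values())
        assert not np.any((report.labels > 0) & seg.mask)


class TestExtractCavities:
    def _seg(self, mask, spacing=(1.0, 1.0, 1.0)):
        return TissueSegmentation(mask=mask, threshold=0.0, spacing_um=spacing)

    def test_all_tissue_gives_empty_report(self):
        report = extract_cavities(self._seg(np.ones((6, 6, 6), dtype=bool)))
        assert report.cavities == []

    def test_single_voxel_equivalent_diameter_closed_form(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = False
        report = extract_cavities(self._seg(mask), min_diameter_um=0.0)
        assert len(report.cavities) == 1
        assert report.cavities[0].equivalent_diameter_um == pytest.approx((6 / np.pi) ** (1 / 3), abs=1e-6)
        assert report.cavities[0].enclosed

    def test_diameter_formula(self):
        assert equivalent_diameter_um(1, (1, 1, 1)) == pytest.approx(1.2407, abs=1e-4)
        # a voxel count whose equivalent sphere is exactly 50 um at (3,1,1) um spacing
        n = int(round(np.pi / 6 * 50**3 / 3))
        assert equivalent_diameter_um(n, (3, 1, 1)) == pytest.approx(50.0, abs=0.01)

    def test_size_filter_keeps_only_large_enclosed_cavity(self):
        """60 um and 30 um spherical holes, 50 um filter: exactly one survives."""
        shape = (96, 96, 96)
        z, y, x = np.ogrid[:96, :96, :96]
        mask = np.ones(shape, dtype=bool)
        mask[(z - 35) ** 2 + (y - 35) ** 2 + (x - 35) ** 2 <= 30**2] = False
        mask[(z - 75) ** 2 + (y - 75) ** 2 + (x - 75) ** 2 <= 15**2] = False
        report = extract_cavities(self._seg(mask), min_diameter_um=50.0)
        enclosed = report.enclosed()
        assert len(enclosed) == 1
        assert enclosed[0].equivalent_diameter_um == pytest.approx(60.0, rel=0.03)

    def test_boundary_touching_component_not_enclosed(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        mask[0, :4, :4] = False  # open to the volume face
        report = extract_cavities(self._seg(mask), min_diameter_um=0.0)
        assert len(report.cavities) == 1
        assert not report.cavities[0].enclosed

    def test_labels_only_on_non_tissue(self, rng):
        mask = rng.random((8, 12, 12)) > 0.3
        report = extract_cavities(self._seg(mask), min_diameter_um=0.0)
        assert not np.any((report.labels > 0) & mask)

    def test_report_table_round_trip(self, tmp_path):
        mask = np.ones((6, 8, 8), dtype=bool)
        mask[3, 4, 4] = False
        report = extract_cavities(self._seg(mask), min_diameter_um=0.0)
        path = report.write_table(tmp_path / "cav.tsv")
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("label\t")
        assert len(lines) == 2
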