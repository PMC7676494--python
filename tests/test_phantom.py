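import numpy as np
import pytest

from biopsy3d import phantom
from biopsy3d.deconvolution import gaussian_psf
from biopsy3d.phantom import CavitySpec, DefocusModel, PhantomSpec
from biopsy3d.segmentation import _energy_nd

SMALL_SHAPE = (24, 64, 64)
SPACING = (3.0, 1.0, 1.0)


def slab_spec(seed=0, cavities=(), **kw):
    return PhantomSpec(volume_shape=SMALL_SHAPE, spacing_um=SPACING, cavities=list(cavities), seed=seed, **kw)


class TestGeneratePhantom:
    def test_no_cavities_means_tissue_fills_extent(self):
        truth = phantom.generate_phantom(slab_spec())
        assert truth.cavity_labels.max() == 0
        (z0, z1), (y0, y1), (x0, x1) = phantom.PhantomSpec.model_validate(slab_spec()).tissue_extent
        expected = np.zeros(SMALL_SHAPE, dtype=bool)
        expected[z0:z1, y0:y1, x0:x1] = True
        np.testing.assert_array_equal(truth.tissue_mask, expected)

    def test_same_seed_is_bit_identical(self):
        cav = CavitySpec(center_um=(36.0, 32.0, 32.0), diameter_um=40.0)
        a = phantom.generate_phantom(slab_spec(seed=5, cavities=[cav]))
        b = phantom.generate_phantom(slab_spec(seed=5, cavities=[cav]))
        for attr in ("tissue_mask", "cavity_labels", "fl1_truth", "fl2_truth", "texture"):
            np.testing.assert_array_equal(getattr(a, attr), getattr(b, attr))

    def test_sphere_voxel_count_matches_analytic_volume(self):
        spec = phantom.graded_cavity_spec(seed=0, diameters_um=(80.0,))
        truth = phantom.generate_phantom(spec)
        count = int((truth.cavity_labels == 1).sum())
        analytic = (np.pi / 6.0) * 80.0**3 / np.prod(spec.spacing_um)
        assert abs(count - analytic) / analytic < 0.10

    def test_cavity_voxels_are_never_tissue(self):
        cav = CavitySpec(center_um=(36.0, 32.0, 32.0), diameter_um=40.0)
        truth = phantom.generate_phantom(slab_spec(cavities=[cav]))
        assert not np.any(truth.tissue_mask & (truth.cavity_labels > 0))

    def test_fl_truth_zero_outside_tissue(self):
        cav = CavitySpec(center_um=(36.0, 32.0, 32.0), diameter_um=40.0)
        truth = phantom.generate_phantom(slab_spec(cavities=[cav]))
        outside = ~truth.tissue_mask
        assert truth.fl1_truth[outside].sum() == 0
        assert truth.fl2_truth[outside].sum() == 0
        assert truth.fl1_truth.sum() > 0 and truth.fl2_truth.sum() > 0

    def test_cavity_outside_extent_rejected(self):
        cav = CavitySpec(center_um=(3.0, 32.0, 32.0), diameter_um=40.0)
        with pytest.raises(ValueError, match="outside"):
            slab_spec(cavities=[cav])


class TestBrightFieldSimulation:
    def test_empty_truth_gives_constant_planes_plus_noise(self):
        spec = slab_spec()
        truth = phantom.generate_phantom(spec)
        truth.tissue_mask[:] = False
        bf = phantom.simulate_bf_stack(truth, noise_sd=0.0, seed=0)
        arr = bf.to_array()
        assert np.ptp(arr) < 1e-9

    def test_zero_blur_growth_makes_planes_identical(self):
        truth = phantom.generate_phantom(slab_spec())
        defocus = DefocusModel(blur_sigma_at_focus_um=0.5, blur_growth_per_um=0.0)
        bf = phantom.simulate_bf_stack(truth, defocus, noise_sd=0.0, seed=0)
        arr = bf.to_array()
        np.testing.assert_allclose(arr, np.broadcast_to(arr[0], arr.shape), rtol=1e-10)

    def test_same_seed_is_bit_identical(self):
        truth = phantom.generate_phantom(slab_spec())
        a = phantom.simulate_bf_stack(truth, seed=3).to_array()
        b = phantom.simulate_bf_stack(truth, seed=3).to_array()
        np.testing.assert_array_equal(a, b)

    def test_in_focus_energy_exceeds_defocused_energy(self):
        """The defining defocus property: high-frequency energy peaks in focus."""
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            spec = slab_spec(seed=seed)
            truth = phantom.generate_phantom(spec)
            bf = phantom.simulate_bf_stack(truth, seed=seed + 1000)
            arr = bf.to_array()
            mid = arr.shape[0] // 2
            interior = (slice(16, -16), slice(16, -16))
            e_focus = _energy_nd(arr[mid], 7, "laplacian")[interior].mean()
            e_far = _energy_nd(arr[1], 7, "laplacian")[interior].mean()
            if e_focus > e_far:
                wins += 1
        assert wins >= int(0.95 * n_rep)

    def test_noiseless_energy_monotone_in_defocus(self):
        """Mean energy of the slab texture never increases with defocus distance."""
        spec = slab_spec(seed=2)
        truth = phantom.generate_phantom(spec)
        # slab restricted to a single textured source plane for a clean probe
        truth.tissue_mask[:] = False
        truth.tissue_mask[12] = True
        bf = phantom.simulate_bf_stack(truth, noise_sd=0.0, seed=0)
        arr = bf.to_array()
        interior = (slice(16, -16), slice(16, -16))
        energies = [_energy_nd(arr[z], 7, "laplacian")[interior].mean() for z in range(12, 24)]
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-9)


class TestDarkFieldSimulation:
    def test_untextured_tissue_signal_concentrates_at_borders(self):
        """With zero texture the scattering source is the tissue border only."""
        spec = PhantomSpec(
            volume_shape=SMALL_SHAPE,
            spacing_um=SPACING,
            tissue_extent=((2, 22), (16, 48), (16, 48)),
            seed=0,
        )
        truth = phantom.generate_phantom(spec)
        truth.texture[:] = 0.0
        df = phantom.simulate_df_stack(truth, noise_sd=0.0, seed=0)
        arr = df.to_array()
        mid = arr.shape[0] // 2
        border_ring = arr[mid, 14:18, 16:48].mean()  # in-focus lateral tissue edge
        deep_interior = arr[mid, 28:36, 28:36].mean()
        # the deep interior still receives defocused light from the slab's
        # z-border sheets, so the edge stands out by a factor, not to zero
        assert border_ring > 2 * max(deep_interior, 1e-12)

    def test_deterministic(self):
        truth = phantom.generate_phantom(slab_spec())
        a = phantom.simulate_df_stack(truth, seed=9).to_array()
        b = phantom.simulate_df_stack(truth, seed=9).to_array()
        np.testing.assert_array_equal(a, b)


class TestFluorescenceSimulation:
    def test_zero_truth_gives_pure_noise(self):
        truth = phantom.generate_phantom(slab_spec())
        truth.fl1_truth[:] = 0.0
        truth.fl2_truth[:] = 0.0
        psf = gaussian_psf(shape=(7, 9, 9), spacing_um=SPACING)
        fl1, fl2 = phantom.simulate_fl_stacks(truth, psf, noise_sd=1.0, seed=0)
        assert fl1.to_array().std() < 1.5
        assert fl2.to_array().std() < 1.5

    def test_linearity_in_label_density(self):
        cav = CavitySpec(center_um=(36.0, 32.0, 32.0), diameter_um=40.0)
        truth = phantom.generate_phantom(slab_spec(cavities=[cav]))
        psf = gaussian_psf(shape=(7, 9, 9), spacing_um=SPACING)
        fl1_a, _ = phantom.simulate_fl_stacks(truth, psf, noise_sd=0.0, seed=0)
        truth.fl1_truth = truth.fl1_truth * 2.0
        truth.fl2_truth = truth.fl2_truth * 2.0
        fl1_b, _ = phantom.simulate_fl_stacks(truth, psf, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(fl1_b.to_array(), 2.0 * fl1_a.to_array(), rtol=1e-10, atol=1e-9)

    def test_point_source_reproduces_psf(self):
        truth = phantom.generate_phantom(slab_spec())
        truth.fl1_truth[:] = 0.0
        truth.fl2_truth[:] = 0.0
        truth.fl1_truth[12, 32, 32] = 1.0
        psf = gaussian_psf(shape=(7, 9, 9), spacing_um=SPACING)
        fl1, _ = phantom.simulate_fl_stacks(truth, psf, noise_sd=0.0, seed=0, gain=1.0)
        patch = fl1.to_array()[12 - 3 : 12 + 4, 32 - 4 : 32 + 5, 32 - 4 : 32 + 5]
        np.testing.assert_allclose(patch, psf.kernel, atol=1e-10)


class TestBeadSimulation:
    def test_single_bead_matches_sphere_convolved_psf(self):
        from scipy.signal import fftconvolve

        psf = gaussian_psf(shape=(7, 9, 9), spacing_um=SPACING)
        stack = phantom.simulate_bead_stack(
            [(12.0, 32.0, 32.0)], psf, shape=SMALL_SHAPE, noise_sd=0.0, amplitude=1.0,
            spacing_um=SPACING,
        )
        grids = np.meshgrid(*[np.arange(n) * d for n, d in zip(SMALL_SHAPE, SPACING)], indexing="ij")
        dist_sq = sum((g - c * d) ** 2 for g, c, d in zip(grids, (12.0, 32.0, 32.0), SPACING))
        sphere = (dist_sq <= 1.5**2).astype(float)
        expected = np.clip(fftconvolve(sphere, psf.kernel, mode="same"), 0, None)
        np.testing.assert_allclose(stack.to_array(), expected, atol=1e-12)

    def test_two_distant_beads_give_equal_patches(self):
        psf = gaussian_psf(shape=(7, 9, 9), spacing_um=SPACING)
        positions = [(12.0, 16.0, 16.0), (12.0, 48.0, 48.0)]
        stack = phantom.simulate_bead_stack(positions, psf, shape=SMALL_SHAPE, noise_sd=0.0, spacing_um=SPACING)
        arr = stack.to_array()
        p1 = arr[8:17, 10:23, 10:23]
        p2 = arr[8:17, 42:55, 42:55]
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    def test_beads_too_close_rejected(self):
        psf = gaussian_psf(shape=(7, 9, 9), spacing_um=SPACING)
        with pytest.raises(ValueError, match="apart"):
            phantom.simulate_bead_stack(
                [(12.0, 30.0, 30.0), (12.0, 32.0, 32.0)], psf, shape=SMALL_SHAPE, spacing_um=SPACING
            )

    def test_zero_beads_is_pure_noise(self):
        psf = gaussian_psf(shape=(7, 9, 9), spacing_um=SPACING)
        stack = phantom.simulate_bead_stack([], psf, shape=SMALL_SHAPE, noise_sd=1.0, seed=4, spacing_um=SPACING)
        arr = stack.to_array()
        assert abs(arr.mean()) < 1.0 and arr.std() < 1.5
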